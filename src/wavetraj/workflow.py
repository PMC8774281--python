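"""End-to-end pipeline: read -> CWT -> segmentation -> co-movement -> statistics.

A single declarative YAML config drives the run:

.. code-block:: yaml

    out: results/
    seed: 0
    params:            # analysis constants (all optional; defaults shown)
      a_tilde: 20
      r: 0.8
      scales_max: 50
      corridor_factor: 1.27
      corridor_min_um: 0.4
      max_turn_deg: 120.0
      corr_thresh: 0.7
      dist_thresh_um: 1.0
      min_overlap: 20
      msd_t_max_s: 4.0
      min_frames: 20
      max_gap: 3
    inputs:
      - cell_id: cell01
        organelle: cell01_lyso.csv
        cargo: cell01_np.csv     # optional; omit for untreated cells

Outputs are CSV tables (labels, runs, flights, pairs, msd, msdfits,
lengthfits, summary) plus a JSON run manifest with the config snapshot,
per-stage row counts and software version.  Re-running with the same config
and inputs reproduces the tables byte-for-byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .comovement import classify_all_pairs, split_by_comovement
from .heavytail import FitError, akaike_weights, fit_all, group_test
from .msdstats import fit_msd, pooled_msd, time_averaged_msd
from .segmentation import (
    ActiveDetectionParams,
    classify_active,
    extract_runs,
    merge_runs_to_flights,
    percent_time_active,
)
from .trajio import TrackSet, fill_gaps_all, filter_tracks, read_tracks
from .wavelet import cwt_trajectory

__all__ = ["DEFAULT_PARAMS", "run_pipeline", "analyze_trackset", "summarize_groups"]

log = logging.getLogger("wavetraj")

DEFAULT_PARAMS = {
    "a_tilde": 20,
    "r": 0.8,
    "scales_max": 50,
    "corridor_factor": 1.27,
    "corridor_min_um": 0.4,
    "max_turn_deg": 120.0,
    "corr_thresh": 0.7,
    "dist_thresh_um": 1.0,
    "min_overlap": 20,
    "msd_t_max_s": 4.0,
    "min_frames": 20,
    "max_gap": 3,
    "axis_combine": "or",
}


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending input."""


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    if not isinstance(config, dict) or "inputs" not in config:
        raise PipelineError("config must be a mapping with an 'inputs' list")
    params = dict(DEFAULT_PARAMS)
    params.update(config.get("params") or {})
    config = dict(config)
    config["params"] = params
    return config


def analyze_trackset(ts: TrackSet, params: dict | None = None) -> dict:
    """Run segmentation + MSD machinery on one (filtered) TrackSet.

    Returns per-track labels, runs, flights, maps and the pooled per-cell
    summaries; the building block the pipeline assembles its tables from.
    """
    p = dict(DEFAULT_PARAMS)
    p.update(params or {})
    det = ActiveDetectionParams(a_tilde=p["a_tilde"], r=p["r"], axis_combine=p["axis_combine"])
    scales = np.arange(1, p["scales_max"] + 1)

    maps, labels, runs, flights, curves = {}, {}, {}, {}, {}
    for tr in ts:
        mx, my = cwt_trajectory(tr, scales=scales)
        maps[tr.track_id] = (mx, my)
        lb = classify_active(mx, my, det)
        labels[tr.track_id] = lb
        rr = extract_runs(lb, tr)
        runs[tr.track_id] = rr
        flights[tr.track_id] = merge_runs_to_flights(
            rr, tr, corridor_factor=p["corridor_factor"],
            corridor_min=p["corridor_min_um"], max_turn=p["max_turn_deg"],
        )
        curves[tr.track_id] = time_averaged_msd(tr)

    out = {"maps": maps, "labels": labels, "runs": runs, "flights": flights, "curves": curves}
    if labels:
        out["pct_active"] = percent_time_active(labels.values())
        pooled = pooled_msd(list(curves.values()))
        out["msd"] = pooled
        try:
            out["msd_fit"] = fit_msd(pooled, t_max=p["msd_t_max_s"])
        except ValueError as exc:
            log.warning("MSD fit skipped: %s", exc)
            out["msd_fit"] = None
    return out


def _length_fit_rows(sample: np.ndarray, cell_id: str, group: str, kind: str) -> list[dict]:
    rows = []
    if sample.size < 10:
        return rows
    try:
        comp = akaike_weights(fit_all(sample))
    except (FitError, ValueError) as exc:
        log.warning("length fits skipped for %s/%s/%s: %s", cell_id, group, kind, exc)
        return rows
    for model, fit in comp.fits.items():
        rows.append({
            "cell_id": cell_id, "group": group, "kind": kind, "model": model,
            "params": json.dumps(fit.params, sort_keys=True), "xmin": fit.xmin,
            "n": fit.n, "loglik": fit.loglik, "aic": fit.aic,
            "weight": comp.weights[model], "winner": model == comp.winner,
        })
    return rows


def run_pipeline(config, out_dir: str | Path | None = None) -> Path:
    """Run the full analysis described by a YAML config (path or mapping)."""
    cfg = _load_config(config)
    p = cfg["params"]
    out = Path(out_dir or cfg.get("out", "wavetraj_out"))
    out.mkdir(parents=True, exist_ok=True)

    label_rows, run_rows, flight_rows, pair_rows = [], [], [], []
    msd_rows, msdfit_rows, lengthfit_rows, summary_rows = [], [], [], []
    manifest = {
        "version": __version__,
        "config": {k: v for k, v in cfg.items() if k != "inputs"},
        "inputs": [],
        "seed": cfg.get("seed", 0),
        "counts": {},
    }

    for item in cfg["inputs"]:
        cell_id = item.get("cell_id") or Path(item["organelle"]).stem
        try:
            lyso_raw = read_tracks(item["organelle"], channel="organelle", cell_id=cell_id)
        except Exception as exc:
            raise PipelineError(f"read stage failed for {item['organelle']}: {exc}") from exc
        lyso = fill_gaps_all(
            filter_tracks(lyso_raw, p["min_frames"], p["max_gap"]), p["max_gap"]
        )
        entry = {
            "cell_id": cell_id,
            "organelle": str(item["organelle"]),
            "n_tracks_raw": len(lyso_raw),
            "n_tracks_kept": len(lyso),
        }

        cargo = None
        if item.get("cargo"):
            cargo_raw = read_tracks(item["cargo"], channel="cargo", cell_id=cell_id)
            cargo = fill_gaps_all(
                filter_tracks(cargo_raw, p["min_frames"], p["max_gap"]), p["max_gap"]
            )
            entry["cargo"] = str(item["cargo"])
            entry["n_cargo_kept"] = len(cargo)
        else:
            entry["pair_stage"] = "skipped (no cargo channel)"
        manifest["inputs"].append(entry)
        if len(lyso) == 0:
            log.warning("cell %s: no tracks left after filtering", cell_id)
            continue

        res = analyze_trackset(lyso, p)

        for tid, lb in res["labels"].items():
            for i, s in enumerate(lb.states):
                label_rows.append({"cell_id": cell_id, "track_id": tid, "idx": i, "state": int(s)})
        for tid, rr in res["runs"].items():
            for r in rr:
                run_rows.append({
                    "cell_id": cell_id, "track_id": tid, "start_idx": r.start_idx,
                    "end_idx": r.end_idx, "l_um": r.l, "duration_s": r.duration,
                    "w_max_um": r.w_max,
                })
        fid = 0
        for tid, ff in res["flights"].items():
            for fl in ff:
                flight_rows.append({
                    "cell_id": cell_id, "track_id": tid, "flight_id": f"{cell_id}-{fid:05d}",
                    "n_runs": len(fl.runs),
                    "member_runs": ";".join(str(r.start_idx) for r in fl.runs),
                    "L_um": fl.L, "corridor_um": fl.corridor_width,
                })
                fid += 1

        groups = {"all": lyso}
        if cargo is not None and len(cargo) > 0:
            pairs = classify_all_pairs(
                lyso, cargo, scales=np.arange(1, p["scales_max"] + 1),
                min_overlap=p["min_overlap"], corr_thresh=p["corr_thresh"],
                dist_thresh=p["dist_thresh_um"], maps=res["maps"],
            )
            for pr in pairs:
                pair_rows.append({
                    "cell_id": cell_id, "lyso_id": pr.lyso_id, "cargo_id": pr.cargo_id,
                    "overlap_start": pr.overlap_start, "overlap_end": pr.overlap_end,
                    "Px": pr.px, "Py": pr.py, "mean_dist_um": pr.mean_dist,
                    "is_comoving": pr.is_comoving,
                })
            bearing, rest = split_by_comovement(lyso, pairs)
            if len(bearing):
                groups["cargo_bearing"] = bearing
            if len(rest):
                groups["cargo_free"] = rest

        for gname, gts in groups.items():
            if len(gts) == 0:
                continue
            if gname == "all":
                gres = res
            else:
                gres = analyze_trackset(gts, p)
            if gres.get("msd") is not None:
                for lag, m, nt in zip(gres["msd"].lag_s, gres["msd"].msd, gres["msd"].n_tracks):
                    msd_rows.append({
                        "cell_id": cell_id, "group": gname, "lag_s": lag,
                        "msd_um2": m, "n_tracks": int(nt),
                    })
            fit = gres.get("msd_fit")
            if fit is not None:
                msdfit_rows.append({
                    "cell_id": cell_id, "group": gname, "alpha": fit.alpha,
                    "D_um2_s": fit.D, "r2": fit.r2, "n_lags": fit.n_points,
                })
            run_l = np.array([r.l for rr in gres["runs"].values() for r in rr if r.l > 0])
            flight_l = np.array(
                [fl.L for ff in gres["flights"].values() for fl in ff if fl.L > 0]
            )
            lengthfit_rows += _length_fit_rows(run_l, cell_id, gname, "run")
            lengthfit_rows += _length_fit_rows(flight_l, cell_id, gname, "flight")
            summary_rows.append({
                "cell_id": cell_id, "group": gname, "n_tracks": len(gts),
                "pct_active": gres.get("pct_active", np.nan),
                "alpha": fit.alpha if fit else np.nan,
                "D_um2_s": fit.D if fit else np.nan,
                "mean_run_um": float(np.mean(run_l)) if run_l.size else np.nan,
                "mean_flight_um": float(np.mean(flight_l)) if flight_l.size else np.nan,
            })

    columns = {
        "labels.csv": ["cell_id", "track_id", "idx", "state"],
        "runs.csv": ["cell_id", "track_id", "start_idx", "end_idx", "l_um",
                     "duration_s", "w_max_um"],
        "flights.csv": ["cell_id", "track_id", "flight_id", "n_runs", "member_runs",
                        "L_um", "corridor_um"],
        "pairs.csv": ["cell_id", "lyso_id", "cargo_id", "overlap_start", "overlap_end",
                      "Px", "Py", "mean_dist_um", "is_comoving"],
        "msd.csv": ["cell_id", "group", "lag_s", "msd_um2", "n_tracks"],
        "msdfits.csv": ["cell_id", "group", "alpha", "D_um2_s", "r2", "n_lags"],
        "lengthfits.csv": ["cell_id", "group", "kind", "model", "params", "xmin",
                           "n", "loglik", "aic", "weight", "winner"],
        "summary.csv": ["cell_id", "group", "n_tracks", "pct_active", "alpha",
                        "D_um2_s", "mean_run_um", "mean_flight_um"],
    }
    tables = {
        "labels.csv": label_rows, "runs.csv": run_rows, "flights.csv": flight_rows,
        "pairs.csv": pair_rows, "msd.csv": msd_rows, "msdfits.csv": msdfit_rows,
        "lengthfits.csv": lengthfit_rows, "summary.csv": summary_rows,
    }
    for name, rows in tables.items():
        df = pd.DataFrame(rows) if rows else pd.DataFrame(columns=columns[name])
        df.to_csv(out / name, index=False)
        manifest["counts"][name] = len(rows)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    log.info("pipeline finished: %s", {k: len(v) for k, v in tables.items()})
    return out


def summarize_groups(summary: pd.DataFrame | str | Path, paired_groups=("cargo_bearing", "cargo_free")) -> pd.DataFrame:
    """Between-group tests on the per-cell summary table.

    Unpaired group contrasts use Wilcoxon-Mann-Whitney; the cargo-bearing vs
    cargo-free contrast is paired within cells (two-tailed paired t).  Groups
    with fewer than 2 cells are skipped with a warning.
    """
    if not isinstance(summary, pd.DataFrame):
        summary = pd.read_csv(Path(summary))
    metrics = ["alpha", "D_um2_s", "pct_active", "mean_run_um", "mean_flight_um"]
    rows = []
    groups = sorted(summary["group"].unique())
    for i, ga in enumerate(groups):
        for gb in groups[i + 1:]:
            a = summary[summary["group"] == ga].set_index("cell_id")
            b = summary[summary["group"] == gb].set_index("cell_id")
            paired = {ga, gb} == set(paired_groups)
            if paired:
                common = a.index.intersection(b.index)
                a, b = a.loc[common], b.loc[common]
            if len(a) < 2 or len(b) < 2:
                log.warning("test skipped for %s vs %s: fewer than 2 cells", ga, gb)
                continue
            for m in metrics:
                va, vb = a[m].dropna(), b[m].dropna()
                if paired:
                    common = va.index.intersection(vb.index)
                    if len(common) < 2:
                        continue
                    res = group_test(va.loc[common], vb.loc[common], paired=True,
                                     ids_a=list(common), ids_b=list(common))
                else:
                    if len(va) < 2 or len(vb) < 2:
                        continue
                    res = group_test(va, vb, paired=False)
                rows.append({
                    "group_a": ga, "group_b": gb, "metric": m, "test": res.name,
                    "statistic": res.statistic, "p_value": res.pvalue,
                    "mean_a": float(va.mean()), "mean_b": float(vb.mean()),
                })
    return pd.DataFrame(rows)
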