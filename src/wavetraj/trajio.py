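"""Reading, validation, filtering and gap-filling of particle-track tables.

A track table is a UTF-8 CSV with header ``track_id,frame,time_s,x_um,y_um``
(``time_s`` optional), one file per cell per imaging channel.  Positions are
assumed already calibrated to micrometres by the tracking software; frames are
non-negative integers.  When no time column is present, time stamps are derived
from the nominal frame interval (default 1/5.11 s, the acquisition rate the
analysis was designed around).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_FPS",
    "DEFAULT_DT",
    "TrackPoint",
    "Trajectory",
    "TrackSet",
    "TrackTableError",
    "read_tracks",
    "write_tracks",
    "filter_tracks",
    "fill_gaps",
]

DEFAULT_FPS = 5.11
#: Nominal frame interval in seconds (~200 ms) used when a file has no time column.
DEFAULT_DT = 1.0 / DEFAULT_FPS

REQUIRED_COLUMNS = ("track_id", "frame", "x_um", "y_um")
HEADER = ("track_id", "frame", "time_s", "x_um", "y_um")


class TrackTableError(ValueError):
    """Raised for malformed or inconsistent track tables."""


class TrackPoint(NamedTuple):
    frame: int
    t: float
    x: float
    y: float
    interpolated: bool


@dataclass
class Trajectory:
    """Ordered per-frame positions (µm) of one tracked object.

    Stored as parallel arrays; ``points`` exposes the per-frame view.
    ``interpolated`` marks frames inserted by :func:`fill_gaps`.
    """

    track_id: str
    frames: np.ndarray
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    interpolated: np.ndarray | None = None
    dt: float = DEFAULT_DT

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.int64)
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.interpolated is None:
            self.interpolated = np.zeros(self.frames.size, dtype=bool)
        self.interpolated = np.asarray(self.interpolated, dtype=bool)
        n = self.frames.size
        if not (self.t.size == self.x.size == self.y.size == self.interpolated.size == n):
            raise TrackTableError(f"track {self.track_id!r}: ragged point arrays")
        if n == 0:
            raise TrackTableError(f"track {self.track_id!r}: empty trajectory")
        if np.any(self.frames < 0):
            raise TrackTableError(f"track {self.track_id!r}: negative frame index")
        if n > 1:
            if np.any(np.diff(self.frames) <= 0):
                raise TrackTableError(f"track {self.track_id!r}: frames not strictly increasing")
            if np.any(np.diff(self.t) <= 0):
                raise TrackTableError(f"track {self.track_id!r}: time not strictly increasing")
        if self.interpolated[0] or self.interpolated[-1]:
            raise TrackTableError(
                f"track {self.track_id!r}: interpolated points at trajectory ends"
            )

    def __len__(self) -> int:
        return int(self.frames.size)

    @property
    def n_points(self) -> int:
        return int(self.frames.size)

    @property
    def span(self) -> int:
        """Temporal extent in frames, last - first + 1."""
        return int(self.frames[-1] - self.frames[0] + 1)

    @property
    def max_gap(self) -> int:
        """Largest number of consecutive missing frames (0 if gap-free)."""
        if self.frames.size < 2:
            return 0
        return int(np.max(np.diff(self.frames)) - 1)

    @property
    def is_gap_free(self) -> bool:
        return self.max_gap == 0

    @property
    def xy(self) -> np.ndarray:
        """(n, 2) position array in µm."""
        return np.column_stack([self.x, self.y])

    @property
    def points(self) -> list[TrackPoint]:
        return [
            TrackPoint(int(f), float(t), float(x), float(y), bool(i))
            for f, t, x, y, i in zip(self.frames, self.t, self.x, self.y, self.interpolated)
        ]


@dataclass
class TrackSet:
    """All trajectories of one imaging channel of one cell."""

    cell_id: str
    channel: str
    trajectories: list[Trajectory] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.channel not in ("organelle", "cargo"):
            raise TrackTableError(f"unknown channel {self.channel!r}")
        ids = [tr.track_id for tr in self.trajectories]
        if len(ids) != len(set(ids)):
            raise TrackTableError(f"duplicate track ids in cell {self.cell_id!r}")

    def __len__(self) -> int:
        return len(self.trajectories)

    def __iter__(self) -> Iterator[Trajectory]:
        return iter(self.trajectories)

    def get(self, track_id: str) -> Trajectory:
        for tr in self.trajectories:
            if tr.track_id == track_id:
                return tr
        raise KeyError(track_id)


def read_tracks(
    path: str | Path,
    channel: str = "organelle",
    cell_id: str | None = None,
    dt: float = DEFAULT_DT,
) -> TrackSet:
    """Parse a track-table CSV into a :class:`TrackSet` (unfiltered).

    Rows are grouped by ``track_id`` and sorted by ``frame``.  Malformed rows,
    duplicate ``(track_id, frame)`` pairs and non-monotone time stamps are
    rejected with the offending 1-based data row number.
    """
    path = Path(path)
    if cell_id is None:
        cell_id = path.stem
    try:
        df = pd.read_csv(path, dtype={"track_id": str}, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise TrackTableError(f"{path}: empty file (missing header)") from exc
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise TrackTableError(f"{path}: missing columns {missing}")
    if len(df) == 0:
        return TrackSet(cell_id=cell_id, channel=channel, trajectories=[])

    df = df.reset_index(drop=False).rename(columns={"index": "_row"})
    df["_row"] += 1  # 1-based data row number (header not counted)
    for col in ("frame", "x_um", "y_um"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna()
        if bad.any():
            row = int(df.loc[bad, "_row"].iloc[0])
            raise TrackTableError(f"{path}: malformed value in column {col!r} at data row {row}")
        df[col] = vals
    frac = df["frame"] % 1
    if (frac != 0).any():
        row = int(df.loc[frac != 0, "_row"].iloc[0])
        raise TrackTableError(f"{path}: non-integer frame at data row {row}")
    has_time = "time_s" in df.columns and df["time_s"].notna().all()
    if "time_s" in df.columns and not has_time and df["time_s"].notna().any():
        row = int(df.loc[df["time_s"].isna(), "_row"].iloc[0])
        raise TrackTableError(f"{path}: missing time_s value at data row {row}")

    dup = df.duplicated(subset=["track_id", "frame"], keep=False)
    if dup.any():
        row = int(df.loc[dup, "_row"].iloc[1])
        raise TrackTableError(f"{path}: duplicate (track_id, frame) at data row {row}")

    trajectories = []
    for tid, grp in df.groupby("track_id", sort=True):
        grp = grp.sort_values("frame")
        frames = grp["frame"].to_numpy(dtype=np.int64)
        t = grp["time_s"].to_numpy(dtype=float) if has_time else frames * dt
        if np.any(np.diff(t) <= 0):
            row = int(grp["_row"].to_numpy()[np.argmax(np.diff(t) <= 0) + 1])
            raise TrackTableError(f"{path}: non-monotone time_s in track {tid!r} at data row {row}")
        trajectories.append(
            Trajectory(
                track_id=str(tid),
                frames=frames,
                t=t,
                x=grp["x_um"].to_numpy(dtype=float),
                y=grp["y_um"].to_numpy(dtype=float),
                dt=float(np.median(np.diff(t))) if (has_time and len(grp) > 1) else dt,
            )
        )
    return TrackSet(cell_id=cell_id, channel=channel, trajectories=trajectories)


def write_tracks(ts: TrackSet, path: str | Path) -> Path:
    """Write a TrackSet back to the track-table dialect (round-trip safe)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(",".join(HEADER) + "\n")
        for tr in ts:
            for f, t, x, y in zip(tr.frames, tr.t, tr.x, tr.y):
                # repr gives shortest exact round-trip decimal for each float
                fh.write(
                    f"{tr.track_id},{int(f)},{float(t)!r},{float(x)!r},{float(y)!r}\n"
                )
    return path


def filter_tracks(ts: TrackSet, min_frames: int = 20, max_gap: int = 3) -> TrackSet:
    """Keep trajectories spanning >= ``min_frames`` frames with every internal
    gap <= ``max_gap`` missing frames.  Order preserved; idempotent."""
    kept = [tr for tr in ts if tr.span >= min_frames and tr.max_gap <= max_gap]
    return TrackSet(cell_id=ts.cell_id, channel=ts.channel, trajectories=kept)


def fill_gaps(tr: Trajectory, max_gap: int = 3) -> Trajectory:
    """Insert linearly interpolated points at missing frames.

    Inserted points are flagged ``interpolated``; originally observed frames
    are returned unchanged.  Gaps larger than ``max_gap`` raise (such tracks
    should have been removed by :func:`filter_tracks`).
    """
    if tr.max_gap > max_gap:
        raise TrackTableError(
            f"track {tr.track_id!r}: gap of {tr.max_gap} frames exceeds {max_gap}"
        )
    if tr.is_gap_free:
        return tr
    full = np.arange(tr.frames[0], tr.frames[-1] + 1, dtype=np.int64)
    x = np.interp(full, tr.frames, tr.x)
    y = np.interp(full, tr.frames, tr.y)
    t = np.interp(full, tr.frames, tr.t)
    observed = np.isin(full, tr.frames)
    # exact values at observed frames (np.interp is exact at knots, but be explicit)
    x[observed] = tr.x
    y[observed] = tr.y
    t[observed] = tr.t
    return replace(tr, frames=full, t=t, x=x, y=y, interpolated=~observed)


def fill_gaps_all(ts: TrackSet, max_gap: int = 3) -> TrackSet:
    """Gap-fill every trajectory of a TrackSet."""
    return TrackSet(
        cell_id=ts.cell_id,
        channel=ts.channel,
        trajectories=[fill_gaps(tr, max_gap=max_gap) for tr in ts],
    )
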