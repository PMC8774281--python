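"""Run the end-to-end pipeline on a simulated two-channel cell.

Simulates organelle tracks plus cargo tracks (some genuinely co-moving),
writes track tables, runs the full analysis (segmentation, co-movement
sorting, MSD fits, length-model selection) and prints the per-group summary.
"""

import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

from wavetraj import SimConfig, TrackSet, run_pipeline, simulate_pair, write_tracks

root = Path(tempfile.mkdtemp(prefix="wavetraj_demo_"))
cfg = SimConfig(seed=9, n_steps=800)
rng = np.random.default_rng(9)

lysos, cargos = [], []
for k in range(6):
    lyso, cargo, _ = simulate_pair(cfg, comoving=(k < 3), rng=rng,
                                   ids=(f"lyso-{k}", f"cargo-{k}"))
    lysos.append(lyso)
    cargos.append(cargo)

lyso_csv = write_tracks(TrackSet("cell01", "organelle", lysos), root / "lyso.csv")
cargo_csv = write_tracks(TrackSet("cell01", "cargo", cargos), root / "cargo.csv")

out = run_pipeline(
    {"inputs": [{"cell_id": "cell01", "organelle": str(lyso_csv),
                 "cargo": str(cargo_csv)}]},
    out_dir=root / "results",
)

pairs = pd.read_csv(out / "pairs.csv")
summary = pd.read_csv(out / "summary.csv")
print(f"output tables in {out}")
print(f"\npairs classified co-moving: {int(pairs['is_comoving'].sum())} "
      f"of {len(pairs)} overlapping pairs")
print("\nper-group summary (organelles sorted by detected cargo):")
print(summary[["group", "n_tracks", "pct_active", "alpha", "D_um2_s"]]
      .to_string(index=False))
print()
print("'cargo_bearing' tracks were identified purely from trajectory data;")
print("their transport statistics can now be compared with the cargo-free rest.")
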