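"""Detect active-transport runs in a simulated stop-and-go trajectory.

Simulates one organelle track (directional runs alternating with tethered
pauses at ~5.11 frames/s), computes its Haar wavelet maps, applies the
universal-threshold detector and prints the recovered runs next to the
planted ground truth.
"""

import numpy as np

from wavetraj import (
    SimConfig,
    classify_active,
    cwt_trajectory,
    extract_runs,
    merge_runs_to_flights,
    percent_time_active,
    simulate_stop_and_go,
)

cfg = SimConfig(seed=7, n_steps=1000)
track, truth = simulate_stop_and_go(cfg)

map_x, map_y = cwt_trajectory(track)
labels = classify_active(map_x, map_y)
runs = extract_runs(labels, track)
flights = merge_runs_to_flights(runs, track)

print(f"track of {len(track)} frames ({len(track) * cfg.dt:.0f} s)")
print(f"planted runs: {len(truth.runs)}   detected runs: {len(runs)}   "
      f"flights: {len(flights)}")
print(f"time in active transport: {percent_time_active([labels]):.1f}% "
      f"(ground truth {100 * truth.active_fraction:.1f}%)")
print()
print("first detected runs (time indices, chord length in um):")
for r in runs[:5]:
    print(f"  [{r.start_idx:4d}, {r.end_idx:4d}]  l = {r.l:.2f} um  "
          f"w_max = {r.w_max:.3f} um")
print()
print("Each run is a maximal stretch whose scale-20 wavelet coefficient")
print("exceeds the noise-adaptive threshold; flights chain runs that continue")
print("in the same direction inside the 1.27x / 0.4 um corridor.")
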