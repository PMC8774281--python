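"""Classify organelle-cargo pairs as co-moving or independent.

Simulates one genuinely co-moving pair (cargo tethered to the organelle by a
mean-reverting offset) and one hard negative (independent motion translated
to sit 0.8 um apart on average), then applies the wavelet-correlation +
distance rule.  The distance gate alone cannot tell them apart; the
multiscale correlation can.
"""

import numpy as np

from wavetraj import SimConfig, TrackSet, classify_all_pairs, simulate_pair

cfg = SimConfig(seed=5, n_steps=600)

for label, comoving in [("true co-moving pair", True), ("independent near pair", False)]:
    lyso, cargo, truth = simulate_pair(cfg, comoving=comoving)
    (result,) = classify_all_pairs(
        TrackSet("demo", "organelle", [lyso]),
        TrackSet("demo", "cargo", [cargo]),
    )
    verdict = "co-moving" if result.is_comoving else "not co-moving"
    print(f"{label}:")
    print(f"  Px = {result.px:+.2f}  Py = {result.py:+.2f}  "
          f"mean distance = {result.mean_dist:.2f} um  ->  {verdict}")

print()
print("A pair is co-moving iff BOTH axis correlations exceed 0.7 AND the mean")
print("center-to-center distance is below 1 um.  The independent pair passes")
print("the distance gate but its wavelet maps are uncorrelated.")
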