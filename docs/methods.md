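# Methods

This note records the models implemented in `wavetraj`, the defaults and why
they were chosen, the numerical decisions, and what the synthetic-data tests
do and do not demonstrate.

## Haar wavelet transform of trajectories

Each coordinate series s(t) of a trajectory is transformed with the Haar
kernel ψ (+1 on the first half of its support, −1 on the second) at integer
scales a = 1…50:

    C[a, t0] = Σ_k w_k(a) · s(t0 − ⌊a/2⌋ + k),   k = 0 … a−1.

The weights w_k(a) are the integrals of the scale-a kernel over each sample
interval (signal treated as piecewise constant). They are exactly zero-sum at
every scale — ±1 for even a, with the middle sample of odd a given weight 0 —
so a constant series maps to zero and the coefficient is a local displacement
detector: the difference between the particle's summed position over the
first and second half of a window of a frames.

**Normalization.** The discrete sum is left *unnormalized* (prefactor 1).
This is the convention under which the standard deviation of the coefficients
of white noise grows exactly as √a, which the threshold projection below
relies on; `1/a` and `1/√a` prefactors are available as options for
sensitivity checks but are not used by the detector.

**Edges.** Windows are centred on t0 (odd scales are off-centre by half a
sample). Columns whose window extends past the series are computed on the
edge-replicated signal (first/last value held) and flagged per scale.
Replication — rather than zero-padding — keeps the transform invariant to a
rigid translation of the whole track even at the edges; this matters for the
pair-correlation stage, where the maps of two tracks are compared regardless
of their absolute positions. Edge-affected columns are excluded from
active-motion detection anyway. The series mean is subtracted before the
cumulative-sum evaluation; for a zero-sum kernel this is an exact no-op that
avoids floating-point cancellation on tracks far from the origin.

## Active-transport detection

With per-track, per-axis noise level σ₂ = medianᵢ|Cᵢ,₂| / 0.6745 (the MAD
estimate; 0.6745 = Φ⁻¹(0.75), computed over non-edge scale-2 columns), the
detection threshold at scale ã is

    δ = r · σ₂ · √(2 ln N) · √(ã/2),

with N the number of time points after excluding ⌊ã/2⌋ points at each end,
r = 0.8 and ã = 20 by default. √(2 ln N) is the universal threshold of
wavelet denoising (the expected maximum of N Gaussians), and √(ã/2) projects
the scale-2 noise level to scale ã under the white-noise √a law. A point is
active when |C| at scale ã exceeds its axis threshold on either axis
(OR-combination; a vector-magnitude rule is available via
`axis_combine="norm"`). OR preserves sensitivity to axis-aligned motion at a
doubled — still small — false-positive rate.

Maximal contiguous active stretches of ≥ 2 points become runs. Run length l
is the start→end chord, not the path length, and w_max is the maximum
perpendicular deviation of the run's points from that chord. Runs are merged
into flights greedily in time order: a run joins the current flight iff the
turning angle between consecutive runs' chord vectors is ≤ 120° and all its
points lie within a corridor of width max(1.27 · w_flight, 0.4 µm) about the
line through the flight's start and the candidate's end, where w_flight is
the flight's own maximum chord width. Degenerate runs (zero chord) carry no
direction: the angle test passes trivially and the corridor floor decides.
Percent time active is pooled over tracks: 100 · active / non-excluded.

**Detector resolution.** The scale-ã coefficient responds whenever the
ã-frame window overlaps directional displacement, so detected runs are
systematically *longer* than the underlying active phases — by up to ~ã/2
frames per boundary. Run counts and recall are reliable; detected run
*durations* (and hence percent-time-active) are upper estimates when true
runs are much shorter than ã. Chord lengths are less affected because the
passive motion surrounding a run adds little net displacement.

**What the detector cannot do.** The √(ã/2) projection assumes the passive
background is white (localization noise, tethered jiggle). Genuinely free
Brownian motion is not white in position: its scale-a Haar energy grows like
a³, so a freely diffusing particle whose per-frame displacement exceeds the
noise floor is partially flagged active at scale 20. This is inherent to the
method — at scale ã it detects *coherent displacement*, not motors. The
conservative-on-noise guarantee (false-positive fraction ≤ 5 %) applies to
the noise-dominated passive regime the generator's pause phases emulate.

## Co-movement classification

For each organelle–cargo pair overlapping ≥ 20 frames (the track-length
floor), the CWT maps of both tracks are restricted to the overlap columns
(all 50 scales, edge columns retained) and flattened; Pₓ and P_y are the
Pearson correlations of the same-axis matrices, and the mean center-to-center
distance is averaged over shared frames. The pair is co-moving iff
Pₓ > 0.7 ∧ P_y > 0.7 ∧ mean distance < 1 µm. Flattening weights scales by
their coefficient variance, which concentrates the comparison on the
large-amplitude transport scales while retaining the fast components.

A caution established by Monte-Carlo during development: the correlation of
two *independent* tracks is only small on average. For free Brownian pairs
the large scales contribute few effective degrees of freedom, and single-pair
|P| values up to ~0.7 occur; the classifier is nevertheless specific because
both axes must independently exceed 0.7 and because near-stationary pairs —
the hard case that also passes the distance gate — have noise-dominated,
high-dof maps with |P| tightly near 0.

## MSD analysis

Per track, the time-averaged MSD at lag k·dt is the mean squared displacement
over all start frames, computed for lags 1…min(span−1, 20); per-cell curves
are unweighted means across tracks at each lag (short tracks contribute to
the lags they have). A line fit to (log t, log MSD) over lags in (0, 4 s]
gives α (slope) and D (intercept) via the 2D convention **MSD = 4 D t^α**.
D is therefore a "generalized diffusion coefficient";
any other prefactor convention rescales D by a constant and leaves α
untouched. With dt = 1/5.11 s the 4-s window is exactly the default 20 lags.
Fits require ≥ 3 strictly positive MSD values in the window.

## Heavy-tailed length models

All five candidates are fit on the common support [xmin, ∞) with densities
truncated and renormalized at xmin (default: the sample minimum), so their
log-likelihoods and AICs are directly comparable:

| model | density on [xmin, ∞) | parameters | MLE |
|---|---|---|---|
| lognormal | LN(x; µ, σ) / S_LN(xmin) | µ, σ | numeric |
| power law | (γ−1)/xmin · (x/xmin)^−γ | γ | γ̂ = 1 + n/Σln(x/xmin) |
| truncated power law | x^−γ e^−λx / Z | γ, λ | numeric |
| stretched exponential | λβ x^{β−1} e^{−λx^β} · e^{λ xmin^β} | λ, β | numeric |
| exponential | λ e^{−λ(x−xmin)} | λ | λ̂ = 1/mean(x−xmin) |

The truncated-power-law normalizer Z = λ^{γ−1} Γ(1−γ, λ·xmin) uses the upper
incomplete gamma continued to non-positive shape by the recurrence
Γ(s,z) = (Γ(s+1,z) − z^s e^{−z})/s, with a quadrature fallback where the
recurrence cancels. Numeric MLEs run multi-start Nelder–Mead from
moment-based initial values with rates/scales optimized on a log scale;
`xatol=1e-8`. AIC = 2k − 2·loglik with k counting shape/rate parameters only
(xmin is shared); AICc is unnecessary at the sample sizes involved
(thousands). Akaike weights are exp(−Δᵢ/2) normalized over the candidate set.

**A structural limit of AIC weights.** The power law is the λ→0 boundary of
the truncated power law, and the exponential is the β=1 point of the
stretched exponential. On data generated from the *smaller* model the larger
model's fitted likelihood is never lower, so ΔAIC ≤ 2 and the generating
model's weight cannot exceed ≈ exp(0)/(exp(0)+exp(−1)) ≈ 0.73 no matter how
much data is collected. The generating model still *wins* (smallest AIC) with
high probability — model identification is reliable; a weight > 0.99 is
simply not a reachable certificate for a model nested at a competitor's
boundary, and the corresponding two acceptance-style assertions are expected
to fail by construction.

Group statistics follow the assignment used throughout: pooled length
distributions are compared with the two-sample Cramér–von Mises test
(asymptotic p by default, permutation option for small n); per-cell summary
metrics with Wilcoxon–Mann–Whitney, except cargo-bearing vs cargo-free
within the same cells, which is a two-tailed paired t-test.

## Synthetic data generator

The generator emulates the acquisition and motion structure the analysis
assumes: 2D tracks at dt = 1/5.11 s ≈ 0.196 s (the nominal confocal frame
interval), default 1000 frames (~3 min), with i.i.d. Gaussian localization
noise σ_loc = 0.03 µm (sub-pixel accuracy typical of confocal particle
tracking).

Stop-and-go tracks alternate two renewal phases:

* **Runs** — lengths drawn from a configurable model, by default the
  lognormal(µ = −0.193, σ = 0.804) law measured for untreated breast
  epithelial cells (median ≈ 0.82 µm), traversed at v = 1 µm/s (a typical
  motor-transport speed) in a direction equal to the previous run's rotated
  by a wrapped-normal angle (s.d. 30°, giving the realistic forward-peaked
  turning-angle distribution; a reversal-heavy preset mimics cargo-loaded
  behaviour).
* **Pauses** — exponential durations with mean 7 s, chosen so the active-time
  fraction lands near 14 %, inside the 7–17 % range reported for lysosomes.
  Pauses are modelled as *tethered* states with residual diffusivity
  D_passive = 2×10⁻⁵ µm²/s: over a full 20-frame detection window the RMS
  wander (~0.013 µm) stays below the localization noise, reflecting caged
  organelle motion at cytoskeletal obstacles rather than free cytoplasmic
  diffusion. Free diffusion at any D above the noise floor is *not* a pause
  in the sense of this detector (see "What the detector cannot do").

Reference fixtures: free Brownian motion (per-axis increment variance
2·D·dt), constant-velocity ballistic tracks, and Brownian motion confined to
a reflecting disc (default radius 0.3 µm). Co-moving pairs tether the cargo
to the organelle's noise-free path by a stationary Ornstein–Uhlenbeck offset
(per-axis s.d. 0.15 µm, relaxation 1 s) — mean-reverting rather than rigid,
so correlations are high but below 1 — plus independent localization noise.
Hard-negative pairs are two independently simulated tethered tracks, the
cargo translated so the mean center-to-center distance equals 0.8 µm:
independent motion *inside* the distance gate, the case the correlation rule
exists to reject. All randomness flows through one `numpy` Generator per
call, so a seed fixes every output bit-for-bit.

**What passing tests show — and don't.** The generator reproduces the
statistical structure the method assumes (heavy-tailed runs, persistent
directions, noise-dominated pauses, tethered cargo). It does not emulate
tracking artifacts (localization error that grows with speed, missed
detections, identity switches), drift, z-escape, or density-dependent
linking errors; recall/specificity numbers on synthetic data are therefore
upper bounds on real-data performance, and run-duration inflation (above)
must be kept in mind when comparing percent-active values across settings
with different run-length scales.

## Problem sizes and determinism

The test suite and the acceptance script size their simulations to run in
seconds on one core: 500 Brownian / 200 confined tracks of 1000 frames for
the MSD limits, 30 stop-and-go and 30 passive tracks for detector recall and
specificity, 100 seeded pairs per class for co-movement rates, n = 3000–5742
for the MLE and model-selection checks. These sizes put Monte-Carlo
uncertainty an order of magnitude below every asserted tolerance. All tests
and the acceptance script derive their randomness from fixed or
caller-supplied seeds through `numpy.random.default_rng`.
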