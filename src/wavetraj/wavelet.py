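"""Continuous wavelet transform of trajectory coordinates with the Haar kernel.

Each coordinate series s(t) of a trajectory is convolved with Haar kernels of
integer scales (widths) a = 1..50, giving a scale-by-time coefficient map
C[a, t0].  The Haar coefficient at scale a is the difference between the sums
of the signal over the first and second half of a window of width a centred at
t0, i.e. a local displacement detector: large |C| marks coherent directional
motion on timescale a, while uncorrelated localization noise only contributes
coefficients with standard deviation growing as sqrt(a).

Discretization.  The signal is treated as piecewise constant between samples
and the kernel is integrated over each sample interval.  The resulting weights
are exactly zero-sum at every scale (so a constant series maps to zero), equal
to +/-1 for even scales, and give the middle sample of odd scales weight zero.
The sum is left unnormalized (prefactor 1) by default: this is the convention
under which the universal-threshold projection from scale 2 to the detection
scale by sqrt(a/2) is exact for white noise (see :mod:`wavetraj.segmentation`).

Windows are centred on t0; columns whose window sticks out of the observed
series are computed on the edge-replicated (first/last value held) signal and
flagged edge-affected.  Replication keeps the transform exactly invariant to
a constant position offset even at the edges, so a stationary track maps to
zero everywhere; edge columns are still discarded by the active-motion
detector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trajio import Trajectory

__all__ = [
    "DEFAULT_SCALES",
    "WaveletMap",
    "haar",
    "haar_weights",
    "cwt_series",
    "cwt_trajectory",
]

#: Integer scales 1..50 used throughout the analysis.
DEFAULT_SCALES = np.arange(1, 51)

_NORMALIZATIONS = ("none", "inv_a", "inv_sqrt_a")


def haar(u):
    """The Haar mother wavelet: +1 on [0, 1/2), -1 on [1/2, 1), 0 otherwise."""
    u = np.asarray(u, dtype=float)
    out = np.where((u >= 0.0) & (u < 0.5), 1.0, np.where((u >= 0.5) & (u < 1.0), -1.0, 0.0))
    return out if out.ndim else float(out)


def haar_weights(a: int) -> np.ndarray:
    """Discrete Haar weights at integer scale ``a``.

    Weight k is the integral of the scale-a Haar kernel over the k-th sample
    interval [k, k+1) of its support, i.e. the overlap of that interval with
    the positive half [0, a/2) minus the overlap with the negative half.
    Zero-sum for every a; +/-1 for even a; middle weight 0 for odd a.
    """
    if a < 1:
        raise ValueError("scale must be a positive integer")
    k = np.arange(a, dtype=float)
    half = a / 2.0
    pos = np.clip(np.minimum(k + 1.0, half) - k, 0.0, 1.0)
    neg = np.clip(k + 1.0 - np.maximum(k, half), 0.0, 1.0)
    return pos - neg


@dataclass
class WaveletMap:
    """CWT coefficient matrix for one coordinate axis of one trajectory.

    ``C[i, t0]`` is the coefficient at ``scales[i]`` and time index t0;
    ``edge[i, t0]`` flags columns whose window extends past either end of the
    series (computed on the edge-replicated signal).
    """

    track_id: str
    axis: str
    scales: np.ndarray
    C: np.ndarray
    edge: np.ndarray
    normalization: str = "none"

    def __post_init__(self) -> None:
        self.scales = np.asarray(self.scales, dtype=int)
        if self.C.shape != (self.scales.size, self.C.shape[1]):
            raise ValueError("C must have one row per scale")
        if self.edge.shape != self.C.shape:
            raise ValueError("edge mask must match C")

    @property
    def n_times(self) -> int:
        return int(self.C.shape[1])

    def scale_index(self, a: int) -> int:
        idx = np.flatnonzero(self.scales == a)
        if idx.size == 0:
            raise ValueError(f"scale {a} not present in map")
        return int(idx[0])

    def row(self, a: int) -> np.ndarray:
        """Coefficient row at scale ``a``."""
        return self.C[self.scale_index(a)]

    def edge_row(self, a: int) -> np.ndarray:
        return self.edge[self.scale_index(a)]


def cwt_series(
    s,
    scales=None,
    normalization: str = "none",
    track_id: str = "",
    axis: str = "x",
) -> WaveletMap:
    """Haar CWT of a uniformly sampled series over the given integer scales.

    The window at scale a for column t0 covers sample indices
    ``[t0 - a//2, t0 - a//2 + a)``; out-of-range samples repeat the first or
    last observed value and the column is flagged edge-affected at that scale.
    The transform is linear in the signal and maps constant series to zero at
    every scale and every column.
    """
    s = np.asarray(s, dtype=float)
    if s.ndim != 1:
        raise ValueError("series must be one-dimensional")
    if normalization not in _NORMALIZATIONS:
        raise ValueError(f"normalization must be one of {_NORMALIZATIONS}")
    scales = DEFAULT_SCALES if scales is None else np.asarray(scales, dtype=int)
    if scales.size == 0 or np.any(scales < 1):
        raise ValueError("scales must be positive integers")
    T = s.size
    amax = int(scales.max())
    if T < amax:
        raise ValueError(f"series length {T} shorter than largest scale {amax}")

    pad = amax
    # the kernel is zero-sum, so removing the series mean is a mathematical
    # no-op; numerically it kills cumsum cancellation for far-from-origin tracks
    s0 = s - s.mean()
    padded = np.concatenate([np.full(pad, s0[0]), s0, np.full(pad, s0[-1])])
    cs = np.concatenate([[0.0], np.cumsum(padded)])
    t = np.arange(T)
    C = np.empty((scales.size, T))
    edge = np.zeros((scales.size, T), dtype=bool)
    for i, a in enumerate(scales):
        a = int(a)
        shift = a // 2          # window start = t0 - shift
        h = a // 2              # number of +1 samples (middle sample of odd a has weight 0)
        j0 = t + pad - shift
        row = (cs[j0 + h] - cs[j0]) - (cs[j0 + a] - cs[j0 + a - h])
        if normalization == "inv_a":
            row = row / a
        elif normalization == "inv_sqrt_a":
            row = row / np.sqrt(a)
        C[i] = row
        edge[i] = (t - shift < 0) | (t - shift + a > T)
    return WaveletMap(
        track_id=track_id, axis=axis, scales=scales, C=C, edge=edge, normalization=normalization
    )


def cwt_trajectory(
    tr: Trajectory, scales=None, normalization: str = "none"
) -> tuple[WaveletMap, WaveletMap]:
    """CWT maps of the x and y coordinate of a gap-filled trajectory."""
    if not tr.is_gap_free:
        raise ValueError(f"track {tr.track_id!r} has gaps; fill_gaps it first")
    mx = cwt_series(tr.x, scales=scales, normalization=normalization, track_id=tr.track_id, axis="x")
    my = cwt_series(tr.y, scales=scales, normalization=normalization, track_id=tr.track_id, axis="y")
    return mx, my
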