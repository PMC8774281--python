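"""Mean-square-displacement curves and anomalous-diffusion fits.

The time-averaged MSD of a track at lag k*dt is the mean over start frames of
the squared 2D displacement; per-track curves are pooled by an unweighted mean
across tracks at each lag.  Fitting log MSD against log t over lags up to 4 s
gives the scaling exponent alpha (slope) and the generalized diffusion
coefficient D via the 2D convention MSD = 4 D t^alpha (intercept).  alpha ~ 1
marks pure diffusion, alpha < 1 confined/subdiffusive motion, alpha -> 2
ballistic transport, and 1 < alpha < 2 the superdiffusive regime typical of
stop-and-go organelle transport.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trajio import Trajectory

__all__ = ["MSDCurve", "MSDFit", "time_averaged_msd", "pooled_msd", "fit_msd"]

#: Default cap on the number of lags per track (with dt ~ 0.1957 s this spans ~4 s).
DEFAULT_MAX_LAG = 20


@dataclass
class MSDCurve:
    """MSD values (µm²) on a strictly increasing lag grid (s).

    ``n_tracks[i]`` is the number of tracks contributing to lag i (1 for a
    single-track curve).  The zero lag, for which MSD = 0 by convention, is
    not stored.
    """

    lag_s: np.ndarray
    msd: np.ndarray
    n_tracks: np.ndarray

    def __post_init__(self) -> None:
        self.lag_s = np.asarray(self.lag_s, dtype=float)
        self.msd = np.asarray(self.msd, dtype=float)
        self.n_tracks = np.asarray(self.n_tracks, dtype=int)
        if not (self.lag_s.size == self.msd.size == self.n_tracks.size):
            raise ValueError("ragged MSD curve arrays")
        if self.lag_s.size and np.any(np.diff(self.lag_s) <= 0):
            raise ValueError("lag times must be strictly increasing")
        if np.any(self.msd < 0):
            raise ValueError("negative MSD value")


@dataclass
class MSDFit:
    """Power-law fit MSD = 4 D t^alpha over a log-log window."""

    alpha: float
    D: float
    t_min: float
    t_max: float
    r2: float
    n_points: int


def time_averaged_msd(tr: Trajectory, max_lag: int | None = None) -> MSDCurve:
    """Time-averaged MSD of one (gap-filled) trajectory for lags 1..max_lag.

    ``max_lag`` defaults to min(span - 1, 20) so that short tracks still
    contribute their small lags when pooled.
    """
    if not tr.is_gap_free:
        raise ValueError(f"track {tr.track_id!r} has gaps; fill_gaps it first")
    n = len(tr)
    if max_lag is None:
        max_lag = min(n - 1, DEFAULT_MAX_LAG)
    if max_lag >= n:
        raise ValueError(f"max_lag {max_lag} >= track length {n}")
    if max_lag < 1:
        raise ValueError("max_lag must be >= 1")
    lags = np.arange(1, max_lag + 1)
    msd = np.empty(max_lag)
    for i, k in enumerate(lags):
        dx = tr.x[k:] - tr.x[:-k]
        dy = tr.y[k:] - tr.y[:-k]
        msd[i] = np.mean(dx * dx + dy * dy)
    return MSDCurve(lag_s=lags * tr.dt, msd=msd, n_tracks=np.ones(max_lag, dtype=int))


def pooled_msd(curves: list[MSDCurve]) -> MSDCurve:
    """Unweighted mean of per-track curves at each lag.

    Curves must share a common lag grid prefix (shorter curves contribute to
    the lags they have); ``n_tracks`` records how many curves entered each
    lag.  Permutation-invariant.
    """
    curves = list(curves)
    if not curves:
        raise ValueError("no curves to pool")
    longest = max(curves, key=lambda c: c.lag_s.size)
    grid = longest.lag_s
    for c in curves:
        m = c.lag_s.size
        if not np.allclose(c.lag_s, grid[:m], rtol=1e-9, atol=1e-12):
            raise ValueError("curves are not on a shared lag grid")
    total = np.zeros(grid.size)
    counts = np.zeros(grid.size, dtype=int)
    for c in curves:
        m = c.lag_s.size
        total[:m] += c.msd * c.n_tracks
        counts[:m] += c.n_tracks
    return MSDCurve(lag_s=grid, msd=total / counts, n_tracks=counts)


def fit_msd(curve: MSDCurve, t_min: float = 0.0, t_max: float = 4.0) -> MSDFit:
    """Least-squares line on (log t, log MSD) over lags in (t_min, t_max].

    The slope is alpha; D is recovered from the intercept via the 2D
    convention MSD = 4 D t^alpha.  Requires at least 3 strictly positive MSD
    values in the window.
    """
    eps = 1e-9 * max(t_max, 1.0)
    sel = (curve.lag_s > t_min) & (curve.lag_s <= t_max + eps)
    if np.sum(sel) < 3:
        raise ValueError("need at least 3 lags inside the fit window")
    t = curve.lag_s[sel]
    m = curve.msd[sel]
    if np.any(m <= 0):
        raise ValueError("non-positive MSD inside the fit window; cannot fit log-log")
    lt, lm = np.log(t), np.log(m)
    slope, intercept = np.polyfit(lt, lm, 1)
    pred = slope * lt + intercept
    ss_res = float(np.sum((lm - pred) ** 2))
    ss_tot = float(np.sum((lm - np.mean(lm)) ** 2))
    r2 = 1.0 if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
    return MSDFit(
        alpha=float(slope),
        D=float(np.exp(intercept) / 4.0),
        t_min=float(t_min),
        t_max=float(t_max),
        r2=r2,
        n_points=int(np.sum(sel)),
    )
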