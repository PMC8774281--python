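"""Active-transport detection, run extraction and flight merging.

Time points of a trajectory are classified *active* when the magnitude of its
Haar wavelet coefficient at the detection scale (default 20 frames, ~4 s)
exceeds a noise-adaptive universal threshold

    delta = r * sigma_2 * sqrt(2 ln N) * sqrt(a_tilde / 2),

where sigma_2 = median|C_{i,2}| / 0.6745 is the MAD estimate of the noise
standard deviation on scale 2, N is the number of points of the trajectory
after excluding a_tilde time steps, and the sqrt(a_tilde/2) factor projects
the scale-2 noise level to the detection scale (exact for white noise under
the unnormalized Haar sum).  The first and last a_tilde/2 points of each track
are excluded because their coefficients are edge-affected.

Maximal contiguous active stretches become *runs*; consecutive runs continuing
in the same direction are chained into *flights* with an error-radius corridor
rule: a run joins the current flight when its turning angle relative to the
previous run is at most 120 degrees and all its points lie inside a corridor
of width max(1.27 * flight width, 0.4 um) around the flight's direction line.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .trajio import Trajectory
from .wavelet import WaveletMap

__all__ = [
    "EXCLUDED",
    "PASSIVE",
    "ACTIVE",
    "ActiveDetectionParams",
    "ActiveLabels",
    "RunSegment",
    "Flight",
    "noise_sigma2",
    "universal_threshold",
    "classify_active",
    "extract_runs",
    "merge_runs_to_flights",
    "percent_time_active",
    "turning_angles",
]

EXCLUDED = -1
PASSIVE = 0
ACTIVE = 1


@dataclass(frozen=True)
class ActiveDetectionParams:
    """Parameters of the wavelet active-transport detector.

    ``a_tilde`` is the detection scale in frames, ``r`` the threshold
    pre-factor, ``noise_scale`` the (fixed) scale used for the MAD noise
    estimate and ``axis_combine`` how the per-axis exceedances are combined
    ("or": active if either axis exceeds its threshold; "norm": active if the
    coefficient vector magnitude exceeds the combined threshold magnitude).
    """

    a_tilde: int = 20
    r: float = 0.8
    noise_scale: int = 2
    mad_const: float = 0.6745
    axis_combine: str = "or"

    def __post_init__(self) -> None:
        if self.a_tilde < 2:
            raise ValueError("a_tilde must be >= 2")
        if self.r <= 0:
            raise ValueError("r must be positive")
        if self.axis_combine not in ("or", "norm"):
            raise ValueError("axis_combine must be 'or' or 'norm'")

    @property
    def n_exclude(self) -> int:
        """Points excluded at each end of a track: floor(a_tilde / 2)."""
        return self.a_tilde // 2


@dataclass
class ActiveLabels:
    """Per-time-point motion state of one trajectory."""

    track_id: str
    states: np.ndarray  # int8: EXCLUDED / PASSIVE / ACTIVE
    params: ActiveDetectionParams
    threshold_x: float = np.nan
    threshold_y: float = np.nan
    sigma2_x: float = np.nan
    sigma2_y: float = np.nan

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int8)

    @property
    def n_active(self) -> int:
        return int(np.sum(self.states == ACTIVE))

    @property
    def n_valid(self) -> int:
        """Number of non-excluded points."""
        return int(np.sum(self.states != EXCLUDED))

    @property
    def active_mask(self) -> np.ndarray:
        return self.states == ACTIVE


@dataclass
class RunSegment:
    """One maximal contiguous active stretch of a trajectory.

    ``l`` is the net start-to-end (chord) displacement in µm; ``w_max`` the
    maximum perpendicular distance of the run's points from that chord.
    Indices are inclusive time indices into the trajectory.
    """

    track_id: str
    start_idx: int
    end_idx: int
    start: np.ndarray
    end: np.ndarray
    l: float
    duration: float
    w_max: float


@dataclass
class Flight:
    """A chain of same-direction runs merged by the corridor rule."""

    runs: list[RunSegment]
    corridor_width: float

    @property
    def start(self) -> np.ndarray:
        return self.runs[0].start

    @property
    def end(self) -> np.ndarray:
        return self.runs[-1].end

    @property
    def L(self) -> float:
        """Net flight length (µm): start-to-end chord of the whole chain."""
        return float(np.hypot(*(self.end - self.start)))

    @property
    def track_id(self) -> str:
        return self.runs[0].track_id


def noise_sigma2(wmap: WaveletMap, noise_scale: int = 2, mad_const: float = 0.6745) -> float:
    """MAD estimate of the noise standard deviation from the scale-2 row.

    Returns median |C_{i,2}| / 0.6745 over non-edge columns (0.6745 is the
    0.75 quantile of the standard normal, making the estimate consistent for
    Gaussian noise).
    """
    row = wmap.row(noise_scale)
    valid = ~wmap.edge_row(noise_scale)
    if valid.any():
        row = row[valid]
    return float(np.median(np.abs(row)) / mad_const)


def universal_threshold(sigma2: float, N: int, params: ActiveDetectionParams) -> float:
    """delta = r * sigma2 * sqrt(2 ln N) * sqrt(a_tilde / 2)."""
    if N <= 1:
        raise ValueError("N must exceed 1")
    if sigma2 < 0:
        raise ValueError("sigma2 must be non-negative")
    return params.r * sigma2 * np.sqrt(2.0 * np.log(N)) * np.sqrt(params.a_tilde / 2.0)


def classify_active(
    map_x: WaveletMap, map_y: WaveletMap, params: ActiveDetectionParams | None = None
) -> ActiveLabels:
    """Label each time point active/passive from the detection-scale rows.

    Per-axis thresholds are computed from the per-axis noise estimates and the
    shared per-track N = T - 2*floor(a_tilde/2); a point is active when the
    coefficient magnitude exceeds the threshold on at least one axis (or on
    the vector magnitude, with ``axis_combine='norm'``).  The first and last
    floor(a_tilde/2) points are excluded.
    """
    params = params or ActiveDetectionParams()
    if map_x.C.shape != map_y.C.shape:
        raise ValueError("x and y maps must share shape")
    T = map_x.n_times
    ne = params.n_exclude
    N = T - 2 * ne
    if N <= 1:
        raise ValueError(f"track too short for a_tilde={params.a_tilde}: T={T}")

    s2x = noise_sigma2(map_x, params.noise_scale, params.mad_const)
    s2y = noise_sigma2(map_y, params.noise_scale, params.mad_const)
    dx = universal_threshold(s2x, N, params)
    dy = universal_threshold(s2y, N, params)
    ax = np.abs(map_x.row(params.a_tilde))
    ay = np.abs(map_y.row(params.a_tilde))
    if params.axis_combine == "or":
        active = (ax > dx) | (ay > dy)
    else:
        active = np.hypot(ax, ay) > np.hypot(dx, dy)

    states = np.where(active, ACTIVE, PASSIVE).astype(np.int8)
    states[:ne] = EXCLUDED
    states[T - ne:] = EXCLUDED
    return ActiveLabels(
        track_id=map_x.track_id,
        states=states,
        params=params,
        threshold_x=dx,
        threshold_y=dy,
        sigma2_x=s2x,
        sigma2_y=s2y,
    )


def _chord_widths(points: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Perpendicular distances of points from the segment-supporting line a->b.

    Falls back to distances from ``a`` when the chord is degenerate.
    """
    d = b - a
    norm = np.hypot(*d)
    rel = points - a
    if norm == 0.0:
        return np.hypot(rel[:, 0], rel[:, 1])
    return np.abs(rel[:, 0] * d[1] - rel[:, 1] * d[0]) / norm


def extract_runs(labels: ActiveLabels, tr: Trajectory, min_points: int = 2) -> list[RunSegment]:
    """Turn maximal contiguous active stretches into runs.

    Stretches shorter than ``min_points`` time points are dropped (a single
    active point has no chord).
    """
    if labels.states.size != len(tr):
        raise ValueError("labels and trajectory are not aligned")
    active = labels.active_mask.astype(np.int8)
    boundaries = np.diff(np.concatenate([[0], active, [0]]))
    starts = np.flatnonzero(boundaries == 1)
    ends = np.flatnonzero(boundaries == -1) - 1  # inclusive
    xy = tr.xy
    runs = []
    for s, e in zip(starts, ends):
        if e - s + 1 < min_points:
            continue
        p0, p1 = xy[s], xy[e]
        l = float(np.hypot(*(p1 - p0)))
        w_max = float(np.max(_chord_widths(xy[s : e + 1], p0, p1)))
        runs.append(
            RunSegment(
                track_id=tr.track_id,
                start_idx=int(s),
                end_idx=int(e),
                start=p0.copy(),
                end=p1.copy(),
                l=l,
                duration=float((e - s) * tr.dt),
                w_max=w_max,
            )
        )
    return runs


def _turning_angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    """Angle between two direction vectors in [0, 180] degrees.

    Degenerate (zero-length) vectors carry no direction information and are
    assigned angle 0 so that the corridor test alone decides the merge.
    """
    nu, nv = np.hypot(*u), np.hypot(*v)
    if nu == 0.0 or nv == 0.0:
        return 0.0
    c = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def merge_runs_to_flights(
    runs: list[RunSegment],
    tr: Trajectory,
    corridor_factor: float = 1.27,
    corridor_min: float = 0.4,
    max_turn: float = 120.0,
) -> list[Flight]:
    """Greedy time-ordered merging of runs into flights (error-radius method).

    The next run joins the current flight iff (i) the turning angle between
    the consecutive runs' start->end vectors is <= ``max_turn`` degrees and
    (ii) every coordinate point of the candidate run lies within half of
    max(corridor_factor * w_flight, corridor_min) of the line through the
    current flight's start and the candidate run's end, where w_flight is the
    maximum perpendicular width of the current flight's points about its own
    chord.  Every run ends up in exactly one flight; a lone run is a one-run
    flight.
    """
    if not runs:
        return []
    xy = tr.xy
    flights: list[Flight] = []
    current = [runs[0]]

    def flight_points(members: list[RunSegment]) -> np.ndarray:
        return np.concatenate([xy[r.start_idx : r.end_idx + 1] for r in members])

    def corridor_width(members: list[RunSegment]) -> float:
        pts = flight_points(members)
        w = float(np.max(_chord_widths(pts, members[0].start, members[-1].end)))
        return max(corridor_factor * w, corridor_min)

    last_width = corridor_width(current)
    for run in runs[1:]:
        prev = current[-1]
        angle = _turning_angle_deg(prev.end - prev.start, run.end - run.start)
        merged = False
        if angle <= max_turn:
            width = corridor_width(current)
            candidate_pts = xy[run.start_idx : run.end_idx + 1]
            dists = _chord_widths(candidate_pts, current[0].start, run.end)
            if np.all(dists <= width / 2.0):
                current.append(run)
                last_width = width
                merged = True
        if not merged:
            flights.append(Flight(runs=current, corridor_width=last_width))
            current = [run]
            last_width = corridor_width(current)
    flights.append(Flight(runs=current, corridor_width=last_width))
    return flights


def percent_time_active(labels_list) -> float:
    """Pooled percentage of non-excluded time points classified active."""
    labels_list = list(labels_list)
    n_active = sum(lb.n_active for lb in labels_list)
    n_valid = sum(lb.n_valid for lb in labels_list)
    if n_valid == 0:
        raise ValueError("no non-excluded time points")
    return 100.0 * n_active / n_valid


def turning_angles(runs_per_track) -> np.ndarray:
    """Angles (degrees, [0, 180]) between consecutive runs' start->end vectors,
    pooled over tracks; one angle per consecutive run pair within a track."""
    angles = []
    for runs in runs_per_track:
        for a, b in zip(runs, runs[1:]):
            angles.append(_turning_angle_deg(a.end - a.start, b.end - b.start))
    return np.asarray(angles)
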