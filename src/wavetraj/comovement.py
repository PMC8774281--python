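"""Co-movement classification of organelle-cargo track pairs.

Two particles transported together produce wavelet coefficient maps that are
correlated across the whole time-scale plane, because both the fast individual
steps (small scales) and the long-range drift (large scales) are shared.  A
pair is classified *co-moving* when the Pearson correlation between the two
same-axis CWT maps over the pair's temporal overlap exceeds 0.7 on BOTH axes
and the time-averaged center-to-center distance is below 1 µm.  The distance
gate alone cannot reject nearby-but-independent pairs; the multiscale
correlation can.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trajio import TrackSet, Trajectory
from .wavelet import WaveletMap, cwt_trajectory

__all__ = [
    "PairOverlap",
    "PairResult",
    "ZeroVarianceError",
    "find_overlaps",
    "wavelet_correlation",
    "classify_pair",
    "classify_all_pairs",
    "split_by_comovement",
]


class ZeroVarianceError(ValueError):
    """Correlation is undefined: one of the coefficient matrices is constant."""


@dataclass
class PairOverlap:
    """Temporal overlap of one organelle-cargo pair with per-frame distances."""

    lyso_id: str
    cargo_id: str
    start_frame: int  # inclusive, global frame numbers
    end_frame: int    # inclusive
    distances: np.ndarray

    @property
    def n_frames(self) -> int:
        return int(self.end_frame - self.start_frame + 1)

    @property
    def mean_distance(self) -> float:
        return float(np.mean(self.distances))


@dataclass
class PairResult:
    """Co-movement verdict for one pair."""

    lyso_id: str
    cargo_id: str
    px: float
    py: float
    mean_dist: float
    is_comoving: bool
    overlap_start: int
    overlap_end: int


def find_overlaps(
    lyso: TrackSet, cargo: TrackSet, min_overlap: int = 20
) -> list[PairOverlap]:
    """All organelle-cargo pairs overlapping for at least ``min_overlap`` frames.

    Trajectories must be gap-filled (consecutive frames) so that shared frames
    can be indexed directly.  Per-frame center-to-center distances are
    computed over the shared frame interval.
    """
    overlaps = []
    for lt in lyso:
        if not lt.is_gap_free:
            raise ValueError(f"track {lt.track_id!r} has gaps; fill_gaps it first")
        for ct in cargo:
            if not ct.is_gap_free:
                raise ValueError(f"track {ct.track_id!r} has gaps; fill_gaps it first")
            f0 = max(lt.frames[0], ct.frames[0])
            f1 = min(lt.frames[-1], ct.frames[-1])
            n = int(f1 - f0 + 1)
            if n < min_overlap:
                continue
            li = slice(int(f0 - lt.frames[0]), int(f1 - lt.frames[0] + 1))
            ci = slice(int(f0 - ct.frames[0]), int(f1 - ct.frames[0] + 1))
            d = np.hypot(lt.x[li] - ct.x[ci], lt.y[li] - ct.y[ci])
            overlaps.append(
                PairOverlap(
                    lyso_id=lt.track_id,
                    cargo_id=ct.track_id,
                    start_frame=int(f0),
                    end_frame=int(f1),
                    distances=d,
                )
            )
    return overlaps


def wavelet_correlation(
    map_a: WaveletMap, map_b: WaveletMap, cols_a: slice | None = None, cols_b: slice | None = None
) -> float:
    """Pearson correlation of two same-axis CWT maps over overlap columns.

    The overlap submatrices (all scales x overlap times) are flattened and
    correlated; symmetric in its arguments.  Edge-affected columns inside the
    overlap are retained.  Raises :class:`ZeroVarianceError` when either
    submatrix is constant.
    """
    A = map_a.C if cols_a is None else map_a.C[:, cols_a]
    B = map_b.C if cols_b is None else map_b.C[:, cols_b]
    if A.shape != B.shape:
        raise ValueError(f"overlap submatrices differ in shape: {A.shape} vs {B.shape}")
    a = A.ravel()
    b = B.ravel()
    if np.std(a) == 0.0 or np.std(b) == 0.0:
        raise ZeroVarianceError("constant coefficient matrix; correlation undefined")
    return float(np.corrcoef(a, b)[0, 1])


def classify_pair(
    po: PairOverlap,
    lyso_tr: Trajectory,
    cargo_tr: Trajectory,
    lyso_maps: tuple[WaveletMap, WaveletMap],
    cargo_maps: tuple[WaveletMap, WaveletMap],
    corr_thresh: float = 0.7,
    dist_thresh: float = 1.0,
) -> PairResult:
    """Apply the correlation + distance rule to one overlapping pair."""
    li = slice(int(po.start_frame - lyso_tr.frames[0]), int(po.end_frame - lyso_tr.frames[0] + 1))
    ci = slice(int(po.start_frame - cargo_tr.frames[0]), int(po.end_frame - cargo_tr.frames[0] + 1))
    px = wavelet_correlation(lyso_maps[0], cargo_maps[0], li, ci)
    py = wavelet_correlation(lyso_maps[1], cargo_maps[1], li, ci)
    mean_dist = po.mean_distance
    return PairResult(
        lyso_id=po.lyso_id,
        cargo_id=po.cargo_id,
        px=px,
        py=py,
        mean_dist=mean_dist,
        is_comoving=bool(px > corr_thresh and py > corr_thresh and mean_dist < dist_thresh),
        overlap_start=po.start_frame,
        overlap_end=po.end_frame,
    )


def classify_all_pairs(
    lyso: TrackSet,
    cargo: TrackSet,
    scales=None,
    min_overlap: int = 20,
    corr_thresh: float = 0.7,
    dist_thresh: float = 1.0,
    maps: dict | None = None,
) -> list[PairResult]:
    """Convenience driver: overlaps -> CWT maps -> pair classification.

    ``maps`` may hold precomputed ``{track_id: (map_x, map_y)}`` entries
    (e.g. from the segmentation stage) to avoid recomputing transforms.
    Pairs with an undefined correlation (constant map) are skipped.
    """
    maps = dict(maps or {})

    def get_maps(tr: Trajectory):
        if tr.track_id not in maps:
            maps[tr.track_id] = cwt_trajectory(tr, scales=scales)
        return maps[tr.track_id]

    results = []
    for po in find_overlaps(lyso, cargo, min_overlap=min_overlap):
        lt = lyso.get(po.lyso_id)
        ct = cargo.get(po.cargo_id)
        try:
            results.append(
                classify_pair(
                    po, lt, ct, get_maps(lt), get_maps(ct),
                    corr_thresh=corr_thresh, dist_thresh=dist_thresh,
                )
            )
        except ZeroVarianceError:
            continue
    return results


def split_by_comovement(
    lyso: TrackSet, results: list[PairResult]
) -> tuple[TrackSet, TrackSet]:
    """Partition organelle tracks into cargo-bearing and the remainder.

    A track is cargo-bearing iff it is co-moving with at least one cargo
    track; the partition is exhaustive and disjoint.
    """
    bearing_ids = {r.lyso_id for r in results if r.is_comoving}
    bearing = [tr for tr in lyso if tr.track_id in bearing_ids]
    rest = [tr for tr in lyso if tr.track_id not in bearing_ids]
    return (
        TrackSet(cell_id=lyso.cell_id, channel=lyso.channel, trajectories=bearing),
        TrackSet(cell_id=lyso.cell_id, channel=lyso.channel, trajectories=rest),
    )
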