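import numpy as np
import pytest

from wavetraj.trajio import DEFAULT_DT, Trajectory


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def write_table(tmp_path):
    """Write rows of (track_id, frame[, time_s], x_um, y_um) to a CSV file."""

    def _write(rows, header="track_id,frame,time_s,x_um,y_um", name="tracks.csv"):
        path = tmp_path / name
        lines = [header] + [",".join(str(v) for v in row) for row in rows]
        path.write_text("\n".join(lines) + "\n")
        return path

    return _write


def make_traj(x, y=None, track_id="t", frames=None, dt=DEFAULT_DT):
    """Build a gap-free Trajectory from coordinate arrays."""
    x = np.asarray(x, dtype=float)
    y = np.zeros_like(x) if y is None else np.asarray(y, dtype=float)
    frames = np.arange(x.size) if frames is None else np.asarray(frames)
    return Trajectory(track_id=track_id, frames=frames, t=frames * dt, x=x, y=y, dt=dt)


def naive_haar_cwt(s, scales):
    """Independent brute-force CWT oracle: direct double loop over (scale, t0).

    Weights come from explicit interval intersections of each sample cell with
    the two half-supports of the centred Haar kernel; out-of-range samples
    repeat the nearest observed value (edge replication).
    """
    s = np.asarray(s, dtype=float)
    T = s.size
    scales = list(scales)
    out = np.zeros((len(scales), T))
    for i, a in enumerate(scales):
        for t0 in range(T):
            start = t0 - a // 2
            acc = 0.0
            for k in range(a):
                idx = min(max(start + k, 0), T - 1)
                pos = max(0.0, min(k + 1, a / 2) - max(k, 0))
                neg = max(0.0, min(k + 1, a) - max(k, a / 2))
                acc += s[idx] * (pos - neg)
            out[i, t0] = acc
    return out
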