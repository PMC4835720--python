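import numpy as np
import pandas as pd
import pytest

from flynet import MoMSettings, TrajectoryTable


@pytest.fixture
def light_settings():
    """Estimation settings scaled for fast unit tests."""
    def make(seed=0, **kw):
        base = dict(n1=25, n2_iterations=20, n2_subphases=3, n3=300, max_restarts=0, seed=seed)
        base.update(kw)
        return MoMSettings(**base)
    return make


def make_trajectory(positions, body_length=2.5, fps=10.0, classes=None):
    """Build a TrajectoryTable from {individual: [(frame, x, y), ...]}."""
    rows = []
    for ind, pts in positions.items():
        for frame, x, y in pts:
            rows.append((frame, ind, float(x), float(y), body_length))
    df = pd.DataFrame(rows, columns=["frame", "individual", "x", "y", "body_length"])
    return TrajectoryTable(df, fps=fps, classes=classes or {})


def random_trajectory(rng, n_flies, n_frames, gap_prob=0.0, box=30.0, body_length=2.5):
    """Random-walk trajectory with optional tracking gaps."""
    rows = []
    for ind in range(n_flies):
        xy = rng.uniform(-box, box, size=2)
        for frame in range(n_frames):
            xy = xy + rng.normal(0, 1.2, size=2)
            if rng.random() >= gap_prob:
                rows.append((frame, ind, xy[0], xy[1], body_length + 0.1 * ind))
    df = pd.DataFrame(rows, columns=["frame", "individual", "x", "y", "body_length"])
    return TrajectoryTable(df)
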