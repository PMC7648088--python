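import numpy as np
import pandas as pd
import pytest

import fibroswarm as fs


def make_tracks(positions: np.ndarray, dt: float = 15.0) -> pd.DataFrame:
    """Track table from a (n_frames, n_cells, 3) position array."""
    n_frames, n_cells, _ = positions.shape
    track_id = np.repeat(np.arange(n_cells), n_frames)
    frame = np.tile(np.arange(n_frames), n_cells)
    xyz = positions.transpose(1, 0, 2).reshape(-1, 3)
    return pd.DataFrame(
        {
            "track_id": track_id,
            "frame": frame,
            "t_min": frame * dt,
            "x": xyz[:, 0],
            "y": xyz[:, 1],
            "z": xyz[:, 2],
        }
    )


def uniform_motion_tracks(n_cells=50, n_frames=10, step=(1.0, 1.0, 0.0), seed=0):
    """Every cell shares the same displacement vector at every frame.

    Positions are seeded on integers so that, with an exactly representable
    step, every displacement vector is bitwise identical.
    """
    rng = np.random.default_rng(seed)
    p0 = rng.integers(0, 100, (n_cells, 3)).astype(float)
    pos = p0[None] + np.arange(n_frames)[:, None, None] * np.asarray(step)
    return make_tracks(pos)


def isotropic_motion_tracks(n_cells=500, n_frames=10, speed=1.0, seed=0, spread=500.0):
    """I.i.d. isotropic unit-sphere displacement vectors, scaled by speed."""
    rng = np.random.default_rng(seed)
    p0 = rng.uniform(0, spread, (n_cells, 3))
    steps = rng.normal(size=(n_frames - 1, n_cells, 3))
    steps *= speed / np.linalg.norm(steps, axis=-1, keepdims=True)
    pos = np.concatenate([p0[None], p0[None] + np.cumsum(steps, axis=0)])
    return make_tracks(pos)


@pytest.fixture(scope="session")
def translation_pair():
    flow = fs.FlowSpec("translation", dx=5.0, dy=-3.0)
    a, b = fs.advected_pair(flow, shape=(512, 512), seed=3)
    return a, b, flow


@pytest.fixture(scope="session")
def trichrome_fixture():
    return fs.histology_fixture(n_nuclei=12, nucleus_area=80, collagen_area=10_000, seed=2)
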