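import numpy as np
import pytest

from ocubss import SimConfig, simulate
from ocubss.core import GRAD, Recording
from ocubss.forward import make_forward_grid, make_sensor_array


def make_matrix_recording(X, sfreq=600.0, page_spans=None):
    """Wrap a plain channels x samples matrix as a gradiometer Recording."""
    X = np.asarray(X, dtype=float)
    n_ch = X.shape[0]
    assert n_ch % 2 == 0, "need an even channel count (two grads per site)"
    return Recording(
        data=X,
        ch_names=[f"MEG{i:03d}" for i in range(n_ch)],
        ch_types=[GRAD] * n_ch,
        sfreq=sfreq,
        page_spans=page_spans or [(0, X.shape[1])],
        site_ids=np.repeat(np.arange(n_ch // 2), 2),
        pair_ids=np.tile([0, 1], n_ch // 2),
    )


@pytest.fixture(scope="session")
def sensors30():
    return make_sensor_array(30)


@pytest.fixture(scope="session")
def grid30(sensors30):
    return make_forward_grid(sensors30, spacing=0.016)


@pytest.fixture(scope="session")
def sim_small(sensors30, grid30):
    """Two-page, 30-site reading simulation shared across test modules."""
    cfg = SimConfig(n_pages=2, page_duration=15.0, n_sensor_sites=30,
                    n_brain_sources=5, blink_rate=0.25, rng_seed=11)
    rec, truth, _ = simulate(cfg, sensors=sensors30, grid=grid30)
    return cfg, rec, truth


@pytest.fixture(scope="session")
def sim_102(tmp_path_factory):
    """One-minute 102-site simulation for the heavier integration tests."""
    cfg = SimConfig(n_pages=3, page_duration=20.0, n_sensor_sites=102,
                    n_brain_sources=10, rng_seed=7)
    rec, truth, grid = simulate(cfg)
    return cfg, rec, truth, grid
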