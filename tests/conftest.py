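import numpy as np
import pytest

import retinawaves as rw


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def single_wave_movie():
    """One noiseless centred wave at 100 µm/s on a small field."""
    cfg = rw.WaveSimConfig(
        fov_um=600.0,
        px_um=10.0,
        fps=10.0,
        duration_s=20.0,
        local_event_rate_per_min=0.0,
        noise_sd=0.0,
        seed=0,
    )
    event = rw.GroundTruthEvent(
        kind="propagating",
        t0_s=5.0,
        site_xy_um=(305.0, 305.0),  # centre of a pixel
        speed_um_s=100.0,
        footprint_fraction=0.5,
    )
    movie, events = rw.simulate_movie(cfg, events=[event])
    return cfg, movie, events[0]


def make_traces(data, fps=10.0, centroids=None):
    """Wrap a plain array as a TraceMatrix with dummy geometry."""
    data = np.asarray(data, dtype=np.float32)
    n = data.shape[0]
    if centroids is None:
        centroids = np.zeros((n, 2))
    return rw.TraceMatrix(
        traces=data, roi_ids=np.arange(n), fps=fps, roi_centroids_um=centroids
    )


@pytest.fixture()
def traces_factory():
    return make_traces
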