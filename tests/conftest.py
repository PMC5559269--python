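import numpy as np
import pytest

from endopatch import SimParams, analyze_movie, simulate_movie


@pytest.fixture(scope="session")
def wt_params():
    return SimParams(n_events=6, n_frames=100, seed=7)


@pytest.fixture(scope="session")
def wt_movie(wt_params):
    return simulate_movie(wt_params)


@pytest.fixture(scope="session")
def wt_analysis(wt_movie):
    movie, _truth = wt_movie
    return analyze_movie(movie)


@pytest.fixture(scope="session")
def quiet_movie():
    """Noiseless, event-free, fill-free movie: flat background only."""
    params = SimParams(n_events=0, n_frames=5, apply_noise=False,
                       cell_fill_photons=0.0, seed=3)
    return simulate_movie(params)


@pytest.fixture
def disk_frame():
    img = np.zeros((128, 128))
    yy, xx = np.mgrid[0:128, 0:128]
    img[np.hypot(yy - 64, xx - 64) <= 30] = 1.0
    return img
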