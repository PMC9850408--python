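import numpy as np
import pytest

from picamsi import MSIDataset, default_config, simulate_msi, tic_normalize


def grid_coords(w: int, h: int) -> np.ndarray:
    X, Y = np.meshgrid(np.arange(1, w + 1), np.arange(1, h + 1))
    return np.column_stack([X.ravel(), Y.ravel()])


def make_dataset(intensities, mz_axis=None, coords=None) -> MSIDataset:
    intensities = np.asarray(intensities, float)
    n_pix, n_feat = intensities.shape
    if mz_axis is None:
        mz_axis = 100.0 + 10.0 * np.arange(n_feat)
    if coords is None:
        coords = np.column_stack([np.arange(1, n_pix + 1), np.ones(n_pix, int)])
    return MSIDataset(coords=coords, intensities=intensities, mz_axis=mz_axis)


@pytest.fixture
def small_dataset() -> MSIDataset:
    rng = np.random.default_rng(42)
    return make_dataset(rng.gamma(2.0, 5.0, size=(30, 8)))


@pytest.fixture(scope="session")
def sim_pair():
    """Default synthetic scene (seed 0), raw."""
    return simulate_msi(default_config(seed=0))


@pytest.fixture(scope="session")
def sim_normalized(sim_pair):
    dataset, truth = sim_pair
    return tic_normalize(dataset), truth


@pytest.fixture(scope="session")
def noiseless_pair():
    cfg = default_config(seed=3, noise_sigma=0.0)
    return simulate_msi(cfg)
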