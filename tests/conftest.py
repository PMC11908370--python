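import numpy as np
import pytest

from reconparc import SyntheticConfig, VoxelVolume, generate_reconfiguring_dataset


def make_volume(data: np.ndarray, mask: np.ndarray | None = None) -> VoxelVolume:
    """Wrap a raw 4D array (full mask unless given)."""
    data = np.asarray(data, dtype=float)
    if mask is None:
        mask = np.ones(data.shape[:3], dtype=bool)
    return VoxelVolume(data, mask)


@pytest.fixture(scope="session")
def planted_dataset():
    """Two-window planted dataset in the identifiable regime: ROI radii
    within the Gaussian kernel's support, weak private noise."""
    cfg = SyntheticConfig(
        grid_shape=(8, 8, 4),
        n_rois=6,
        n_timepoints=160,
        n_windows=2,
        gaussian_variance=5.0,
        noise_amplitude=0.1,
        reconfigure_fraction=0.3,
        noise_seed=7,
    )
    return generate_reconfiguring_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
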