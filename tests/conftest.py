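import numpy as np
import pytest

from ktpca import (
    PhantomConfig,
    SensitivityMaps,
    apply_coils,
    extract_training,
    make_phantom,
    make_sheared_grid,
    undersample,
)


@pytest.fixture(scope="session")
def small_series():
    """Noiseless 32x32x16 two-coil perfusion series, rank-4 temporal structure."""
    cfg = PhantomConfig(
        n_readout=32, n_pe=32, n_frames=16, n_coils=2,
        snr_db=np.inf, temporal_rank=3, seed=1,
    )
    return make_phantom(cfg)


@pytest.fixture(scope="session")
def small_kt(small_series):
    return apply_coils(small_series)


@pytest.fixture(scope="session")
def small_acq(small_kt):
    """R=4 sheared-grid acquisition with 11 training profiles."""
    pattern = make_sheared_grid(32, 16, 4, 1)
    return {
        "pattern": pattern,
        "undersampled": undersample(small_kt, pattern),
        "training": extract_training(small_kt, 11),
    }


@pytest.fixture(scope="session")
def true_maps(small_series):
    return SensitivityMaps(
        S=small_series.sensitivities, mask=small_series.object_mask
    )
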