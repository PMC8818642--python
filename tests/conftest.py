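import numpy as np
import pytest

from nanometrics.loc_io import LocalizationTable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_table():
    """Three localizations with known values (nm)."""
    return LocalizationTable(
        frame=np.array([0, 5, 2]),
        x_nm=np.array([100.0, 250.5, 400.25]),
        y_nm=np.array([50.0, 60.0, 70.5]),
        precision_nm=np.array([12.0, 18.0, 25.0]),
    )


def random_table(rng, n=1000, extent_nm=1000.0, precision_range=(5.0, 80.0)):
    return LocalizationTable(
        frame=rng.integers(0, 1000, n),
        x_nm=rng.uniform(0, extent_nm, n),
        y_nm=rng.uniform(0, extent_nm, n),
        precision_nm=rng.uniform(*precision_range, n),
    )
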