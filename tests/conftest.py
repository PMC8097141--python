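import pytest

from thetanet.database import GridSpec, build_database, derive_bands


@pytest.fixture(scope="session")
def small_grid():
    """3^4 grid bracketing the default cell (all features defined)."""
    return GridSpec(a=(0.0006, 0.0012, 0.0024),
                    b=(2.0, 3.0, 4.0),
                    d=(5.0, 10.0, 15.0),
                    k_low=(0.07, 0.1, 0.14))


@pytest.fixture(scope="session")
def small_db(small_grid):
    return build_database(small_grid)


@pytest.fixture(scope="session")
def small_bands(small_db):
    return derive_bands(small_db)
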