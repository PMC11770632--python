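import numpy as np
import pytest

from delscreen import del_decode, synthetic_del


@pytest.fixture(scope="session")
def small_library():
    """3x3 two-cycle library, no planted truth."""
    return synthetic_del.generate_library([3, 3], 2, seed=1)


@pytest.fixture(scope="session")
def planted_library():
    """10x10 two-cycle library with one competitive motif, one matrix binder."""
    lib = synthetic_del.generate_library([10, 10], 2, seed=5)
    return synthetic_del.plant_binders(
        lib, n_competitive=1, n_noncompetitive=1, n_matrix=2, seed=6
    )


@pytest.fixture(scope="session")
def screen_library():
    """50x50 two-cycle screen with planted binders of every role."""
    lib = synthetic_del.generate_library([50, 50], 2, seed=101)
    return synthetic_del.plant_binders(
        lib, n_competitive=3, n_noncompetitive=2, n_matrix=10, seed=102
    )


@pytest.fixture(scope="session")
def schema(planted_library):
    return del_decode.TagSchema.from_libraries([planted_library])


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
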