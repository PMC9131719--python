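import numpy as np
import pytest

from cyclopean import GridSpec, IOCSFParams, QuickIOCSF


@pytest.fixture(scope="session")
def example_params() -> IOCSFParams:
    """A mid-range observer: peak gain 10 at 1.5 c/d, 3-octave bandwidth."""
    return IOCSFParams(gamma_max=10.0, f_max=1.5, beta_octaves=3.0, trunc_delta=0.5)


@pytest.fixture(scope="session")
def tiny_grid() -> GridSpec:
    """A 3 x 3 x 2 x 2 lattice small enough for exhaustive enumeration."""
    return GridSpec(
        gamma_max_bounds=(5.0, 40.0), gamma_max_n=3,
        f_max_bounds=(1.0, 3.0), f_max_n=3,
        beta_bounds=(2.0, 4.0), beta_n=2,
        delta_bounds=(0.2, 0.8), delta_n=2,
    )


@pytest.fixture(scope="session")
def default_engine() -> QuickIOCSF:
    """One shared default engine: the likelihood tables are expensive."""
    return QuickIOCSF()
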