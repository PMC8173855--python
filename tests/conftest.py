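import numpy as np
import pytest

from cardiotwist.phantom import PhantomSpec


@pytest.fixture(scope="session")
def mouse_spec():
    """Default mouse phantom (full deformation + rotation)."""
    return PhantomSpec.mouse()


@pytest.fixture(scope="session")
def rotation_only_spec():
    """Mouse phantom with pure twist (no strain deformation)."""
    return PhantomSpec.mouse(
        circ_shortening_frac=0.0, radial_thickening_frac=0.0, long_shortening_frac=0.0
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
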