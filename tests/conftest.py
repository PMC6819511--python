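import numpy as np
import pytest

from strokeconn.connectome import ROI, Parcellation
from strokeconn.phantom import Bundle, PhantomSpec, make_phantom


@pytest.fixture
def toy_parcellation():
    """4-ROI unit-surface parcellation with 1<->3, 2<->4 homotopic pairs."""
    return Parcellation((
        ROI(1, "a_L", "L", "cortical", 1.0, "SMA", 3),
        ROI(2, "b_L", "L", "cortical", 1.0, "DMN", 4),
        ROI(3, "a_R", "R", "cortical", 1.0, "SMA", 1),
        ROI(4, "b_R", "R", "cortical", 1.0, "DMN", 2),
    ))


@pytest.fixture
def two_bundle_phantom():
    """Two parallel straight bundles along +x with ROI pairs (1,2) and (3,4)."""
    spec = PhantomSpec(
        grid_dims=(40, 20, 11),
        bundles=(
            Bundle(1, 2, ((4.0, 5.0, 5.0), (35.0, 5.0, 5.0)), radius=1.5),
            Bundle(3, 4, ((4.0, 14.0, 5.0), (35.0, 14.0, 5.0)), radius=1.5),
        ),
        rng_seed=0,
    )
    return spec, make_phantom(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
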