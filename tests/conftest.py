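import numpy as np
import pytest

from emgsim.phantom import PhantomSpec, build_phantom


@pytest.fixture(scope="session")
def phantom_rest():
    """Coarse (2 mm mesh) resting-state phantom shared across tests."""
    return build_phantom(PhantomSpec(state="rest"))


@pytest.fixture(scope="session")
def phantom_fine_states():
    """Finer (1 mm mesh) abduction/flexion phantoms for FEM comparisons."""
    return {
        state: build_phantom(PhantomSpec(state=state, mesh_h_mm=1.0))
        for state in ("abduction", "flexion")
    }


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
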