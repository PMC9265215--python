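import numpy as np
import pytest

from rtmc import SceneSpec, make_highpass_kernel, render_scene_detailed


@pytest.fixture(scope="session")
def kernel10():
    """Default high-pass kernel for 10-px neurons."""
    return make_highpass_kernel(neuron_diameter=10)


@pytest.fixture(scope="session")
def small_spec():
    """A small, quick-to-render scene used by most unit tests."""
    return SceneSpec(height=96, width=96, n_neurons=4, vessel_count=2, seed=42)


@pytest.fixture(scope="session")
def small_scene(small_spec):
    return render_scene_detailed(small_spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
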