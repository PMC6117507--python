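import numpy as np
import pytest

from saltrank.synthetic import SceneSpec, render_scene


@pytest.fixture(scope="session")
def default_scene():
    """One default noisy scene with a clear treatment shift."""
    spec = SceneSpec(shift=0.2, seed=11)
    cube, truth = render_scene(spec)
    return spec, cube, truth


@pytest.fixture(scope="session")
def clean_scene():
    """Noise- and illumination-free scene: pixels lie exactly on the
    endmember segment and the planted pure pixels are the extremes."""
    spec = SceneSpec(shift=0.2, seed=7, illum_sd=0.0, noise_sd=0.0)
    cube, truth = render_scene(spec)
    return spec, cube, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
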