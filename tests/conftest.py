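import numpy as np
import pytest

from qdcount import SceneSpec, simulate_scene


@pytest.fixture(scope="session")
def default_scene():
    """The package's default study scene: 20 cells, NB(mean 100) counts,
    autofluorescence on, peak S/N ≈ 10. Shared because it is the most
    expensive fixture in the suite."""
    spec = SceneSpec(seed=5)
    stack, truth = simulate_scene(spec)
    return spec, stack, truth


def gaussian_patch(shape, cx, cy, sigma=1.1, amplitude=100.0, offset=0.0):
    """Isotropic 2D Gaussian sampled at pixel centers."""
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return offset + amplitude * np.exp(
        -((xx - cx) ** 2 + (yy - cy) ** 2) / (2.0 * sigma**2)
    )
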