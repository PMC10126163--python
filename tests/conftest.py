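import numpy as np
import pytest

from fractometry import ComplexField, FractalFieldSpec, SphereSpec, fractal_phantom, sphere_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def bump_field():
    """Smooth isolated Gaussian phase bump on a unit-amplitude background."""
    n = 128
    yy, xx = np.mgrid[0:n, 0:n]
    s = 10.0
    phi = 1.5 * np.exp(-(((xx - n / 2) ** 2 + (yy - n / 2) ** 2) / (2 * s * s)))
    return ComplexField(
        amplitude=np.ones((n, n)), phase=phi, wavelength_um=1.064, pixel_um=0.2
    )


@pytest.fixture
def sphere_field():
    return sphere_phantom(
        SphereSpec(radius_um=3.0, delta_n=0.01, pixel_um=0.2, grid_size=128)
    )


@pytest.fixture
def fractal_field():
    return fractal_phantom(FractalFieldSpec(beta=2.0, grid_size=64, seed=17))
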