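import numpy as np
import pytest

from haemopost.fields import FluidProperties, TimeGrid
from haemopost.synthetic import (
    PhantomSpec,
    WomersleySpec,
    cylinder_mesh,
    helical_cylinder_field,
    two_lumen_phantom,
    womersley_field,
)


@pytest.fixture(scope="session")
def small_cylinder():
    """Coarse z-aligned cylinder for geometry/plumbing tests."""
    return cylinder_mesh(radius=0.01, length=0.02, n_rings=4, n_theta=16, n_axial=3)


@pytest.fixture(scope="session")
def womersley_spec():
    """Moderate-alpha pulsatile pipe flow resolved finely enough near the
    wall that the linear-element shear extraction meets a 5% error bound
    (resolution fixed from a mesh-convergence study, see docs/methods.md)."""
    return WomersleySpec(
        radius=0.004,
        period=1.0,
        harmonic_amplitudes=np.array([20.0, 8.0]),
        harmonic_phases=np.array([0.0, 0.6]),
        n_rings=14,
        n_theta=96,
    )


@pytest.fixture(scope="session")
def womersley(womersley_spec):
    return womersley_field(womersley_spec, 16)


@pytest.fixture(scope="session")
def womersley_fluid(womersley_spec):
    return FluidProperties(density=womersley_spec.density, mu=womersley_spec.viscosity)


@pytest.fixture(scope="session")
def poiseuille():
    spec = WomersleySpec(
        radius=0.004,
        period=1.0,
        harmonic_amplitudes=np.array([20.0]),
        harmonic_phases=np.array([0.0]),
        n_rings=10,
        n_theta=90,
    )
    return womersley_field(spec, 8)


@pytest.fixture(scope="session")
def phantom():
    return two_lumen_phantom(PhantomSpec(n_rings=3, n_theta=12, n_axial=6, n_snapshots=16))


@pytest.fixture(scope="session")
def helical(small_cylinder):
    """Solid-body rotation Omega = 10 rad/s plus axial drift W = 0.5 m/s."""
    grid = TimeGrid.over_cycle(1.0, 8)
    return helical_cylinder_field(10.0, 0.5, small_cylinder, grid)
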