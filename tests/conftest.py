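import numpy as np
import pytest

from fmrisr.io import FunctionalSeries, TaskDesign
from fmrisr.phantom import PhantomSpec, default_task_design, make_functional_series


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20_240_101)


@pytest.fixture(scope="session")
def small_design() -> TaskDesign:
    """Two-task alternating design on a short series (300 frames, TR 0.5)."""
    return default_task_design(n_volumes=300, tr=0.5)


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    """Cheap phantom: 32x32 HR grid, 300 frames."""
    return PhantomSpec(
        grid_hr=32,
        n_volumes=300,
        region_a_geometry=_ellipse((13.0, 16.0)),
        region_b_geometry=_ellipse((19.0, 16.0)),
        overlap_fraction=0.2,
        seed=7,
    )


def _ellipse(center):
    from fmrisr.phantom import EllipseGeometry

    return EllipseGeometry(center=center, semi_axes=(4.0, 3.0))


@pytest.fixture(scope="session")
def small_phantom(small_spec, small_design):
    return make_functional_series(small_spec, small_design)


def random_series(rng, nx=6, ny=5, nt=40, tr=0.5) -> FunctionalSeries:
    return FunctionalSeries(
        data=rng.normal(100.0, 5.0, size=(nx, ny, 1, nt)), tr=tr
    )
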