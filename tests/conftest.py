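import numpy as np
import pytest

from facetfit.io import bundled_habit_path, load_bundled_habit, load_prior
from facetfit.habit import CrystalConfiguration, CrystalHabit
from facetfit.projector import ImageGeometry


@pytest.fixture(scope="session")
def cube_habit():
    return load_bundled_habit("cube")


@pytest.fixture(scope="session")
def octa_habit():
    return load_bundled_habit("octa")


@pytest.fixture(scope="session")
def lga_habit():
    return load_bundled_habit("alpha_lga")


@pytest.fixture(scope="session")
def lga_prior():
    return load_prior(bundled_habit_path("alpha_lga"))


@pytest.fixture(scope="session")
def cube_prior():
    return load_prior(bundled_habit_path("cube"))


@pytest.fixture
def geom():
    return ImageGeometry(width=400, height=400, scale=100.0)


def random_bounded_habit(rng, n_extra=4):
    """Random bounded half-space system: paired +/- directions plus a few
    free ones (pairing guarantees the normals positively span R^3)."""
    k = rng.integers(3, 6)
    dirs = rng.normal(size=(k, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    normals = np.vstack([dirs, -dirs, rng.normal(size=(n_extra, 3))])
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)
    return CrystalHabit.from_normals(f"random{rng.integers(1 << 30)}", normals)


def random_config(habit, rng, d_range=(0.6, 1.4), rotate=True):
    d = rng.uniform(*d_range, habit.n_faces)
    rot = rng.normal(0, 0.4, 3) if rotate else np.zeros(3)
    return CrystalConfiguration(habit, d, rotation=rot, refractive_index=1.7)
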