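import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from beehoming.compare import potential_for_model
from beehoming.render import build_view_grid
from beehoming.scene import build_scene

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

# study-scale defaults used by the slower integration/acceptance fixtures:
# 2 deg/px panoramas on a 4-cm lattice at 6 cm flight altitude
DEG_PER_PX = 2.0
SPACING = 4.0


@pytest.fixture(scope="session")
def hab_scene():
    return build_scene(condition="0/0")


@pytest.fixture(scope="session")
def hab_grid6(hab_scene):
    return build_view_grid(
        hab_scene, spacing=SPACING, altitude=6.0, deg_per_px=DEG_PER_PX
    )


@pytest.fixture(scope="session")
def hab_grid15(hab_scene):
    return build_view_grid(
        hab_scene, spacing=SPACING, altitude=15.0, deg_per_px=DEG_PER_PX
    )


@pytest.fixture(scope="session")
def _potential_cache():
    return {}


@pytest.fixture(scope="session")
def hab_potential(hab_scene, hab_grid6, _potential_cache):
    """Cached habituation potentials per model name (6 cm altitude)."""

    def get(model: str):
        key = ("hab6", model)
        if key not in _potential_cache:
            _potential_cache[key] = potential_for_model(
                model, hab_scene, hab_scene, hab_grid6
            )
        return _potential_cache[key]

    return get


@pytest.fixture(scope="session")
def coarse_grid(hab_scene):
    """A very coarse rendered grid for fast structural tests."""
    return build_view_grid(
        hab_scene, spacing=24.0, altitude=6.0, deg_per_px=DEG_PER_PX
    )


@pytest.fixture(scope="session")
def bowl_field():
    """Quadratic-bowl gradient field on the masked 4-cm disc lattice."""
    from beehoming.homing_models import VectorField

    r_disc = 74.0
    coords = np.arange(-18, 19) * 4.0
    xx, yy = np.meshgrid(coords, coords, indexing="ij")
    valid = np.hypot(xx, yy) <= r_disc
    g = (xx**2 + yy**2) / r_disc**2
    hv = np.stack([-2 * xx / r_disc**2, -2 * yy / r_disc**2], axis=-1)
    return VectorField(coords, coords.copy(), hv, valid), g
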