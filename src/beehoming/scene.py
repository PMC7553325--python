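"""Arena geometry, cue constellations and cue-conflict conditions.

The flight arena is a closed cylinder. Two independent constellations of
visual cues indicate the nest location: three small dark cylinders on a ring
around the nest hole, and three dark vertical stripes on the rotatable part
of the arena wall. A test condition rigidly rotates each constellation about
the arena centre by its own angle (``theta_cyl``, ``theta_str``), so each
constellation points at its own *fictive nest*. The directed angle between
the two fictive nests is the cue-conflict angle.

All angles are degrees, positive counter-clockwise seen from above, azimuth
0 along +x. Lengths are centimetres. A condition label is parsed as
``"theta_cyl/theta_str"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "ArenaGeometry",
    "CylinderConstellation",
    "StripePattern",
    "ConflictCondition",
    "Scene",
    "SceneConfigError",
    "build_scene",
    "fictive_nests",
    "condition_equivalence_classes",
    "scene_from_config",
    "load_config",
]


class SceneConfigError(ValueError):
    """A scene or condition violates a geometric invariant."""


def _rot2d(deg: float) -> np.ndarray:
    a = math.radians(deg)
    return np.array([[math.cos(a), -math.sin(a)], [math.sin(a), math.cos(a)]])


def wrap_angle(deg: float) -> float:
    """Map an angle to the directed interval (-180, 180]."""
    a = (float(deg) + 180.0) % 360.0 - 180.0
    return 180.0 if a == -180.0 else a


@dataclass(frozen=True)
class ArenaGeometry:
    """Cylindrical arena with a rotatable lower wall and fixed upper rim."""

    radius: float = 75.0
    height: float = 90.0
    rotatable_wall_height: float = 80.0
    fixed_wall_height: float = 10.0
    nest_radial_distance: float = 30.0
    nest_azimuth: float = 0.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise SceneConfigError("arena radius must be positive")
        if not math.isclose(
            self.rotatable_wall_height + self.fixed_wall_height, self.height
        ):
            raise SceneConfigError(
                "rotatable_wall_height + fixed_wall_height must equal height"
            )
        if self.nest_radial_distance >= self.radius - 12.0:
            raise SceneConfigError(
                "nest too close to the wall: |nest_position| must be < radius - 12"
            )

    @property
    def nest_position(self) -> np.ndarray:
        return self.nest_radial_distance * np.array(
            [math.cos(math.radians(self.nest_azimuth)),
             math.sin(math.radians(self.nest_azimuth))]
        )


@dataclass(frozen=True)
class CylinderConstellation:
    """Three upright cylinders on a ring around the (possibly fictive) nest.

    ``centres`` are absolute arena-frame footprint centres after any
    condition rotation has been applied.
    """

    ring_radius: float = 10.0
    cylinder_height: float = 15.0
    cylinder_radius: float = 1.0
    phase_angles: tuple[float, float, float] = (30.0, 150.0, 270.0)
    centres: np.ndarray = field(default=None)  # type: ignore[assignment]

    def validate(self, geometry: ArenaGeometry) -> None:
        c = np.asarray(self.centres, dtype=float)
        if c.shape != (3, 2):
            raise SceneConfigError("exactly 3 cylinders are required")
        d = np.linalg.norm(c[:, None, :] - c[None, :, :], axis=-1)
        iu = np.triu_indices(3, 1)
        if np.any(d[iu] < 2.0 * self.cylinder_radius):
            raise SceneConfigError("cylinders overlap")
        if np.any(np.linalg.norm(c, axis=1) + self.cylinder_radius > geometry.radius):
            raise SceneConfigError("cylinder footprint outside arena")


@dataclass(frozen=True)
class StripePattern:
    """Three dark stripes on the rotatable wall, asymmetric about the nest.

    ``centre_azimuths`` are the habituation-pose wall azimuths of the stripe
    centres; ``wall_rotation`` is the rigid rotation applied in a test.
    """

    stripe_width: float = 12.0
    stripe_height: float = 80.0
    centre_azimuths: tuple[float, float, float] = (-25.0, 25.0, 135.0)
    wall_rotation: float = 0.0

    def half_width_deg(self, wall_radius: float) -> float:
        # angular half-width of the flat chord of the stripe seen from centre
        return math.degrees(math.asin(self.stripe_width / (2.0 * wall_radius)))

    def azimuths(self) -> np.ndarray:
        """Stripe centre azimuths in the current (rotated) pose."""
        return np.array([wrap_angle(a + self.wall_rotation)
                         for a in self.centre_azimuths])

    def validate(self, geometry: ArenaGeometry) -> None:
        if self.stripe_height > geometry.rotatable_wall_height:
            raise SceneConfigError("stripes must lie on the rotatable wall only")
        hw = self.half_width_deg(geometry.radius)
        az = self.azimuths()
        for i in range(3):
            for j in range(i + 1, 3):
                gap = abs(wrap_angle(az[i] - az[j]))
                if gap < 2.0 * hw:
                    raise SceneConfigError("stripes overlap on the wall")


@dataclass(frozen=True)
class ConflictCondition:
    """A cue-conflict test condition ``theta_cyl/theta_str``."""

    theta_cyl: float = 0.0
    theta_str: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        if not (math.isfinite(self.theta_cyl) and math.isfinite(self.theta_str)):
            raise SceneConfigError("condition angles must be finite")
        if not self.label:
            object.__setattr__(
                self, "label", f"{self.theta_cyl:+g}/{self.theta_str:+g}"
            )

    @classmethod
    def from_label(cls, label: str) -> "ConflictCondition":
        """Parse ``"theta_cyl/theta_str"`` (e.g. ``"-45/-90"``)."""
        parts = label.split("/")
        if len(parts) != 2:
            raise SceneConfigError(f"cannot parse condition label {label!r}")
        return cls(theta_cyl=float(parts[0]), theta_str=float(parts[1]), label=label)

    @property
    def conflict(self) -> float:
        """Directed conflict angle (cylinders minus stripes), in (-180, 180]."""
        return wrap_angle(self.theta_cyl - self.theta_str)


DEFAULT_BRIGHTNESS: Mapping[str, float] = {
    "wall": 1.0,
    "stripe": 0.0,
    "cylinder": 0.0,
    "floor": 0.5,
    "ceiling": 1.0,
}


@dataclass(frozen=True)
class Scene:
    """Pure geometric description of one arena arrangement.

    The nest hole and the foraging-chamber entrance are deliberately not
    part of the scene, so conditions that differ only by a global rotation
    render identically.
    """

    geometry: ArenaGeometry
    cylinders: CylinderConstellation
    stripes: StripePattern
    condition: ConflictCondition
    surface_brightness: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BRIGHTNESS)
    )

    @property
    def nest(self) -> np.ndarray:
        return self.geometry.nest_position


def fictive_nests(
    condition: ConflictCondition, geometry: ArenaGeometry | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Positions indicated as 'nest' by the cylinders and by the stripes.

    Each is the habituation nest position rotated about the arena centre by
    the constellation's condition angle.
    """
    geometry = geometry if geometry is not None else ArenaGeometry()
    nest = geometry.nest_position
    return _rot2d(condition.theta_cyl) @ nest, _rot2d(condition.theta_str) @ nest


def build_scene(
    geometry: ArenaGeometry | None = None,
    condition: ConflictCondition | str = "0/0",
    cylinders: CylinderConstellation | None = None,
    stripes: StripePattern | None = None,
    surface_brightness: Mapping[str, float] | None = None,
) -> Scene:
    """Assemble and validate the arena scene for one condition.

    The cylinder constellation is rotated rigidly about the arena centre by
    ``theta_cyl`` and the wall stripe pattern by ``theta_str``.
    """
    geometry = geometry if geometry is not None else ArenaGeometry()
    if isinstance(condition, str):
        condition = ConflictCondition.from_label(condition)
    cylinders = cylinders if cylinders is not None else CylinderConstellation()
    stripes = stripes if stripes is not None else StripePattern()

    nest = geometry.nest_position
    phases = np.radians(np.asarray(cylinders.phase_angles, dtype=float))
    local = nest[None, :] + cylinders.ring_radius * np.stack(
        [np.cos(phases), np.sin(phases)], axis=1
    )
    centres = (_rot2d(condition.theta_cyl) @ local.T).T
    cylinders = replace(cylinders, centres=centres)
    cylinders.validate(geometry)

    stripes = replace(
        stripes, wall_rotation=stripes.wall_rotation + condition.theta_str
    )
    stripes.validate(geometry)

    brightness = dict(DEFAULT_BRIGHTNESS)
    if surface_brightness:
        brightness.update(surface_brightness)
    return Scene(
        geometry=geometry,
        cylinders=cylinders,
        stripes=stripes,
        condition=condition,
        surface_brightness=brightness,
    )


def condition_equivalence_classes(
    conditions: Sequence[ConflictCondition | str],
) -> list[list[ConflictCondition]]:
    """Partition conditions into visually-identical classes.

    Because neither the nest hole nor the arena entrance is modelled, two
    conditions render as globally rotated copies of each other exactly when
    their directed conflict angles agree; each returned class lists its
    conditions with the first element acting as representative.
    """
    parsed = [
        ConflictCondition.from_label(c) if isinstance(c, str) else c
        for c in conditions
    ]
    classes: dict[float, list[ConflictCondition]] = {}
    for cond in parsed:
        key = round(cond.conflict, 9)
        classes.setdefault(key, []).append(cond)
    return list(classes.values())


def load_config(path) -> dict:
    """Read a YAML/JSON arena configuration file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def scene_from_config(cfg: Mapping) -> Scene:
    """Build a Scene from a nested config mapping (see package docs)."""
    arena = cfg.get("arena", {})
    wall_split = arena.get("wall_split", 80.0)
    height = arena.get("height", 90.0)
    geometry = ArenaGeometry(
        radius=arena.get("radius", 75.0),
        height=height,
        rotatable_wall_height=wall_split,
        fixed_wall_height=height - wall_split,
        nest_radial_distance=arena.get("nest_r", 30.0),
        nest_azimuth=arena.get("nest_azimuth", 0.0),
    )
    cyl = cfg.get("cylinders", {})
    cylinders = CylinderConstellation(
        ring_radius=cyl.get("ring_radius", 10.0),
        cylinder_height=cyl.get("height", 15.0),
        cylinder_radius=cyl.get("radius", 1.0),
        phase_angles=tuple(cyl.get("phases", (30.0, 150.0, 270.0))),
    )
    st = cfg.get("stripes", {})
    stripes = StripePattern(
        stripe_width=st.get("width", 12.0),
        stripe_height=st.get("height", 80.0),
        centre_azimuths=tuple(st.get("azimuths", (-25.0, 25.0, 135.0))),
    )
    br = cfg.get("brightness", {})
    brightness = {"floor": br.get("floor", 0.5), "ceiling": br.get("ceiling", 1.0)}
    cond_cfg = cfg.get("condition", {})
    condition = ConflictCondition(
        theta_cyl=cond_cfg.get("theta_cyl", 0.0),
        theta_str=cond_cfg.get("theta_str", 0.0),
    )
    return build_scene(geometry, condition, cylinders, stripes, brightness)
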