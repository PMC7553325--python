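"""Equirectangular panoramic rendering of the arena by ray casting.

Each pixel of a panorama corresponds to one viewing direction on the unit
sphere (azimuth u, elevation v; pixel centres). A single ray per pixel is
intersected with the arena wall, floor, ceiling and the three cue cylinders
(capped side surfaces plus top discs); the nearest hit determines both the
pixel brightness and the distance behind it. Rendering is deliberately flat
(no shading, texture or anti-aliasing), matching the simplified geometry of
the modelled set-up.

Images are stored as ``(n_v, n_u)`` arrays with row 0 at elevation -90
(down) and column 0 at azimuth -180 relative to the view orientation; the
orientation maps to the central column. The azimuth axis wraps around.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .scene import Scene, wrap_angle

__all__ = [
    "PanoramicView",
    "NearnessMap",
    "CwNView",
    "ViewGrid",
    "PoseError",
    "render_panorama",
    "michelson_contrast",
    "contrast_weighted_nearness",
    "rotate_view",
    "build_view_grid",
]

_EPS = 1e-9


class PoseError(ValueError):
    """Requested viewpoint lies outside the arena or inside an object."""


@dataclass(frozen=True)
class PanoramicView:
    """Equirectangular brightness panorama with its acquisition pose."""

    brightness: np.ndarray  # (n_v, n_u), values in [0, 1]
    position: np.ndarray  # (3,) cm
    orientation: float  # deg, world azimuth of the centre column
    deg_per_px: float = 1.0

    @property
    def n_u(self) -> int:
        return self.brightness.shape[1]

    @property
    def n_v(self) -> int:
        return self.brightness.shape[0]


@dataclass(frozen=True)
class NearnessMap:
    """Per-pixel distance to the nearest surface; nearness is its inverse."""

    distance: np.ndarray  # (n_v, n_u) cm, finite and positive
    position: np.ndarray
    orientation: float
    deg_per_px: float = 1.0

    @property
    def nearness(self) -> np.ndarray:
        return 1.0 / self.distance


@dataclass(frozen=True)
class CwNView:
    """Michelson contrast weighted by nearness (cm^-1); non-negative."""

    values: np.ndarray
    position: np.ndarray
    orientation: float
    deg_per_px: float = 1.0

    @property
    def n_u(self) -> int:
        return self.values.shape[1]

    @property
    def n_v(self) -> int:
        return self.values.shape[0]


def _pixel_angles(deg_per_px: float) -> tuple[np.ndarray, np.ndarray]:
    n_u = int(round(360.0 / deg_per_px))
    n_v = int(round(180.0 / deg_per_px))
    az = -180.0 + (np.arange(n_u) + 0.5) * deg_per_px
    el = -90.0 + (np.arange(n_v) + 0.5) * deg_per_px
    return az, el


def render_panorama(
    scene: Scene,
    position,
    orientation: float = 0.0,
    deg_per_px: float = 1.0,
) -> tuple[PanoramicView, NearnessMap]:
    """Ray-cast one panoramic brightness image and its distance map.

    Parameters
    ----------
    scene
        Arena arrangement to render.
    position
        Eye position ``(x, y, z)`` in cm; must lie inside the arena and
        outside every cue cylinder.
    orientation
        World azimuth (deg) mapped to the image centre column.
    deg_per_px
        Angular resolution; 1 gives 360x180 images, 2 gives 180x90.
    """
    p = np.asarray(position, dtype=float)
    geom = scene.geometry
    if np.hypot(p[0], p[1]) >= geom.radius:
        raise PoseError(f"position {p[:2]} outside the arena wall")
    if not (0.0 < p[2] < geom.height):
        raise PoseError(f"altitude {p[2]} outside (0, {geom.height})")
    cyl = scene.cylinders
    centres = np.asarray(cyl.centres, dtype=float)
    if p[2] < cyl.cylinder_height:
        d2 = np.hypot(centres[:, 0] - p[0], centres[:, 1] - p[1])
        if np.any(d2 <= cyl.cylinder_radius):
            raise PoseError(f"position {p[:2]} inside a cue cylinder")

    az, el = _pixel_angles(deg_per_px)
    psi = np.radians(orientation + az)[None, :]  # world azimuth per column
    elev = np.radians(el)[:, None]
    cos_el = np.cos(elev)
    dx = cos_el * np.cos(psi)
    dy = cos_el * np.sin(psi)
    dz = np.sin(elev) * np.ones_like(psi)

    shape = dx.shape
    t_best = np.full(shape, np.inf)
    bright = np.zeros(shape)
    sb = scene.surface_brightness

    # arena wall (infinite cylinder; z-validity implied by floor/ceiling hits)
    a = dx * dx + dy * dy
    b = 2.0 * (p[0] * dx + p[1] * dy)
    c = p[0] * p[0] + p[1] * p[1] - geom.radius**2
    disc = b * b - 4.0 * a * c
    safe_a = np.where(a > _EPS, a, 1.0)
    t_wall = np.where(
        a > _EPS, (-b + np.sqrt(np.maximum(disc, 0.0))) / (2.0 * safe_a), np.inf
    )
    zw = p[2] + t_wall * dz
    hit = (t_wall > _EPS) & (zw >= -_EPS) & (zw <= geom.height + _EPS)
    wall_az = np.degrees(np.arctan2(p[1] + t_wall * dy, p[0] + t_wall * dx))
    stripe_hw = scene.stripes.half_width_deg(geom.radius)
    on_stripe = np.zeros(shape, dtype=bool)
    for centre in scene.stripes.azimuths():
        dang = (wall_az - centre + 180.0) % 360.0 - 180.0
        on_stripe |= np.abs(dang) <= stripe_hw
    on_stripe &= zw <= scene.stripes.stripe_height
    wall_brightness = np.where(on_stripe, sb["stripe"], sb["wall"])
    upd = hit & (t_wall < t_best)
    t_best = np.where(upd, t_wall, t_best)
    bright = np.where(upd, wall_brightness, bright)

    # floor and ceiling
    for z_plane, key in ((0.0, "floor"), (geom.height, "ceiling")):
        denom = np.where(np.abs(dz) > _EPS, dz, 1.0)
        t_pl = np.where(np.abs(dz) > _EPS, (z_plane - p[2]) / denom, np.inf)
        hit = t_pl > _EPS
        upd = hit & (t_pl < t_best)
        t_best = np.where(upd, t_pl, t_best)
        bright = np.where(upd, sb[key], bright)

    # cue cylinders: capped sides and top discs
    r2 = cyl.cylinder_radius**2
    h_cyl = cyl.cylinder_height
    for cx, cy in centres:
        ox, oy = p[0] - cx, p[1] - cy
        b2 = 2.0 * (ox * dx + oy * dy)
        c2 = ox * ox + oy * oy - r2
        disc2 = b2 * b2 - 4.0 * a * c2
        ok = (disc2 > 0.0) & (a > _EPS)
        sq = np.sqrt(np.maximum(disc2, 0.0))
        t1 = np.where(ok, (-b2 - sq) / (2.0 * safe_a), np.inf)
        z1 = p[2] + t1 * dz
        side = ok & (t1 > _EPS) & (z1 >= 0.0) & (z1 <= h_cyl)
        upd = side & (t1 < t_best)
        t_best = np.where(upd, t1, t_best)
        bright = np.where(upd, sb["cylinder"], bright)

        denom = np.where(np.abs(dz) > _EPS, dz, 1.0)
        t_top = np.where(np.abs(dz) > _EPS, (h_cyl - p[2]) / denom, np.inf)
        hx = p[0] + t_top * dx - cx
        hy = p[1] + t_top * dy - cy
        top = (t_top > _EPS) & (hx * hx + hy * hy <= r2)
        upd = top & (t_top < t_best)
        t_best = np.where(upd, t_top, t_best)
        bright = np.where(upd, sb["cylinder"], bright)

    if not np.all(np.isfinite(t_best)):  # pragma: no cover - closed arena
        raise RuntimeError("ray escaped the closed arena; invalid geometry")

    view = PanoramicView(bright, p, float(orientation), float(deg_per_px))
    near = NearnessMap(t_best, p, float(orientation), float(deg_per_px))
    return view, near


def michelson_contrast(brightness) -> np.ndarray:
    """Per-pixel Michelson contrast over a 3x3 window.

    Computes ``(I_max - I_min) / (I_max + I_min)`` within each pixel's 3x3
    neighbourhood, wrapping around in azimuth and clipping the window at the
    elevation edges; pixels whose window sums to zero get contrast 0.
    """
    img = brightness.brightness if isinstance(brightness, PanoramicView) else brightness
    img = np.asarray(img, dtype=float)
    modes = ("nearest", "wrap")  # clipped elevation rows, periodic azimuth
    i_max = ndimage.maximum_filter(img, size=3, mode=modes)
    i_min = ndimage.minimum_filter(img, size=3, mode=modes)
    denom = i_max + i_min
    with np.errstate(invalid="ignore", divide="ignore"):
        contrast = np.where(denom > 0.0, (i_max - i_min) / np.where(denom > 0, denom, 1.0), 0.0)
    return contrast


def contrast_weighted_nearness(view: PanoramicView, nearness: NearnessMap) -> CwNView:
    """Weight the local Michelson contrast by nearness (inverse distance)."""
    if view.brightness.shape != nearness.distance.shape:
        raise ValueError(
            f"shape mismatch: brightness {view.brightness.shape} vs "
            f"distance {nearness.distance.shape}"
        )
    values = michelson_contrast(view.brightness) * nearness.nearness
    return CwNView(values, view.position, view.orientation, view.deg_per_px)


def rotate_view(image, degrees: float, deg_per_px: float | None = None):
    """Rotate a panoramic image about the vertical axis by ``degrees``.

    Rotation is an exact circular shift of azimuth columns; ``degrees`` must
    be a multiple of the angular resolution (no interpolation). For view
    objects the pose orientation is updated accordingly, so
    ``rotate_view(v, d)`` equals a re-render at ``orientation + d``.
    """
    if isinstance(image, (PanoramicView, NearnessMap, CwNView)):
        res = image.deg_per_px
        arr = (
            image.brightness
            if isinstance(image, PanoramicView)
            else image.distance if isinstance(image, NearnessMap) else image.values
        )
        shifted = rotate_view(arr, degrees, res)
        field_name = (
            "brightness"
            if isinstance(image, PanoramicView)
            else "distance" if isinstance(image, NearnessMap) else "values"
        )
        return replace(
            image,
            **{field_name: shifted},
            orientation=wrap_angle(image.orientation + degrees),
        )
    res = 1.0 if deg_per_px is None else float(deg_per_px)
    shift = degrees / res
    if abs(shift - round(shift)) > 1e-9:
        raise ValueError(
            f"rotation {degrees} deg is not a multiple of {res} deg per pixel"
        )
    # column u of the rotated view shows what column u + shift showed before
    return np.roll(np.asarray(image), -int(round(shift)), axis=-1)


@dataclass
class ViewGrid:
    """Panoramas on a square lattice of positions at one altitude.

    Arrays are indexed ``[ix, iy]`` with ``x = x_coords[ix]`` and
    ``y = y_coords[iy]``; all views are oriented along +x (orientation 0).
    Lattice points outside the arena (with a safety margin from the wall) or
    inside a cue cylinder footprint are flagged invalid.
    """

    scene: Scene
    x_coords: np.ndarray
    y_coords: np.ndarray
    altitude: float
    deg_per_px: float
    valid: np.ndarray  # (nx, ny) bool
    brightness: np.ndarray  # (nx, ny, n_v, n_u) float32
    distance: np.ndarray  # (nx, ny, n_v, n_u) float32
    _cwn: np.ndarray | None = None

    @property
    def spacing(self) -> float:
        return float(self.x_coords[1] - self.x_coords[0])

    @property
    def shape(self) -> tuple[int, int]:
        return self.valid.shape

    def positions(self) -> np.ndarray:
        """(nx, ny, 2) array of lattice x-y positions."""
        xx, yy = np.meshgrid(self.x_coords, self.y_coords, indexing="ij")
        return np.stack([xx, yy], axis=-1)

    def view_at(self, ix: int, iy: int) -> tuple[PanoramicView, NearnessMap]:
        if not self.valid[ix, iy]:
            raise PoseError(f"lattice point ({ix}, {iy}) is invalid")
        pos = np.array([self.x_coords[ix], self.y_coords[iy], self.altitude])
        view = PanoramicView(
            self.brightness[ix, iy].astype(float), pos, 0.0, self.deg_per_px
        )
        near = NearnessMap(
            self.distance[ix, iy].astype(float), pos, 0.0, self.deg_per_px
        )
        return view, near

    def cwn(self) -> np.ndarray:
        """Contrast-weighted-nearness images for every valid point (cached)."""
        if self._cwn is None:
            out = np.zeros_like(self.brightness)
            for ix, iy in zip(*np.nonzero(self.valid)):
                contrast = michelson_contrast(self.brightness[ix, iy].astype(float))
                out[ix, iy] = contrast / self.distance[ix, iy]
            self._cwn = out
        return self._cwn

    def save(self, directory) -> None:
        """Persist the grid as one .npz of arrays plus a JSON index."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savez_compressed(
            directory / "grid.npz",
            brightness=self.brightness,
            distance=self.distance,
            valid=self.valid,
            x_coords=self.x_coords,
            y_coords=self.y_coords,
        )
        index = {
            "altitude": self.altitude,
            "deg_per_px": self.deg_per_px,
            "condition": self.scene.condition.label,
            "n_valid": int(self.valid.sum()),
        }
        (directory / "index.json").write_text(json.dumps(index, indent=2))


def build_view_grid(
    scene: Scene,
    spacing: float = 2.0,
    altitude: float = 6.0,
    deg_per_px: float = 1.0,
    margin: float = 1.0,
) -> ViewGrid:
    """Render x-oriented panoramas on a square lattice covering the arena.

    The lattice is symmetric about the arena centre with the given spacing;
    points within ``margin`` of the wall or inside a cylinder footprint are
    excluded (flagged invalid, not rendered).
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    geom = scene.geometry
    if not (0.0 < altitude < geom.height):
        raise ValueError("altitude must lie strictly inside the arena height")
    k = int(math.floor((geom.radius - margin) / spacing))
    coords = np.arange(-k, k + 1) * spacing
    nx = coords.size
    xx, yy = np.meshgrid(coords, coords, indexing="ij")
    valid = np.hypot(xx, yy) <= geom.radius - margin
    centres = np.asarray(scene.cylinders.centres, dtype=float)
    for cx, cy in centres:
        valid &= np.hypot(xx - cx, yy - cy) > scene.cylinders.cylinder_radius

    n_u = int(round(360.0 / deg_per_px))
    n_v = int(round(180.0 / deg_per_px))
    brightness = np.zeros((nx, nx, n_v, n_u), dtype=np.float32)
    distance = np.ones((nx, nx, n_v, n_u), dtype=np.float32)
    for ix, iy in zip(*np.nonzero(valid)):
        view, near = render_panorama(
            scene, (xx[ix, iy], yy[ix, iy], altitude), 0.0, deg_per_px
        )
        brightness[ix, iy] = view.brightness
        distance[ix, iy] = near.distance
    return ViewGrid(
        scene=scene,
        x_coords=coords,
        y_coords=coords.copy(),
        altitude=float(altitude),
        deg_per_px=float(deg_per_px),
        valid=valid,
        brightness=brightness,
        distance=distance,
    )
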