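"""Homing-vector fields for five visual guidance models.

Every model turns the comparison between what is seen at a grid position in
a (possibly cue-conflict) test scene and what was memorized in the
habituation scene into a unit homing vector, forming a vector field over
the arena:

* ``ALV`` — average landmark vector: mean unit bearing to the six cues
  (three cylinders, three stripe centres); the homing vector is the
  difference between the current and the memorized average. Requires a
  compass; does not use rendered views.
* ``B1`` / ``CwN1`` — a single panoramic snapshot at the nest; the scalar
  landscape of best-match values (min rotIDF, or max rotSimF for
  contrast-weighted nearness) is descended (resp. ascended) by gradient.
* ``Bn`` / ``CwNn`` — n nest-oriented snapshots on a circle around the
  nest; each snapshot contributes a heading (its best-match rotation) and a
  match weight, fused by a weighted circular mean.

Grid views are rendered with orientation 0 (along +x) while memory views
face the nest, so the best-match rotation of a grid view *is* the world
azimuth of the heading that snapshot recommends.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .render import (
    CwNView,
    PanoramicView,
    ViewGrid,
    contrast_weighted_nearness,
    render_panorama,
)
from .scene import Scene
from .view_metrics import elevation_weights

__all__ = [
    "SnapshotMemory",
    "VectorField",
    "acquire_memory",
    "alv_field",
    "single_snapshot_field",
    "multi_snapshot_field",
    "masked_gradient",
]


@dataclass(frozen=True)
class SnapshotMemory:
    """Ordered nest-oriented views memorized in the habituation scene."""

    views: tuple  # PanoramicView (kind="brightness") or CwNView (kind="cwn")
    poses: np.ndarray  # (n, 3) acquisition positions
    orientations: np.ndarray  # (n,) world azimuths, each toward the nest
    kind: str  # "brightness" | "cwn"
    r_mem: float
    z_mem: float

    @property
    def n(self) -> int:
        return len(self.views)


def acquire_memory(
    habituation_scene: Scene,
    kind: str = "brightness",
    n: int = 1,
    r_mem: float = 0.0,
    z_mem: float = 6.0,
    phase: float = 0.0,
    deg_per_px: float = 1.0,
) -> SnapshotMemory:
    """Render the memorized snapshot set around the habituation nest.

    ``n`` views are taken at angles ``phase + 360 k / n`` on a circle of
    radius ``r_mem`` around the nest, each oriented toward the nest (a view
    at the nest itself, ``r_mem = 0``, is oriented along +x). ``kind="cwn"``
    converts each view to contrast-weighted nearness.
    """
    if kind not in ("brightness", "cwn"):
        raise ValueError(f"unknown snapshot kind {kind!r}")
    if n not in (1, 4, 8):
        raise ValueError("snapshot count n must be 1, 4 or 8")
    if r_mem == 0.0 and n != 1:
        raise ValueError("r_mem = 0 requires a single snapshot")
    nest = habituation_scene.nest
    views = []
    poses = np.zeros((n, 3))
    orientations = np.zeros(n)
    for k in range(n):
        if r_mem == 0.0:
            pos = np.array([nest[0], nest[1], z_mem])
            ori = 0.0
        else:
            ang = math.radians(phase + 360.0 * k / n)
            pos = np.array(
                [nest[0] + r_mem * math.cos(ang), nest[1] + r_mem * math.sin(ang), z_mem]
            )
            ori = math.degrees(math.atan2(nest[1] - pos[1], nest[0] - pos[0]))
        view, near = render_panorama(habituation_scene, pos, ori, deg_per_px)
        views.append(
            contrast_weighted_nearness(view, near) if kind == "cwn" else view
        )
        poses[k] = pos
        orientations[k] = ori
    return SnapshotMemory(
        views=tuple(views),
        poses=poses,
        orientations=orientations,
        kind=kind,
        r_mem=float(r_mem),
        z_mem=float(z_mem),
    )


@dataclass
class VectorField:
    """Unit homing vectors on the view-grid lattice.

    ``hv[ix, iy]`` is the unit homing vector at ``(x_coords[ix],
    y_coords[iy])``; points where no direction is defined (e.g. exactly at
    the goal, or outside the arena) are flagged invalid. ``scalar`` holds
    the best-match landscape for the single-snapshot models; ``headings``
    and ``weights`` the per-snapshot data of the multi-snapshot models.
    """

    x_coords: np.ndarray
    y_coords: np.ndarray
    hv: np.ndarray  # (nx, ny, 2)
    valid: np.ndarray  # (nx, ny) bool
    metadata: dict = field(default_factory=dict)
    scalar: np.ndarray | None = None
    headings: np.ndarray | None = None  # (nx, ny, n) deg
    weights: np.ndarray | None = None  # (nx, ny, n), max 1 per point

    @property
    def spacing(self) -> float:
        return float(self.x_coords[1] - self.x_coords[0])

    def to_frame(self):
        """Long-format DataFrame (x_cm, y_cm, hv_x, hv_y, valid)."""
        import pandas as pd

        xx, yy = np.meshgrid(self.x_coords, self.y_coords, indexing="ij")
        return pd.DataFrame(
            {
                "x_cm": xx.ravel(),
                "y_cm": yy.ravel(),
                "hv_x": self.hv[..., 0].ravel(),
                "hv_y": self.hv[..., 1].ravel(),
                "valid": self.valid.ravel(),
            }
        )


def _normalize(vec: np.ndarray, eps: float = 1e-12) -> tuple[np.ndarray, np.ndarray]:
    """Unit vectors and a mask of points whose magnitude was above eps."""
    mag = np.linalg.norm(vec, axis=-1)
    ok = mag > eps
    unit = np.zeros_like(vec)
    unit[ok] = vec[ok] / mag[ok][..., None]
    return unit, ok


def _landmark_bearings(scene: Scene, points: np.ndarray) -> np.ndarray:
    """(npts, 6, 2) unit bearings to the 3 cylinder axes and 3 stripe centres.

    Landmarks are identified geometrically (perfect detection, no
    occlusion); a stripe's bearing aims at the angular centre of the stripe
    on the wall.
    """
    targets = [np.asarray(c, dtype=float) for c in scene.cylinders.centres]
    r_wall = scene.geometry.radius
    for az in scene.stripes.azimuths():
        a = math.radians(az)
        targets.append(r_wall * np.array([math.cos(a), math.sin(a)]))
    t = np.stack(targets)  # (6, 2)
    diff = t[None, :, :] - points[:, None, :]
    norm = np.linalg.norm(diff, axis=-1, keepdims=True)
    return diff / np.where(norm > 0, norm, 1.0)


def alv_field(
    test_scene: Scene,
    habituation_scene: Scene,
    grid: ViewGrid | None = None,
    x_coords: np.ndarray | None = None,
    y_coords: np.ndarray | None = None,
    valid: np.ndarray | None = None,
) -> VectorField:
    """Average-landmark-vector homing field over the lattice.

    The memorized vector is the mean landmark bearing at the habituation
    nest; the homing vector at a point is the (unit-normalized) difference
    between the current mean bearing and the memorized one. The lattice can
    be given either as a rendered ViewGrid (only its lattice is used) or as
    explicit coordinates.
    """
    if grid is not None:
        x_coords, y_coords, valid = grid.x_coords, grid.y_coords, grid.valid
    if x_coords is None or y_coords is None:
        raise ValueError("either a ViewGrid or explicit lattice coords are required")
    if valid is None:
        valid = np.ones((x_coords.size, y_coords.size), dtype=bool)

    alv_nest = _landmark_bearings(
        habituation_scene, habituation_scene.nest[None, :]
    )[0].mean(axis=0)

    xx, yy = np.meshgrid(x_coords, y_coords, indexing="ij")
    pts = np.stack([xx[valid], yy[valid]], axis=-1)
    alv_curr = _landmark_bearings(test_scene, pts).mean(axis=1)
    raw = alv_curr - alv_nest[None, :]
    unit, ok = _normalize(raw)

    hv = np.zeros((x_coords.size, y_coords.size, 2))
    good = np.zeros_like(valid)
    hv[valid] = unit
    good[valid] = ok
    return VectorField(
        x_coords=x_coords,
        y_coords=y_coords,
        hv=hv,
        valid=good,
        metadata={
            "model": "ALV",
            "condition": test_scene.condition.label,
            "sign_convention": "current_minus_memory",
        },
    )


def masked_gradient(
    f: np.ndarray, valid: np.ndarray, spacing: float
) -> tuple[np.ndarray, np.ndarray]:
    """Finite-difference gradient of a masked lattice scalar.

    Central differences where both neighbours along an axis are valid,
    one-sided at mask boundaries; points with no valid neighbour along an
    axis get derivative 0 there. Returns (grad (nx, ny, 2), defined mask).
    """
    grad = np.zeros(f.shape + (2,))
    any_nb = np.zeros(f.shape, dtype=bool)
    for axis in range(2):
        plus = np.zeros_like(valid)
        minus = np.zeros_like(valid)
        f_plus = np.zeros_like(f)
        f_minus = np.zeros_like(f)
        sl_to = [slice(None)] * 2
        sl_from = [slice(None)] * 2
        sl_to[axis] = slice(None, -1)
        sl_from[axis] = slice(1, None)
        plus[tuple(sl_to)] = valid[tuple(sl_from)]
        f_plus[tuple(sl_to)] = f[tuple(sl_from)]
        sl_to[axis] = slice(1, None)
        sl_from[axis] = slice(None, -1)
        minus[tuple(sl_to)] = valid[tuple(sl_from)]
        f_minus[tuple(sl_to)] = f[tuple(sl_from)]
        both = plus & minus
        d = np.zeros_like(f)
        d[both] = (f_plus[both] - f_minus[both]) / (2.0 * spacing)
        only_p = plus & ~minus
        d[only_p] = (f_plus[only_p] - f[only_p]) / spacing
        only_m = minus & ~plus
        d[only_m] = (f[only_m] - f_minus[only_m]) / spacing
        grad[..., axis] = d
        any_nb |= plus | minus
    return grad, any_nb & valid


def _check_resolution(grid: ViewGrid, memory: SnapshotMemory) -> None:
    mv = memory.views[0]
    shape = (mv.n_v, mv.n_u)
    if grid.brightness.shape[2:] != shape:
        raise ValueError(
            f"grid resolution {grid.brightness.shape[2:]} does not match "
            f"memory resolution {shape}"
        )
    if memory.kind == "cwn" and not isinstance(mv, CwNView):
        raise ValueError("memory kind 'cwn' requires CwNView snapshots")
    if memory.kind == "brightness" and not isinstance(mv, PanoramicView):
        raise ValueError("memory kind 'brightness' requires PanoramicView snapshots")


def _img(view) -> np.ndarray:
    return view.values if isinstance(view, CwNView) else view.brightness


def _grid_images(grid: ViewGrid, kind: str) -> np.ndarray:
    return grid.cwn() if kind == "cwn" else grid.brightness


def _batch_profiles(grid: ViewGrid, memory: SnapshotMemory) -> np.ndarray:
    """Rotational profiles of every valid grid view against every snapshot.

    Returns ``values[j, i, :]``, the rotIDF (or rotSimF) profile of valid
    point ``j`` against snapshot ``i``, computed with the same rFFT
    cross-correlation as :mod:`beehoming.view_metrics`.
    """
    imgs = _grid_images(grid, memory.kind)
    n_v, n_u = imgs.shape[2:]
    w = elevation_weights(n_v).w[:, None]
    mems = np.stack([np.asarray(_img(v), dtype=float) for v in memory.views])
    f_mem = np.conj(np.fft.rfft(w[None] * mems, axis=2))  # (n, n_v, nf)
    s_mem = (w[None] * mems**2).sum(axis=(1, 2))  # (n,)

    idx = np.nonzero(grid.valid)
    cur = imgs[idx].astype(float)  # (npts, n_v, n_u)
    f_cur = np.fft.rfft(cur, axis=2)
    s_cur = (w[None] * cur**2).sum(axis=(1, 2))  # (npts,)
    cross = np.fft.irfft(np.einsum("jvf,ivf->jif", f_cur, f_mem), n=n_u, axis=2)
    if memory.kind == "brightness":
        norm = n_u * w.sum()
        sq = s_cur[:, None, None] + s_mem[None, :, None] - 2.0 * cross
        np.maximum(sq, 0.0, out=sq)
        tol = 1e-12 * (s_cur[:, None, None] + s_mem[None, :, None])
        sq[sq < tol] = 0.0
        return np.sqrt(sq / norm)
    denom = np.sqrt(s_cur[:, None] * s_mem[None, :])
    if np.any(denom <= 0.0):
        raise ValueError("correlation undefined: an all-zero CwN image")
    return cross / denom[:, :, None]


def _best_shift(
    values: np.ndarray, kind: str, deg_per_px: float
) -> tuple[np.ndarray, np.ndarray]:
    """Extremum value and shift (deg) along the last axis, breaking ties
    toward the smallest ``|alpha|`` and then toward positive ``alpha``."""
    n_u = values.shape[-1]
    alpha = (np.arange(n_u) * deg_per_px + 180.0) % 360.0 - 180.0
    order = np.lexsort((-np.sign(alpha), np.abs(alpha)))
    ordered = values[..., order]
    idx = (
        np.argmin(ordered, axis=-1)
        if kind == "brightness"
        else np.argmax(ordered, axis=-1)
    )
    best = np.take_along_axis(ordered, idx[..., None], axis=-1)[..., 0]
    return best, alpha[order][idx]


def single_snapshot_field(grid: ViewGrid, memory: SnapshotMemory) -> VectorField:
    """Gradient field of the best-match landscape of one nest snapshot.

    For brightness the landscape is the minimum rotIDF and the agent
    descends it (homing vector = -grad); for contrast-weighted nearness it
    is the maximum similarity and the agent ascends it.
    """
    if memory.n != 1:
        raise ValueError("single-snapshot model requires exactly one view")
    _check_resolution(grid, memory)
    values = _batch_profiles(grid, memory)
    best, _shift = _best_shift(values[:, 0, :], memory.kind, grid.deg_per_px)
    f = np.zeros(grid.shape)
    f[grid.valid] = best
    grad, defined = masked_gradient(f, grid.valid, grid.spacing)
    vec = -grad if memory.kind == "brightness" else grad
    hv, ok = _normalize(vec)
    return VectorField(
        x_coords=grid.x_coords,
        y_coords=grid.y_coords,
        hv=hv,
        valid=defined & ok,
        scalar=f,
        metadata={
            "model": "B1" if memory.kind == "brightness" else "CwN1",
            "condition": grid.scene.condition.label,
            "kind": memory.kind,
            "altitude": grid.altitude,
        },
    )


def multi_snapshot_field(grid: ViewGrid, memory: SnapshotMemory) -> VectorField:
    """Weighted-circular-mean fusion of per-snapshot headings.

    Each snapshot votes for the world heading at which it matches the local
    view best. Brightness snapshots are weighted by ``S_dmin / d_si`` (the
    best rotIDF over the set divided by their own), similarity snapshots by
    ``sim_si / max_i sim_si``; the best-matching snapshot always has weight
    1. The homing vector is the direction of the weighted complex sum; it
    is undefined (invalid) where the votes cancel.
    """
    if memory.n < 2:
        raise ValueError("multi-snapshot model requires at least 2 views")
    _check_resolution(grid, memory)
    values = _batch_profiles(grid, memory)
    best, shift = _best_shift(values, memory.kind, grid.deg_per_px)  # (npts, n)
    if memory.kind == "brightness":
        s_dmin = best.min(axis=1, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            wgt = s_dmin / np.where(best > 0.0, best, 1.0)
        # an exact match dominates: it keeps weight 1 while the 0/0 form of
        # the other snapshots resolves to S_dmin / d = 0
        wgt[best == 0.0] = 1.0
    else:
        s_max = best.max(axis=1, keepdims=True)
        if np.any(s_max <= 0.0):
            raise ValueError("all-zero similarities at some grid point")
        wgt = best / s_max

    z = (wgt * np.exp(1j * np.radians(shift))).sum(axis=1)
    ok = np.abs(z) > 1e-9
    unit, _ = _normalize(np.stack([z.real, z.imag], axis=-1), eps=1e-9)

    nx, ny = grid.shape
    hv = np.zeros((nx, ny, 2))
    good = np.zeros((nx, ny), dtype=bool)
    headings = np.zeros((nx, ny, memory.n))
    weights = np.zeros((nx, ny, memory.n))
    hv[grid.valid] = unit
    good[grid.valid] = ok
    headings[grid.valid] = shift
    weights[grid.valid] = wgt
    name = ("B" if memory.kind == "brightness" else "CwN") + str(memory.n)
    return VectorField(
        x_coords=grid.x_coords,
        y_coords=grid.y_coords,
        hv=hv,
        valid=good,
        headings=headings,
        weights=weights,
        metadata={
            "model": name,
            "condition": grid.scene.condition.label,
            "kind": memory.kind,
            "n_snapshots": memory.n,
            "r_mem": memory.r_mem,
            "z_mem": memory.z_mem,
            "altitude": grid.altitude,
        },
    )
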