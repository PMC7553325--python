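"""Homing potentials and search basins via Helmholtz-Hodge decomposition.

A homing-vector field V tells an agent where to move; where its vectors
converge, the agent's search ends. The curl-free part of V is the gradient
of a scalar potential phi (V_curlfree = -grad phi), obtained here by
solving the Poisson problem ``laplace(phi) = -div(V)`` on the masked arena
disc with homogeneous Neumann (no-flow-through-the-wall) boundary
conditions and a zero-mean gauge. The potential is then affinely rescaled
to [0, 1]; connected regions below an isohypse (level) of the rescaled
landscape are *basins* — the model's predicted search areas.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .homing_models import VectorField, masked_gradient

__all__ = [
    "HomingPotential",
    "Basin",
    "helmholtz_hodge",
    "extract_basins",
    "basin_report",
    "rotate_lattice_quarter",
]

_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])  # 4-connectivity


@dataclass
class HomingPotential:
    """Scalar homing landscape on the view-grid lattice, scaled to [0, 1]."""

    phi: np.ndarray  # (nx, ny), min 0 / max 1 over the mask
    mask: np.ndarray  # (nx, ny) bool, valid lattice cells
    x_coords: np.ndarray
    y_coords: np.ndarray
    metadata: dict = field(default_factory=dict)

    @property
    def spacing(self) -> float:
        return float(self.x_coords[1] - self.x_coords[0])

    def minimum_point(self) -> np.ndarray:
        """Position of the global minimum over valid cells."""
        masked = np.where(self.mask, self.phi, np.inf)
        ix, iy = np.unravel_index(np.argmin(masked), masked.shape)
        return np.array([self.x_coords[ix], self.y_coords[iy]])

    def to_frame(self):
        import pandas as pd

        xx, yy = np.meshgrid(self.x_coords, self.y_coords, indexing="ij")
        return pd.DataFrame(
            {
                "x_cm": xx.ravel(),
                "y_cm": yy.ravel(),
                "phi": self.phi.ravel(),
                "valid": self.mask.ravel(),
            }
        )


@dataclass
class Basin:
    """One connected sub-isohypse component of the homing landscape."""

    cells: np.ndarray  # (nx, ny) bool
    x_coords: np.ndarray
    y_coords: np.ndarray
    minimum_point: np.ndarray  # (2,) position of the deepest cell, cm
    minimum_value: float
    area: float  # cm^2

    def contains(self, point, tol_cells: int = 1) -> bool:
        """Whether ``point`` falls in the basin, within ``tol_cells`` cells.

        The point is snapped to its nearest lattice index; the basin
        contains it if any basin cell lies within a Chebyshev distance of
        ``tol_cells`` lattice steps.
        """
        p = np.asarray(point, dtype=float)
        ix = int(np.argmin(np.abs(self.x_coords - p[0])))
        iy = int(np.argmin(np.abs(self.y_coords - p[1])))
        nx, ny = self.cells.shape
        sl = (
            slice(max(ix - tol_cells, 0), min(ix + tol_cells + 1, nx)),
            slice(max(iy - tol_cells, 0), min(iy + tol_cells + 1, ny)),
        )
        return bool(self.cells[sl].any())


def _fill_invalid(field_arr: np.ndarray, valid: np.ndarray, domain: np.ndarray) -> np.ndarray:
    """Nearest-neighbour fill of domain cells that carry no field value."""
    if np.all(valid[domain]):
        return field_arr
    # distance transform indices of the nearest valid cell
    _, (ii, jj) = ndimage.distance_transform_edt(~valid, return_indices=True)
    filled = field_arr[ii, jj]
    out = field_arr.copy()
    hole = domain & ~valid
    out[hole] = filled[hole]
    return out


def helmholtz_hodge(
    vector_field: VectorField,
    domain: np.ndarray | None = None,
) -> HomingPotential:
    """Curl-free potential of a homing-vector field.

    Computes the potential whose negative gradient is the curl-free
    (convergent/divergent) component of V by convolving the negative
    divergence of V with the free-space Green's function of the 2D
    Laplacian (``phi = -(1/2 pi) sum log|x - x'| div V(x') h^2``), the
    open-boundary formulation of the Helmholtz-Hodge decomposition. The
    divergence is evaluated with central differences at cells whose full
    5-point stencil lies inside the (disc-shaped) domain, which keeps the
    stair-stepped lattice boundary from polluting the potential: a
    divergence-free flow around the arena yields an exactly flat phi,
    while any convergence of homing vectors appears as a basin. Cells
    inside the domain that carry no vector (cylinder footprints) are
    filled by nearest-neighbour interpolation before differentiation and
    masked afterwards. phi is affinely rescaled to [0, 1] over the valid
    cells.

    The unscaled range and the r.m.s. of the non-gradient remainder are
    reported in the metadata so solver sensitivity stays visible.
    """
    f = vector_field
    h = f.spacing
    if domain is None:
        xx, yy = np.meshgrid(f.x_coords, f.y_coords, indexing="ij")
        rr = np.hypot(xx, yy)
        r_max = rr[f.valid].max() if f.valid.any() else 0.0
        domain = rr <= r_max + 1e-9
    lbl, n_comp = ndimage.label(domain, structure=_CROSS)
    if n_comp != 1:
        raise ValueError(f"solve domain must be connected, found {n_comp} components")

    vx = _fill_invalid(f.hv[..., 0], f.valid, domain) * domain
    vy = _fill_invalid(f.hv[..., 1], f.valid, domain) * domain

    nx, ny = domain.shape
    interior = np.zeros((nx, ny), dtype=bool)
    interior[1:-1, 1:-1] = (
        domain[1:-1, 1:-1]
        & domain[2:, 1:-1]
        & domain[:-2, 1:-1]
        & domain[1:-1, 2:]
        & domain[1:-1, :-2]
    )
    div = np.zeros((nx, ny))
    div[1:-1, 1:-1] = (vx[2:, 1:-1] - vx[:-2, 1:-1]) / (2.0 * h) + (
        vy[1:-1, 2:] - vy[1:-1, :-2]
    ) / (2.0 * h)
    rho = np.where(interior, -div, 0.0)  # laplace(phi) = -div(V)

    xx, yy = np.meshgrid(f.x_coords, f.y_coords, indexing="ij")
    targets = np.stack([xx[domain], yy[domain]], axis=-1)
    sources = np.stack([xx[interior], yy[interior]], axis=-1)
    mass = rho[interior] * h * h
    dist = np.linalg.norm(targets[:, None, :] - sources[None, :, :], axis=-1)
    a_eq = h / np.sqrt(np.pi)  # equal-area disc radius of one cell
    green = np.where(
        dist > 1e-9,
        np.log(np.maximum(dist, 1e-9)),
        np.log(a_eq) - 0.5,  # self-potential of a uniform cell
    ) / (2.0 * np.pi)
    phi = np.zeros((nx, ny))
    phi[domain] = green @ mass

    valid = f.valid & domain
    lo = phi[valid].min()
    hi = phi[valid].max()
    raw_range = hi - lo
    scaled = np.zeros_like(phi)
    if raw_range > 0:
        scaled[domain] = (phi[domain] - lo) / raw_range
    grad_phi, _ = masked_gradient(phi, domain, h)
    remainder = np.stack([vx, vy], axis=-1) + grad_phi
    meta = dict(f.metadata)
    meta.update(
        {
            "raw_range": float(raw_range),
            "remainder_rms": float(
                np.sqrt((remainder[domain] ** 2).sum(axis=-1).mean())
            ),
            "solver": "greens_function_open_boundary",
        }
    )
    return HomingPotential(
        phi=scaled,
        mask=valid,
        x_coords=f.x_coords,
        y_coords=f.y_coords,
        metadata=meta,
    )


def extract_basins(potential: HomingPotential, isohypse: float = 0.15) -> list[Basin]:
    """Connected components (4-connectivity) of ``phi <= isohypse``.

    Basins are returned sorted by their minimum value, deepest first, so
    the first entry is the 'lowest basin' containing the global minimum.
    """
    if not (0.0 < isohypse < 1.0):
        raise ValueError("isohypse must lie strictly between 0 and 1")
    low = (potential.phi <= isohypse) & potential.mask
    lbl, n = ndimage.label(low, structure=_CROSS)
    basins = []
    for k in range(1, n + 1):
        cells = lbl == k
        masked = np.where(cells, potential.phi, np.inf)
        ix, iy = np.unravel_index(np.argmin(masked), masked.shape)
        basins.append(
            Basin(
                cells=cells,
                x_coords=potential.x_coords,
                y_coords=potential.y_coords,
                minimum_point=np.array(
                    [potential.x_coords[ix], potential.y_coords[iy]]
                ),
                minimum_value=float(potential.phi[ix, iy]),
                area=float(cells.sum()) * potential.spacing**2,
            )
        )
    basins.sort(key=lambda b: b.minimum_value)
    return basins


def basin_report(
    potential: HomingPotential,
    points_of_interest: dict,
    isohypse: float = 0.15,
):
    """Tabulate basin membership for named points (nest, fictive nests).

    For each point: whether any basin at the isohypse contains it (one-cell
    tolerance), whether the *lowest* basin does, and the distance to the
    nearest basin minimum.
    """
    import pandas as pd

    basins = extract_basins(potential, isohypse)
    rows = []
    for name, point in points_of_interest.items():
        p = np.asarray(point, dtype=float)
        contained = any(b.contains(p) for b in basins)
        in_lowest = basins[0].contains(p) if basins else False
        dist = (
            min(float(np.linalg.norm(b.minimum_point - p)) for b in basins)
            if basins
            else np.nan
        )
        rows.append(
            {
                "point": name,
                "x_cm": p[0],
                "y_cm": p[1],
                "in_basin": contained,
                "in_lowest_basin": in_lowest,
                "dist_to_nearest_minimum_cm": dist,
            }
        )
    return pd.DataFrame(rows)


def rotate_lattice_quarter(arr: np.ndarray, k: int = 1) -> np.ndarray:
    """Rotate a lattice scalar by ``k`` quarter turns counter-clockwise.

    For arrays indexed ``[ix, iy]`` on coordinates symmetric about zero,
    the rotated array B satisfies ``B(x, y) = A(R(-90k) (x, y))``.
    """
    out = np.asarray(arr)
    for _ in range(k % 4):
        # B[ix, iy] = A(y, -x) -> index [iy, n-1-ix]
        out = out[:, ::-1].T if out.ndim == 2 else np.transpose(out[:, ::-1], (1, 0, 2))
    return out
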