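"""Flight-trajectory analysis: altitude filtering and KDE search maps.

A bumblebee searching for its nest hole flies low over the arena floor.
Samples outside the search-related altitude band (walking below 3 cm,
non-search flight above 20.63 cm — the pooled 75th percentile of flight
height) are discarded; the remaining x-y positions of each flight are
turned into a 2D Gaussian kernel density (Scott's-rule bandwidth),
normalized per flight so that short successful flights weigh as much as
full five-minute searches, and averaged across flights. Cells whose
density reaches a third of the map's maximum form the *search area* that
model basins are compared against.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Trajectory",
    "GridSpec",
    "SearchMap",
    "TrajectoryValidationError",
    "read_trajectories",
    "write_trajectories",
    "altitude_band_filter",
    "percentile_altitude",
    "kde_search_map",
    "search_area",
    "lattice_for_arena",
]

CSV_COLUMNS = ["flight_id", "t_s", "x_cm", "y_cm", "z_cm"]


class TrajectoryValidationError(ValueError):
    """A trajectory file violates the expected structure."""


@dataclass
class Trajectory:
    """One recorded (or simulated) return flight at nominal 74 Hz."""

    flight_id: str
    t: np.ndarray  # s, strictly increasing
    x: np.ndarray  # cm
    y: np.ndarray
    z: np.ndarray
    condition: str = ""

    def __len__(self) -> int:
        return self.t.size

    def validate(self, arena_radius: float = 75.0, max_duration: float = 300.0) -> None:
        if np.any(np.diff(self.t) <= 0):
            row = int(np.argmax(np.diff(self.t) <= 0)) + 1
            raise TrajectoryValidationError(
                f"flight {self.flight_id}: non-monotonic time at sample {row}"
            )
        r = np.hypot(self.x, self.y)
        if np.any(r > arena_radius + 1e-9):
            row = int(np.argmax(r > arena_radius + 1e-9))
            raise TrajectoryValidationError(
                f"flight {self.flight_id}: position outside arena at sample {row}"
            )
        if self.t.size and self.t[-1] - self.t[0] > max_duration + 1e-9:
            raise TrajectoryValidationError(
                f"flight {self.flight_id}: duration exceeds {max_duration} s"
            )


def read_trajectories(path, arena_radius: float = 75.0) -> list[Trajectory]:
    """Read flights from a CSV with columns flight_id,t_s,x_cm,y_cm,z_cm."""
    df = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise TrajectoryValidationError(f"missing columns {missing} in {path}")
    if df.empty:
        return []
    bad = df[CSV_COLUMNS[1:]].isna().any(axis=1)
    if bad.any():
        lines = (np.nonzero(bad.to_numpy())[0] + 2).tolist()  # header = line 1
        raise TrajectoryValidationError(f"malformed rows at lines {lines} in {path}")
    out = []
    for fid, g in df.groupby("flight_id", sort=False):
        traj = Trajectory(
            flight_id=str(fid),
            t=g["t_s"].to_numpy(float),
            x=g["x_cm"].to_numpy(float),
            y=g["y_cm"].to_numpy(float),
            z=g["z_cm"].to_numpy(float),
            condition=(
                str(g["condition"].iloc[0])
                if "condition" in g and pd.notna(g["condition"].iloc[0])
                else ""
            ),
        )
        traj.validate(arena_radius=arena_radius)
        out.append(traj)
    return out


def write_trajectories(trajectories: list[Trajectory], path) -> None:
    """Write flights in the CSV dialect understood by read_trajectories."""
    frames = []
    for tr in trajectories:
        frames.append(
            pd.DataFrame(
                {
                    "flight_id": tr.flight_id,
                    "t_s": tr.t,
                    "x_cm": tr.x,
                    "y_cm": tr.y,
                    "z_cm": tr.z,
                    "condition": tr.condition,
                }
            )
        )
    df = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=CSV_COLUMNS + ["condition"])
    )
    df.to_csv(path, index=False, float_format="%.6f")


def altitude_band_filter(
    trajectories: list[Trajectory],
    z_low: float = 3.0,
    z_high: float = 20.63,
) -> list[Trajectory]:
    """Keep samples with z_low <= z <= z_high; drop flights left empty.

    The default band discards walking (below 3 cm) and flight unrelated to
    nest search (above 20.63 cm, the 75th percentile of flight height).
    """
    if z_low >= z_high:
        raise ValueError("z_low must be smaller than z_high")
    kept = []
    for tr in trajectories:
        sel = (tr.z >= z_low) & (tr.z <= z_high)
        if not sel.any():
            warnings.warn(
                f"flight {tr.flight_id}: no samples in altitude band, dropped",
                stacklevel=2,
            )
            continue
        kept.append(
            Trajectory(tr.flight_id, tr.t[sel], tr.x[sel], tr.y[sel], tr.z[sel], tr.condition)
        )
    return kept


def percentile_altitude(trajectories: list[Trajectory], q: float = 75.0) -> float:
    """q-th percentile of the pooled flight heights (linear interpolation)."""
    if not (0.0 < q < 100.0):
        raise ValueError("q must lie in (0, 100)")
    if not trajectories:
        raise ValueError("no trajectories to pool")
    pooled = np.concatenate([tr.z for tr in trajectories])
    if pooled.size == 0:
        raise ValueError("no samples to pool")
    return float(np.percentile(pooled, q))


@dataclass(frozen=True)
class GridSpec:
    """Evaluation lattice for search maps, aligned with the model grids."""

    x_coords: np.ndarray
    y_coords: np.ndarray
    mask: np.ndarray  # (nx, ny) bool, cells inside the arena

    @property
    def spacing(self) -> float:
        return float(self.x_coords[1] - self.x_coords[0])


def lattice_for_arena(
    radius: float = 75.0, spacing: float = 2.0, margin: float = 1.0
) -> GridSpec:
    """Square lattice matching :func:`beehoming.render.build_view_grid`."""
    k = int(np.floor((radius - margin) / spacing))
    coords = np.arange(-k, k + 1) * spacing
    xx, yy = np.meshgrid(coords, coords, indexing="ij")
    return GridSpec(coords, coords.copy(), np.hypot(xx, yy) <= radius - margin)


@dataclass
class SearchMap:
    """Flight-averaged, time-normalized 2D density of search positions."""

    density: np.ndarray  # (nx, ny) cm^-2, integrates to 1 over the mask
    grid: GridSpec
    n_flights: int
    bandwidth_factors: list = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def search_area_mask(self, fraction: float = 1.0 / 3.0) -> np.ndarray:
        return search_area(self, fraction)


def kde_search_map(trajectories: list[Trajectory], grid: GridSpec) -> SearchMap:
    """Average of per-flight Gaussian KDEs of x-y position on the lattice.

    Each flight's (x, y) samples are smoothed with a 2D Gaussian kernel
    whose bandwidth follows Scott's rule (``n**(-1/6)`` times the sample
    covariance factor), evaluated at the lattice cell centres, clipped to
    the arena disc and renormalized to integrate to 1; the search map is
    the plain mean of the per-flight densities, so every flight counts
    equally regardless of its duration. Flights with fewer than 3 samples
    or degenerate spatial variance are skipped with a warning.
    """
    if not trajectories:
        raise ValueError("at least one trajectory is required")
    xx, yy = np.meshgrid(grid.x_coords, grid.y_coords, indexing="ij")
    pts = np.vstack([xx[grid.mask], yy[grid.mask]])
    cell = grid.spacing**2
    densities = []
    factors = []
    for tr in trajectories:
        if len(tr) < 3:
            warnings.warn(
                f"flight {tr.flight_id}: fewer than 3 samples, skipped", stacklevel=2
            )
            continue
        data = np.vstack([tr.x, tr.y])
        if np.linalg.matrix_rank(np.cov(data)) < 2:
            warnings.warn(
                f"flight {tr.flight_id}: degenerate spatial variance, skipped",
                stacklevel=2,
            )
            continue
        kde = stats.gaussian_kde(data, bw_method="scott")
        dens = np.zeros(grid.mask.shape)
        dens[grid.mask] = kde(pts)
        total = dens.sum() * cell
        if total <= 0:
            warnings.warn(
                f"flight {tr.flight_id}: zero density on the arena lattice, skipped",
                stacklevel=2,
            )
            continue
        densities.append(dens / total)
        factors.append(float(kde.factor))
    if not densities:
        raise ValueError("no usable flights for the search map")
    avg = np.mean(densities, axis=0)
    return SearchMap(
        density=avg,
        grid=grid,
        n_flights=len(densities),
        bandwidth_factors=factors,
        metadata={"max_density": float(avg.max())},
    )


def search_area(search_map: SearchMap, fraction: float = 1.0 / 3.0) -> np.ndarray:
    """Cells whose density reaches ``fraction`` of the map's maximum."""
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must lie in (0, 1)")
    return search_map.density >= fraction * search_map.density.max()
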