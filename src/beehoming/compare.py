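"""Confronting model basins with behavioural search areas.

Predicted search areas (basins of the homing potential below an isohypse)
and observed search areas (thresholded KDE search maps) are boolean masks
on the same lattice; their overlap is summarized by a confusion matrix and
precision / recall / F1. Because the isohypse choice trades basin size
against accuracy, F1 is swept over a range of isohypses, and models are
compared per condition with a Kruskal-Wallis test followed by pairwise
Dunn tests with Bonferroni correction.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .behaviour import (
    SearchMap,
    altitude_band_filter,
    kde_search_map,
    lattice_for_arena,
    read_trajectories,
    search_area,
)
from .homing_models import (
    acquire_memory,
    alv_field,
    multi_snapshot_field,
    single_snapshot_field,
)
from .potential import HomingPotential, basin_report, extract_basins, helmholtz_hodge
from .render import build_view_grid
from .scene import ConflictCondition, build_scene, fictive_nests, scene_from_config
from .synthetic_data import paper_like_dataset

__all__ = [
    "ConfusionResult",
    "confusion",
    "isohypse_sweep",
    "dunn_test",
    "f1_model_comparison",
    "run_pipeline",
    "MODEL_SPECS",
]


@dataclass(frozen=True)
class ConfusionResult:
    """Cellwise confusion between observed and predicted search areas."""

    tp: int
    fp: int
    fn: int
    tn: int
    isohypse: float = float("nan")
    condition: str = ""
    model: str = ""
    degenerate: bool = False  # an empty mask made a ratio undefined

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2.0 * p * r / (p + r) if p + r > 0 else 0.0


def confusion(
    search_mask: np.ndarray,
    basin_mask: np.ndarray,
    valid: np.ndarray | None = None,
    isohypse: float = float("nan"),
    condition: str = "",
    model: str = "",
) -> ConfusionResult:
    """Count lattice cells by observed search vs predicted basin."""
    if search_mask.shape != basin_mask.shape:
        raise ValueError(
            f"lattice mismatch: {search_mask.shape} vs {basin_mask.shape}"
        )
    if valid is None:
        valid = np.ones_like(search_mask, dtype=bool)
    s = search_mask & valid
    b = basin_mask & valid
    return ConfusionResult(
        tp=int((s & b).sum()),
        fp=int((~s & b).sum()),
        fn=int((s & ~b).sum()),
        tn=int((~s & ~b & valid).sum()),
        isohypse=isohypse,
        condition=condition,
        model=model,
        degenerate=bool(not s.any() or not b.any()),
    )


def isohypse_sweep(
    potential: HomingPotential,
    search_mask: np.ndarray,
    lo: float = 0.10,
    hi: float = 0.29,
    step: float = 0.01,
) -> list[ConfusionResult]:
    """One confusion result per isohypse in [lo, hi] (inclusive)."""
    if not (0.0 < lo < hi < 1.0):
        raise ValueError("need 0 < lo < hi < 1")
    results = []
    for iso in np.arange(lo, hi + step / 2.0, step):
        basin_mask = (potential.phi <= iso) & potential.mask
        results.append(
            confusion(
                search_mask,
                basin_mask,
                valid=potential.mask,
                isohypse=float(iso),
                condition=str(potential.metadata.get("condition", "")),
                model=str(potential.metadata.get("model", "")),
            )
        )
    return results


def dunn_test(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Pairwise Dunn z-tests on pooled ranks, with tie correction.

    For groups i, j the statistic is
    ``z = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T/(12(N-1))) (1/n_i + 1/n_j))``
    with ``T = sum(t^3 - t)`` over tie groups; two-sided p-values are
    Bonferroni-multiplied by the number of pairs (capped at 1).
    """
    names = list(groups)
    values = [np.asarray(groups[k], dtype=float) for k in names]
    pooled = np.concatenate(values)
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    mean_ranks = {}
    start = 0
    for name, v in zip(names, values):
        mean_ranks[name] = ranks[start : start + v.size].mean()
        start += v.size
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float((counts**3 - counts).sum())
    var_base = n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1))
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
    rows = []
    for a, b in pairs:
        na, nb = groups[a].__len__(), groups[b].__len__()
        se = np.sqrt(var_base * (1.0 / na + 1.0 / nb))
        z = (mean_ranks[a] - mean_ranks[b]) / se
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "z": z,
                "p": p,
                "p_adjusted": min(1.0, p * len(pairs)),
            }
        )
    return pd.DataFrame(rows)


def f1_model_comparison(
    results_by_model_and_condition: dict[str, dict[str, list[ConfusionResult]]],
) -> dict[str, pd.DataFrame]:
    """Rank-based model comparison of F1-across-isohypse samples.

    Input maps condition -> model -> sweep results. Per condition, a
    Kruskal-Wallis H test across the models' F1 samples is followed by
    pairwise Dunn tests with Bonferroni adjustment. Models with fewer than
    2 sweep points are excluded with a warning column in the output.
    Returns ``{"kruskal": ..., "dunn": ...}`` DataFrames.
    """
    kw_rows = []
    dunn_frames = []
    for condition, by_model in results_by_model_and_condition.items():
        samples = {
            model: np.array([r.f1 for r in sweep])
            for model, sweep in by_model.items()
            if len(sweep) >= 2
        }
        excluded = sorted(set(by_model) - set(samples))
        if len(samples) < 2:
            continue
        h, p = stats.kruskal(*samples.values())
        kw_rows.append(
            {
                "condition": condition,
                "H": h,
                "p": p,
                "n_models": len(samples),
                "excluded": ",".join(excluded),
            }
        )
        dd = dunn_test(samples)
        dd.insert(0, "condition", condition)
        dunn_frames.append(dd)
    return {
        "kruskal": pd.DataFrame(kw_rows),
        "dunn": (
            pd.concat(dunn_frames, ignore_index=True)
            if dunn_frames
            else pd.DataFrame()
        ),
    }


# model name -> (kind, n snapshots, memory circle radius cm); None = ALV
MODEL_SPECS = {
    "ALV": None,
    "B1": ("brightness", 1, 0.0),
    "CwN1": ("cwn", 1, 0.0),
    "B4": ("brightness", 4, 15.0),
    "B8": ("brightness", 8, 15.0),
    "CwN4": ("cwn", 4, 15.0),
    "CwN8": ("cwn", 8, 15.0),
    "B4@5": ("brightness", 4, 5.0),
    "B8@5": ("brightness", 8, 5.0),
    "CwN4@5": ("cwn", 4, 5.0),
}


@dataclass
class PipelineReport:
    """Everything one pipeline run computed, plus a text summary."""

    condition: str
    basin_tables: dict[str, pd.DataFrame]
    confusion_at_default: pd.DataFrame
    sweeps: dict[str, list[ConfusionResult]]
    statistics: dict[str, pd.DataFrame]
    search_map: SearchMap | None
    potentials: dict[str, HomingPotential]
    timings: dict[str, float] = field(default_factory=dict)

    def summary(self) -> str:
        lines = [f"condition {self.condition}"]
        for model, table in self.basin_tables.items():
            for _, row in table.iterrows():
                lines.append(
                    f"  {model}: {row['point']} "
                    f"{'inside' if row['in_basin'] else 'outside'} a basin "
                    f"(nearest minimum {row['dist_to_nearest_minimum_cm']:.1f} cm)"
                )
        if len(self.confusion_at_default):
            for _, row in self.confusion_at_default.iterrows():
                lines.append(
                    f"  {row['model']}: F1={row['f1']:.3f} "
                    f"precision={row['precision']:.3f} recall={row['recall']:.3f}"
                )
        return "\n".join(lines)


def potential_for_model(
    model: str,
    test_scene,
    habituation_scene,
    grid,
    z_mem: float | None = None,
    phase: float = 0.0,
) -> HomingPotential:
    """Vector field and potential of one named model on a rendered grid."""
    if model not in MODEL_SPECS:
        raise ValueError(f"unknown model {model!r}; choose from {sorted(MODEL_SPECS)}")
    spec = MODEL_SPECS[model]
    if spec is None:
        vf = alv_field(test_scene, habituation_scene, grid)
    else:
        kind, n, r_mem = spec
        mem = acquire_memory(
            habituation_scene,
            kind,
            n,
            r_mem,
            z_mem=grid.altitude if z_mem is None else z_mem,
            phase=phase,
            deg_per_px=grid.deg_per_px,
        )
        vf = (
            single_snapshot_field(grid, mem)
            if n == 1
            else multi_snapshot_field(grid, mem)
        )
    return helmholtz_hodge(vf)


def run_pipeline(config: dict) -> PipelineReport:
    """Run the full analysis for one condition described by a config dict.

    Recognized keys: the scene configuration (see
    :func:`beehoming.scene.scene_from_config`), plus ``models`` (list of
    names from MODEL_SPECS), ``altitude``, ``spacing``, ``deg_per_px``,
    ``isohypse`` (default 0.15), ``trajectories`` (a CSV path) or
    ``scenario`` + ``seed`` + ``n_flights`` for synthetic flights, and
    ``sweep`` bounds. Deterministic given the config and seed.
    """
    timings: dict[str, float] = {}
    t0 = time.perf_counter()
    test_scene = scene_from_config(config)
    hab_cfg = dict(config)
    hab_cfg["condition"] = {"theta_cyl": 0.0, "theta_str": 0.0}
    habituation = scene_from_config(hab_cfg)
    condition = test_scene.condition
    geometry = test_scene.geometry

    models = config.get("models", ["ALV", "B8", "CwN4"])
    altitude = float(config.get("altitude", 6.0))
    spacing = float(config.get("spacing", 2.0))
    deg_per_px = float(config.get("deg_per_px", 1.0))
    isohypse = float(config.get("isohypse", 0.15))

    grid = build_view_grid(test_scene, spacing=spacing, altitude=altitude, deg_per_px=deg_per_px)
    timings["render"] = time.perf_counter() - t0

    p_cyl, p_str = fictive_nests(condition, geometry)
    poi = {
        "nest": geometry.nest_position,
        "fictive_nest_cylinders": p_cyl,
        "fictive_nest_stripes": p_str,
        "arena_centre": np.zeros(2),
    }

    t0 = time.perf_counter()
    potentials = {}
    basin_tables = {}
    for model in models:
        pot = potential_for_model(model, test_scene, habituation, grid)
        potentials[model] = pot
        basin_tables[model] = basin_report(pot, poi, isohypse)
    timings["models"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    search_map = None
    flights = None
    if "trajectories" in config:
        flights = read_trajectories(config["trajectories"], geometry.radius)
    elif "scenario" in config:
        flights = paper_like_dataset(
            condition,
            config["scenario"],
            geometry=geometry,
            n_flights=int(config.get("n_flights", 8)),
            duration=float(config.get("duration", 300.0)),
            seed=int(config.get("seed", 0)),
        )
    conf_rows = []
    sweeps: dict[str, list[ConfusionResult]] = {}
    statistics: dict[str, pd.DataFrame] = {}
    if flights is not None:
        filtered = altitude_band_filter(flights)
        lattice = lattice_for_arena(geometry.radius, spacing)
        search_map = kde_search_map(filtered, lattice)
        s_mask = search_area(search_map)
        for model, pot in potentials.items():
            basins = extract_basins(pot, isohypse)
            b_mask = np.zeros_like(pot.mask)
            for b in basins:
                b_mask |= b.cells
            c = confusion(
                s_mask, b_mask, pot.mask, isohypse, condition.label, model
            )
            conf_rows.append(
                {
                    "model": model,
                    "tp": c.tp,
                    "fp": c.fp,
                    "fn": c.fn,
                    "tn": c.tn,
                    "precision": c.precision,
                    "recall": c.recall,
                    "f1": c.f1,
                    "degenerate": c.degenerate,
                }
            )
            sweeps[model] = isohypse_sweep(pot, s_mask)
        if len(sweeps) >= 2:
            statistics = f1_model_comparison({condition.label: sweeps})
    timings["behaviour"] = time.perf_counter() - t0

    return PipelineReport(
        condition=condition.label,
        basin_tables=basin_tables,
        confusion_at_default=pd.DataFrame(conf_rows),
        sweeps=sweeps,
        statistics=statistics,
        search_map=search_map,
        potentials=potentials,
        timings=timings,
    )
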