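"""Sensitivity analysis: Morris elementary-effects screening and a full
factorial design over the meadow parameters.

The screening follows the elementary-effects idea — one-factor-at-a-time
perturbations, no assumptions about the model — in an *individually
randomized OAT* variant: each trajectory draws a random base point on the
level grid and perturbs each parameter once, in random order, from that same
base (a radial/star design), rather than walking a path through parameter
space.  The classic walking trajectory is available as an option.  Effects
are computed on parameters rescaled to [0, 1] over their ranges, so they are
comparable across parameters with different units.

The default screening ranges follow the study design: the four parameters
(rough-ground area and search distance, meadow area and search distance)
varied around their reference values by ±70% for rgr_dist and ±67% for the
other three.

The factorial design crosses meadow area requirement (9.5-17.5 ha, step
1 ha) with meadow search distance (800-1600 m, step 100 m): 81 cells, each
evaluated with fixed per-cell seeds shared across cells (common random
numbers), so the response surface is reproducible and order-invariant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from buteo_abm.engine import (
    RunConfig,
    SimulationParams,
    derive_seeds,
    run_simulation,
)
from buteo_abm.landscape import InvalidInputError, ResourceMap, StudyMask
from buteo_abm.ranges import abundance, pairwise_overlaps, percentage_polygon

log = logging.getLogger(__name__)

#: The six standard screening outputs.
STANDARD_OUTPUTS: tuple[str, ...] = (
    "abundance",
    "overlap80_pct",
    "core40_area_ha",
    "core80_area_ha",
    "core40_perimeter_m",
    "core80_perimeter_m",
)

#: Relative screening ranges around the reference values.
DEFAULT_REL_RANGES: dict[str, float] = {
    "rgr_area_ha": 0.67,
    "rgr_dist_m": 0.70,
    "mead_area_ha": 0.67,
    "mead_dist_m": 0.67,
}


@dataclass
class MorrisSpec:
    """Screening design: parameters, relative ranges, levels, trajectories."""

    parameters: dict[str, float] = field(default_factory=dict)  # name -> reference value
    rel_ranges: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_REL_RANGES))
    n_levels: int = 4
    n_trajectories: int = 10
    outputs: tuple[str, ...] = STANDARD_OUTPUTS
    scheme: str = "radial"  # "radial" (individually randomized OAT) or "classic"

    def __post_init__(self) -> None:
        if self.n_levels < 2:
            raise InvalidInputError("n_levels must be >= 2")
        if self.n_trajectories < 1:
            raise InvalidInputError("n_trajectories must be >= 1")
        for name in self.parameters:
            if self.rel_ranges.get(name, 0) <= 0:
                raise InvalidInputError(f"parameter {name} needs a positive relative range")

    def bounds(self, name: str) -> tuple[float, float]:
        ref = self.parameters[name]
        rel = self.rel_ranges[name]
        return ref * (1 - rel), ref * (1 + rel)

    @classmethod
    def from_params(
        cls, params: SimulationParams, **kwargs
    ) -> "MorrisSpec":
        refs = {
            "rgr_area_ha": params.rgr_area_ha,
            "rgr_dist_m": params.rgr_dist_m,
            "mead_area_ha": params.mead_area_ha,
            "mead_dist_m": params.mead_dist_m,
        }
        return cls(parameters=refs, **kwargs)


def morris_screening(
    evaluator: Callable[[Mapping[str, float]], Mapping[str, float]],
    spec: MorrisSpec,
    seed: int = 0,
    return_raw: bool = False,
) -> pd.DataFrame | tuple[pd.DataFrame, pd.DataFrame]:
    """Elementary-effects screening of ``evaluator`` under ``spec``.

    The evaluator maps a parameter dict to an output dict.  Each elementary
    effect is Δoutput / Δparameter with the parameter rescaled to [0, 1]
    over its range.  Returns per (parameter, output): the mean (mu),
    mean-absolute (mu_star) and standard deviation (sigma) of effects, and
    the effect count.  Failed evaluations are recorded as missing and
    logged.
    """
    rng = np.random.default_rng(seed)
    names = list(spec.parameters)
    k = len(names)
    p = spec.n_levels
    delta = p / (2.0 * (p - 1))  # classic Morris step on the unit grid
    base_levels = np.arange(p) / (p - 1)  # unit-scaled grid levels

    def to_physical(unit: np.ndarray) -> dict[str, float]:
        out = {}
        for j, name in enumerate(names):
            lo, hi = spec.bounds(name)
            out[name] = lo + unit[j] * (hi - lo)
        return out

    def safe_eval(point: dict[str, float]):
        try:
            return dict(evaluator(point))
        except Exception:  # pragma: no cover - evaluator failures are data-dependent
            log.exception("evaluator failed at %s", point)
            return None

    effects: list[dict] = []
    for _ in range(spec.n_trajectories):
        # base point on the grid, leaving room for a +delta step
        base = np.array([rng.choice(base_levels[base_levels + delta <= 1 + 1e-12])
                         for _ in range(k)])
        order = rng.permutation(k)
        y_base = safe_eval(to_physical(base))
        current = base.copy()
        for j in order:
            step = delta if current[j] + delta <= 1 + 1e-12 else -delta
            perturbed = current.copy()
            perturbed[j] += step
            y_pert = safe_eval(to_physical(perturbed))
            if y_base is not None and y_pert is not None:
                for out_name in spec.outputs:
                    ya, yb = y_base.get(out_name), y_pert.get(out_name)
                    ee = (yb - ya) / step if ya is not None and yb is not None else np.nan
                    effects.append({"parameter": names[j], "output": out_name, "effect": ee})
            else:
                for out_name in spec.outputs:
                    effects.append({"parameter": names[j], "output": out_name, "effect": np.nan})
            if spec.scheme == "classic":
                current = perturbed
                y_base = y_pert
    raw = pd.DataFrame(effects)
    agg = (
        raw.groupby(["parameter", "output"])["effect"]
        .agg(mu="mean", mu_star=lambda e: np.nanmean(np.abs(e)), sigma="std",
             n_effects="count")
        .reset_index()
    )
    return (agg, raw) if return_raw else agg


@dataclass
class FactorialSpec:
    """Full factorial axes over meadow area requirement and search distance."""

    mead_areas_ha: tuple[float, ...] = tuple(np.arange(9.5, 17.5 + 0.5, 1.0))
    mead_dists_m: tuple[float, ...] = tuple(np.arange(800.0, 1600.0 + 50.0, 100.0))
    runs_per_cell: int = 6

    def __post_init__(self) -> None:
        if not self.mead_areas_ha or not self.mead_dists_m:
            raise InvalidInputError("factorial axes must be non-empty")
        if self.runs_per_cell < 1:
            raise InvalidInputError("runs_per_cell must be >= 1")

    @property
    def n_cells(self) -> int:
        return len(self.mead_areas_ha) * len(self.mead_dists_m)


def simulation_outputs(
    rmap: ResourceMap,
    mask: StudyMask | None,
    params: SimulationParams,
    seeds: list[int],
) -> dict[str, float]:
    """The six standard outputs, averaged over runs with the given seeds."""
    per_run: list[dict[str, float]] = []
    for seed in seeds:
        result = run_simulation(rmap, mask, params, RunConfig(seed=seed))
        out: dict[str, float] = {"abundance": float(abundance(result, mask))
                                 if mask is not None else float(result.n_settled)}
        cores40, cores80 = [], []
        for b in result.buzzards:
            pts = b.locations()
            cores40.append(percentage_polygon(pts, 40, bird_id=b.name))
            cores80.append(percentage_polygon(pts, 80, bird_id=b.name))
        out["core40_area_ha"] = float(np.mean([c.area_ha for c in cores40])) if cores40 else np.nan
        out["core80_area_ha"] = float(np.mean([c.area_ha for c in cores80])) if cores80 else np.nan
        out["core40_perimeter_m"] = float(np.mean([c.perimeter_m for c in cores40])) if cores40 else np.nan
        out["core80_perimeter_m"] = float(np.mean([c.perimeter_m for c in cores80])) if cores80 else np.nan
        overlaps = pairwise_overlaps([c for c in cores80 if c.area_ha > 0])
        out["overlap80_pct"] = float(np.mean([o.overlap_pct for o in overlaps])) if overlaps else 0.0
        per_run.append(out)
    keys = per_run[0].keys() if per_run else STANDARD_OUTPUTS
    return {key: float(np.nanmean([r.get(key, np.nan) for r in per_run])) for key in keys}


def make_simulation_evaluator(
    rmap: ResourceMap,
    mask: StudyMask | None,
    base_params: SimulationParams,
    n_runs: int = 3,
    base_seed: int = 0,
) -> Callable[[Mapping[str, float]], dict[str, float]]:
    """Evaluator for :func:`morris_screening` backed by the simulation.

    The same run seeds are used at every parameter point (common random
    numbers), so elementary effects measure the parameter change, not seed
    noise.
    """
    seeds = derive_seeds(base_seed, n_runs)

    def evaluate(point: Mapping[str, float]) -> dict[str, float]:
        params = base_params.replace(**{k: float(v) for k, v in point.items()})
        return simulation_outputs(rmap, mask, params, seeds)

    return evaluate


def full_factorial(
    rmap: ResourceMap,
    mask: StudyMask | None,
    base_params: SimulationParams,
    spec: FactorialSpec,
    base_seed: int = 0,
) -> pd.DataFrame:
    """Mean abundance on every (mead_area, mead_dist) cell of the design.

    Per-cell run seeds are identical across cells (common random numbers),
    making the table deterministic and invariant to evaluation order.
    Returns one row per cell: mead_area_ha, mead_dist_m, mean_abundance,
    sd_abundance, n_runs.
    """
    from buteo_abm.landscape import full_mask

    if mask is None:
        mask = full_mask(rmap)
    seeds = derive_seeds(base_seed, spec.runs_per_cell)
    rows = []
    for area in spec.mead_areas_ha:
        for dist in spec.mead_dists_m:
            params = base_params.replace(mead_area_ha=float(area), mead_dist_m=float(dist))
            counts = []
            for seed in seeds:
                result = run_simulation(rmap, mask, params, RunConfig(seed=seed))
                counts.append(abundance(result, mask))
            rows.append({
                "mead_area_ha": float(area),
                "mead_dist_m": float(dist),
                "mean_abundance": float(np.mean(counts)),
                "sd_abundance": float(np.std(counts, ddof=1)) if len(counts) > 1 else 0.0,
                "n_runs": len(counts),
            })
    return pd.DataFrame(rows)


def marginal_means(table: pd.DataFrame, axis: str) -> pd.Series:
    """Marginal mean abundance along one factorial axis."""
    return table.groupby(axis)["mean_abundance"].mean()
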