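"""Meadow-to-woodland landscape-change scenarios.

Scenarios emulate a rural economy gradually converting meadow to woodland
for timber and carbon: whole meadow plots of economically viable size
(>= 20 ha by default) are drawn uniformly at random, without replacement,
and converted to woodland until the cumulative converted area first reaches
the target fraction of the total eligible area.  Plots are indivisible
economic units, so the target can be overshot by at most the largest
eligible plot; the realized conversion is reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from buteo_abm.landscape import InvalidInputError, Patch, Resource, ResourceMap, label_patches

log = logging.getLogger(__name__)

#: Smallest economically viable plot for meadow-to-woodland conversion (ha).
DEFAULT_MIN_PLOT_HA = 20.0


@dataclass
class ScenarioSpec:
    """Target conversion fraction of eligible meadow area, threshold and seed."""

    fraction: float
    min_plot_area_ha: float = DEFAULT_MIN_PLOT_HA
    seed: int = 0
    connectivity: int = 8

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise InvalidInputError(f"fraction must be in [0, 1], got {self.fraction}")
        if not self.min_plot_area_ha >= 0:
            raise InvalidInputError("min_plot_area_ha must be non-negative")


@dataclass
class ConversionReport:
    """What a conversion actually did: plots chosen and areas, for provenance."""

    target_fraction: float
    eligible_area_ha: float
    target_area_ha: float
    converted_area_ha: float
    plots_converted: list[Patch] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "plot_index": range(len(self.plots_converted)),
                "area_ha": [p.area_ha for p in self.plots_converted],
                "n_pixels": [len(p) for p in self.plots_converted],
            }
        )


def eligible_plots(
    rmap: ResourceMap,
    min_plot_area_ha: float = DEFAULT_MIN_PLOT_HA,
    connectivity: int = 8,
) -> list[Patch]:
    """Meadow patches at or above the economic-viability threshold (inclusive)."""
    return [
        p
        for p in label_patches(rmap, Resource.MEADOW, connectivity=connectivity)
        if p.area_ha >= min_plot_area_ha
    ]


def convert_meadow(
    rmap: ResourceMap, spec: ScenarioSpec, return_report: bool = False
) -> ResourceMap | tuple[ResourceMap, ConversionReport]:
    """Convert randomly chosen eligible meadow plots to woodland.

    Whole plots are drawn uniformly at random without replacement until the
    cumulative converted area first reaches ``fraction`` x (total eligible
    area).  Only meadow pixels change; everything else is conserved exactly.
    Deterministic for a fixed ``spec.seed``.
    """
    plots = eligible_plots(rmap, spec.min_plot_area_ha, spec.connectivity)
    eligible_area = sum(p.area_ha for p in plots)
    target = spec.fraction * eligible_area
    out = rmap.copy()
    report = ConversionReport(
        target_fraction=spec.fraction,
        eligible_area_ha=eligible_area,
        target_area_ha=target,
        converted_area_ha=0.0,
    )
    if spec.fraction > 0 and not plots:
        log.warning("no eligible meadow plots (threshold %.1f ha); map unchanged", spec.min_plot_area_ha)
        return (out, report) if return_report else out
    if target > 0:
        # Stable ordering before shuffling keeps the draw reproducible.
        ordered = sorted(plots, key=lambda p: min(p.pixels))
        rng = np.random.default_rng(spec.seed)
        order = rng.permutation(len(ordered))
        converted = 0.0
        for i in order:
            if converted >= target:
                break
            plot = ordered[i]
            for c, r in plot.pixels:
                out.grid[r, c] = int(Resource.WOODLAND)
            converted += plot.area_ha
            report.plots_converted.append(plot)
        report.converted_area_ha = converted
    return (out, report) if return_report else out
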