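"""Small culture-level arithmetic: reprogramming efficiency and
post-irradiation survival fractions."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np


@dataclass(frozen=True)
class EfficiencyResult:
    """Colony-formation efficiency as a percentage of plated cells."""

    colonies: int
    cells_plated: int
    efficiency_percent: float


@dataclass(frozen=True)
class SurvivalPoint:
    """Survival at one radiation dose, normalised to non-irradiated controls."""

    dose_gy: float
    replicate_counts: tuple[float, ...]
    control_counts: tuple[float, ...]
    percent_mean: float
    percent_sd: float


def reprogramming_efficiency(colonies: int, cells_plated: int) -> EfficiencyResult:
    """Percent of plated cells that yielded an iPS colony."""
    if cells_plated <= 0:
        raise ValueError("cells_plated must be positive")
    if colonies < 0:
        raise ValueError("colonies must be non-negative")
    if colonies > cells_plated:
        raise ValueError("cannot have more colonies than plated cells")
    return EfficiencyResult(
        colonies=colonies,
        cells_plated=cells_plated,
        efficiency_percent=100.0 * colonies / cells_plated,
    )


def efficiency_ratio(a: EfficiencyResult, b: EfficiencyResult) -> float:
    """Fold difference a/b of two efficiencies (assumes comparable plating)."""
    if b.efficiency_percent <= 0:
        raise ValueError("reference efficiency must be positive")
    return a.efficiency_percent / b.efficiency_percent


def survival_fraction(
    irradiated: Sequence[float],
    control: Sequence[float],
    dose_gy: float = math.nan,
) -> SurvivalPoint:
    """Viable-cell survival relative to matched non-irradiated controls.

    Each irradiated replicate is expressed as a percentage of the control
    mean (controls are 100% by construction); the point reports mean +/- SD
    over replicates. Scale-invariant to the counting units.
    """
    if len(irradiated) == 0 or len(control) == 0:
        raise ValueError("replicate lists must be non-empty")
    control_mean = float(np.mean(control))
    if control_mean <= 0:
        raise ValueError("control mean must be positive")
    percents = 100.0 * np.asarray(irradiated, dtype=float) / control_mean
    sd = float(np.std(percents, ddof=1)) if len(percents) > 1 else 0.0
    return SurvivalPoint(
        dose_gy=dose_gy,
        replicate_counts=tuple(float(x) for x in irradiated),
        control_counts=tuple(float(x) for x in control),
        percent_mean=float(np.mean(percents)),
        percent_sd=sd,
    )
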