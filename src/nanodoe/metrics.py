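"""Closed-form formulation and wound metrics.

Entrapment efficiency (EE%) quantifies the drug fraction incorporated in
nanoparticles, measured indirectly from the free drug left in the
supernatant.  Cumulative drug release follows a Franz-diffusion-cell
protocol where a fixed sample volume is withdrawn and replaced with fresh
buffer at each time point; the literal release formula ignores the drug
mass removed in earlier samples, and an opt-in correction adds it back.
The wound closure rate is the fractional reduction of wound area from
day 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "ReleaseProfile",
    "WoundSeries",
    "entrapment_efficiency",
    "cumulative_release",
    "wound_closure_rate",
]


def entrapment_efficiency(total_drug: float, free_drug: float) -> float:
    """EE% = (total - free) / total * 100."""
    if total_drug <= 0:
        raise ValueError("total drug amount must be positive")
    if free_drug < 0 or free_drug > total_drug:
        raise ValueError("free drug must lie in [0, total]")
    return (total_drug - free_drug) / total_drug * 100.0


@dataclass(frozen=True)
class ReleaseProfile:
    """Sampled concentrations from a fixed-volume-replacement release assay.

    times : sampling times in hours, strictly increasing
    sampled_conc : drug concentration (mass/volume) in each withdrawn sample
    receptor_volume : receptor compartment volume, mL
    sample_volume : withdrawn (and replaced) volume per time point, mL
    dose : total drug loaded in the donor, mg
    """

    times: tuple[float, ...]
    sampled_conc: tuple[float, ...]
    receptor_volume: float
    sample_volume: float
    dose: float

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.sampled_conc, dtype=float)
        if len(t) != len(c) or len(t) == 0:
            raise ValueError("times and sampled_conc must be nonempty and aligned")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(c < 0):
            raise ValueError("concentrations must be nonnegative")
        if not 0 < self.sample_volume < self.receptor_volume:
            raise ValueError("require 0 < sample_volume < receptor_volume")
        if self.dose <= 0:
            raise ValueError("dose must be positive")


def cumulative_release(
    profile: ReleaseProfile,
    correct_sampling: bool = False,
    tolerance: float = 0.5,
) -> list[float]:
    """Cumulative drug release percentages, Q_i / Q_r * 100.

    With ``correct_sampling=False`` (default) Q_i is simply the measured
    concentration times the receptor volume — the literal assay formula.
    With the correction on, Q_i additionally accumulates the drug mass
    removed in all earlier samples (sample_volume times each earlier
    concentration), making the series nondecreasing for nonnegative
    concentrations.

    A release percentage exceeding 100 + ``tolerance`` (percentage points)
    indicates inconsistent inputs and raises.
    """
    conc = np.asarray(profile.sampled_conc, dtype=float)
    q = conc * profile.receptor_volume
    if correct_sampling:
        removed = np.concatenate([[0.0], np.cumsum(conc[:-1] * profile.sample_volume)])
        q = q + removed
    pct = q / profile.dose * 100.0
    if np.any(pct > 100.0 + tolerance):
        raise ValueError(
            f"cumulative release exceeds 100% + {tolerance} "
            f"(max {pct.max():.2f}%): inconsistent profile"
        )
    return [float(p) for p in pct]


@dataclass(frozen=True)
class WoundSeries:
    """Wound areas (mm^2) tracked over days; day 0 is the initial wound."""

    day: tuple[int, ...]
    area: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.day) != len(self.area) or len(self.day) == 0:
            raise ValueError("day and area must be nonempty and aligned")
        if 0 not in self.day:
            raise ValueError("day 0 (initial wound area) is required")
        if any(a < 0 for a in self.area):
            raise ValueError("wound areas must be nonnegative")


def wound_closure_rate(series: WoundSeries, t: int) -> float:
    """Closure % at day t: (W0 - Wt) / W0 * 100."""
    lookup = dict(zip(series.day, series.area))
    w0 = lookup[0]
    if w0 == 0:
        raise ValueError("initial wound area W0 must be positive")
    if t not in lookup:
        raise KeyError(f"day {t} not present in series (have {sorted(lookup)})")
    return (w0 - lookup[t]) / w0 * 100.0
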