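"""Three-factor Box-Behnken designs and coded/actual level conversion.

A Box-Behnken design (BBD) for three factors consists of the 12 edge
midpoints of the design cube (every +/-1 combination of each factor pair,
with the third factor held at its center) plus replicated center runs.
Factor levels are expressed both in *actual* units (mg, % w/v, ...) and in
*coded* units, where the center maps to 0 and the low/high levels to -1/+1:

    coded = (actual - center) / ((high - low) / 2)

Coded columns of a BBD are mutually orthogonal, which makes the regression
coefficients of a response-surface model independent contrasts.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FactorSpec",
    "Run",
    "DesignTable",
    "code_level",
    "decode_level",
    "build_bbd",
]


@dataclass(frozen=True)
class FactorSpec:
    """One design factor with its low/center/high actual levels."""

    name: str
    low: float
    center: float
    high: float
    units: str = ""

    def __post_init__(self) -> None:
        if not (self.low < self.center < self.high):
            raise ValueError(
                f"factor {self.name!r}: require low < center < high, "
                f"got {self.low}, {self.center}, {self.high}"
            )
        midpoint = (self.low + self.high) / 2.0
        if not np.isclose(self.center, midpoint):
            warnings.warn(
                f"factor {self.name!r}: center {self.center} is not the "
                f"midpoint {midpoint} of [low, high]; coded levels remain "
                "well-defined but the design loses level symmetry",
                UserWarning,
                stacklevel=2,
            )

    @property
    def half_range(self) -> float:
        return (self.high - self.low) / 2.0

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "low": self.low,
            "center": self.center,
            "high": self.high,
            "units": self.units,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FactorSpec":
        return cls(
            name=d["name"],
            low=float(d["low"]),
            center=float(d["center"]),
            high=float(d["high"]),
            units=d.get("units", ""),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "FactorSpec":
        return cls.from_dict(json.loads(s))


def code_level(spec: FactorSpec, actual: float) -> float:
    """Map an actual level to coded units; the exact inverse of decode_level.

    Values outside [low, high] are permitted (extrapolation) but warned about.
    """
    if spec.high == spec.low:
        raise ValueError(f"degenerate factor {spec.name!r}: high == low")
    coded = (actual - spec.center) / spec.half_range
    if abs(coded) > 1.0 + 1e-12:
        warnings.warn(
            f"actual level {actual} for factor {spec.name!r} codes to "
            f"{coded:.4g}, outside [-1, 1]",
            UserWarning,
            stacklevel=2,
        )
    return coded


def decode_level(spec: FactorSpec, coded: float) -> float:
    """Map a coded level back to actual units."""
    if spec.high == spec.low:
        raise ValueError(f"degenerate factor {spec.name!r}: high == low")
    return spec.center + coded * spec.half_range


@dataclass(frozen=True)
class Run:
    run_id: int
    coded: tuple[float, float, float]
    actual: tuple[float, float, float]


# Canonical BBD run order: factor-pair blocks (1,2), (1,3), (2,3), each in
# (-,-), (+,-), (-,+), (+,+) sign order, followed by the center replicates.
_PAIRS = ((0, 1), (0, 2), (1, 2))
_SIGNS = ((-1, -1), (1, -1), (-1, 1), (1, 1))


@dataclass
class DesignTable:
    """A coded + actual run matrix for a three-factor BBD."""

    factors: tuple[FactorSpec, FactorSpec, FactorSpec]
    runs: list[Run] = field(default_factory=list)
    n_center: int = 0

    @property
    def n_runs(self) -> int:
        return len(self.runs)

    @property
    def factor_names(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.factors)

    @property
    def coded_matrix(self) -> np.ndarray:
        """(n_runs, 3) array of coded levels, run order preserved."""
        return np.array([r.coded for r in self.runs], dtype=float)

    @property
    def actual_matrix(self) -> np.ndarray:
        return np.array([r.actual for r in self.runs], dtype=float)

    def to_dataframe(self) -> pd.DataFrame:
        cols: dict[str, list] = {"run_id": [r.run_id for r in self.runs]}
        for j, f in enumerate(self.factors):
            cols[f"{f.name}_coded"] = [r.coded[j] for r in self.runs]
            cols[f"{f.name}_actual"] = [r.actual[j] for r in self.runs]
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, factors: Sequence[FactorSpec]) -> "DesignTable":
        factors = tuple(factors)
        if len(factors) != 3:
            raise ValueError("exactly three factors required")
        df = pd.read_csv(path)
        runs = []
        for _, row in df.iterrows():
            coded = tuple(float(row[f"{f.name}_coded"]) for f in factors)
            actual = tuple(float(row[f"{f.name}_actual"]) for f in factors)
            runs.append(Run(int(row["run_id"]), coded, actual))
        n_center = sum(1 for r in runs if all(c == 0.0 for c in r.coded))
        return cls(factors=factors, runs=runs, n_center=n_center)

    def validate(self) -> None:
        """Check the structural BBD invariants; raise on violation."""
        if self.n_runs != 12 + self.n_center:
            raise ValueError(
                f"BBD run count {self.n_runs} != 12 + {self.n_center} center runs"
            )
        coded = self.coded_matrix
        for row in coded:
            n_zero = int(np.sum(row == 0.0))
            n_pm = int(np.sum(np.abs(row) == 1.0))
            if not ((n_zero == 3) or (n_zero == 1 and n_pm == 2)):
                raise ValueError(f"run with coded levels {row} is not a BBD point")
        if not np.allclose(coded.sum(axis=0), 0.0):
            raise ValueError("coded factor columns do not sum to zero")


def build_bbd(
    factors: Sequence[FactorSpec], n_center: int = 5
) -> DesignTable:
    """Construct a three-factor Box-Behnken design.

    Parameters
    ----------
    factors : sequence of three FactorSpec
        The design factors, in order (x1, x2, x3).
    n_center : int
        Number of center-point replicates (>= 1). With ``n_center=5`` the
        design has 17 runs, the standard choice for three factors.

    Returns
    -------
    DesignTable
        Runs in the canonical order: factor-pair blocks (1,2), (1,3), (2,3),
        each in (-,-), (+,-), (-,+), (+,+) sign order, then the center runs.
    """
    factors = tuple(factors)
    if len(factors) != 3:
        raise ValueError(f"a three-factor BBD requires exactly 3 factors, got {len(factors)}")
    if n_center < 1:
        raise ValueError(f"n_center must be >= 1, got {n_center}")

    runs: list[Run] = []
    run_id = 1
    for i, j in _PAIRS:
        for si, sj in _SIGNS:
            coded = [0.0, 0.0, 0.0]
            coded[i] = float(si)
            coded[j] = float(sj)
            actual = tuple(decode_level(f, c) for f, c in zip(factors, coded))
            runs.append(Run(run_id, tuple(coded), actual))
            run_id += 1
    center_actual = tuple(f.center for f in factors)
    for _ in range(n_center):
        runs.append(Run(run_id, (0.0, 0.0, 0.0), center_actual))
        run_id += 1

    table = DesignTable(factors=factors, runs=runs, n_center=n_center)
    table.validate()
    return table
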