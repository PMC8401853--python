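"""Multi-response desirability optimization and checkpoint validation.

Each predicted response is mapped to a desirability d in [0, 1] by a
Derringer-Suich ramp (linear for weight 1): for a maximized response d
rises from 0 at the lower anchor to 1 at the upper anchor; for a minimized
response the ramp is mirrored, and the goal's weight enters as the ramp
exponent.  The overall desirability is the geometric mean

    D = (prod_i d_i)^(1/n),

maximized over the coded design cube by an exhaustive grid search followed
by a bounded Nelder-Mead polish started from the best grid point, so the
whole procedure is deterministic.

Checkpoint validation compares a measured formulation against model
predictions via the absolute prediction-error percentage
|estimated - expected| / estimated * 100.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import minimize

from .design import DesignTable, decode_level
from .models import FittedModel, predict

__all__ = [
    "DesirabilityGoal",
    "OptimizationResult",
    "ValidationReport",
    "desirability",
    "overall_desirability",
    "goals_from_observed",
    "optimize_desirability",
    "prediction_error_pct",
    "validate_checkpoint",
]


@dataclass(frozen=True)
class DesirabilityGoal:
    response: str
    direction: str  # "minimize" | "maximize"
    anchor_low: float
    anchor_high: float
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.direction not in ("minimize", "maximize"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if not self.anchor_low < self.anchor_high:
            raise ValueError(
                f"anchor_low must be < anchor_high, got "
                f"{self.anchor_low} >= {self.anchor_high}"
            )
        if self.weight <= 0:
            raise ValueError("weight must be positive")


def desirability(value, goal: DesirabilityGoal):
    """Derringer-Suich one-sided ramp; accepts scalars or arrays."""
    v = np.asarray(value, dtype=float)
    span = goal.anchor_high - goal.anchor_low
    frac = np.clip((v - goal.anchor_low) / span, 0.0, 1.0)
    if goal.direction == "minimize":
        frac = 1.0 - frac
    d = frac**goal.weight
    return float(d) if np.isscalar(value) else d


def overall_desirability(values: Mapping[str, float | np.ndarray],
                         goals: Sequence[DesirabilityGoal]):
    """Geometric mean of the individual desirabilities.

    Each individual desirability already carries its goal's weight as the
    ramp exponent, so the overall score is the plain geometric mean
    D = (prod_i d_i)^(1/n).
    """
    if not goals:
        raise ValueError("at least one desirability goal required")
    log_d = None
    for g in goals:
        d = np.asarray(desirability(values[g.response], g), dtype=float)
        with np.errstate(divide="ignore"):
            term = np.where(d > 0.0, np.log(np.maximum(d, 1e-300)), -np.inf)
        log_d = term if log_d is None else log_d + term
    D = np.exp(log_d / len(goals))
    D = np.where(np.isfinite(D), D, 0.0)
    return float(D) if D.ndim == 0 else D


def goals_from_observed(
    data_means: Mapping[str, np.ndarray],
    directions: Mapping[str, str],
    weights: Mapping[str, float] | None = None,
) -> list[DesirabilityGoal]:
    """Default goals: anchors at each response's observed min/max."""
    weights = weights or {}
    goals = []
    for name, direction in directions.items():
        y = np.asarray(data_means[name], dtype=float)
        goals.append(
            DesirabilityGoal(
                response=name,
                direction=direction,
                anchor_low=float(y.min()),
                anchor_high=float(y.max()),
                weight=float(weights.get(name, 1.0)),
            )
        )
    return goals


@dataclass
class OptimizationResult:
    coded_optimum: tuple[float, float, float]
    actual_optimum: tuple[float, float, float]
    predicted: dict[str, float]
    individual_desirabilities: dict[str, float]
    overall_D: float

    def to_dict(self) -> dict:
        return {
            "coded_optimum": list(self.coded_optimum),
            "actual_optimum": list(self.actual_optimum),
            "predicted": self.predicted,
            "individual_desirabilities": self.individual_desirabilities,
            "overall_D": self.overall_D,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def _predict_all(models: Mapping[str, FittedModel], pts: np.ndarray) -> dict[str, np.ndarray]:
    return {name: np.atleast_1d(predict(m, pts)) for name, m in models.items()}


def optimize_desirability(
    models: Mapping[str, FittedModel],
    goals: Sequence[DesirabilityGoal],
    resolution: float = 0.01,
    design: DesignTable | None = None,
    polish: bool = True,
) -> OptimizationResult:
    """Maximize overall desirability over the coded cube [-1, 1]^3.

    Exhaustive grid search with coded step ``resolution``, then (by
    default) a Nelder-Mead polish constrained to the cube, started at the
    best grid point.  Exact ties in overall desirability break toward the
    lower predicted value of the first minimized response, then toward
    lexicographically smallest coded coordinates, so the result is
    deterministic even for flat surfaces.
    """
    if not goals:
        raise ValueError("empty goal set")
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    missing = [g.response for g in goals if g.response not in models]
    if missing:
        raise KeyError(f"no fitted model for goal response(s) {missing}")

    n = int(round(2.0 / resolution)) + 1
    axis = np.linspace(-1.0, 1.0, n)
    G1, G2, G3 = np.meshgrid(axis, axis, axis, indexing="ij")
    pts = np.column_stack([G1.ravel(), G2.ravel(), G3.ravel()])
    preds = _predict_all(models, pts)
    D = np.asarray(overall_desirability(preds, goals))

    best = D.max()
    tied = np.flatnonzero(D == best)
    if len(tied) > 1:
        min_goals = [g for g in goals if g.direction == "minimize"]
        if min_goals:
            key = preds[min_goals[0].response][tied]
            tied = tied[key == key.min()]
        # lexicographic: pts rows are already generated in lexicographic
        # order of (x1, x2, x3), so the first remaining index is smallest
    idx = int(tied[0])
    x_best = pts[idx]

    if polish:
        def neg_D(x: np.ndarray) -> float:
            p = {name: predict(m, np.clip(x, -1, 1)) for name, m in models.items()}
            return -overall_desirability(p, goals)

        res = minimize(
            neg_D,
            x_best,
            method="Nelder-Mead",
            bounds=[(-1.0, 1.0)] * 3,
            options={"xatol": 1e-6, "fatol": 1e-10},
        )
        if -res.fun > best:
            x_best = np.clip(res.x, -1.0, 1.0)

    x_best = tuple(float(v) for v in x_best)
    predicted = {name: float(predict(m, np.array(x_best))) for name, m in models.items()}
    indiv = {g.response: float(desirability(predicted[g.response], g)) for g in goals}
    D_final = overall_desirability(predicted, goals)
    actual = x_best
    if design is not None:
        actual = tuple(
            decode_level(f, c) for f, c in zip(design.factors, x_best)
        )
    return OptimizationResult(
        coded_optimum=x_best,
        actual_optimum=tuple(float(a) for a in actual),
        predicted=predicted,
        individual_desirabilities=indiv,
        overall_D=float(D_final),
    )


def prediction_error_pct(estimated: float, expected: float) -> float:
    """Absolute checkpoint prediction error, |estimated - expected| / estimated * 100."""
    if estimated == 0:
        raise ValueError("estimated (measured) value must be nonzero")
    return abs(estimated - expected) / abs(estimated) * 100.0


@dataclass
class ValidationReport:
    """Measured vs. model-expected responses at a checkpoint formulation."""

    rows: list[dict] = field(default_factory=list)
    max_error_pct: float = 10.0

    @property
    def passed(self) -> bool:
        return all(r["within_tolerance"] for r in self.rows)

    def to_dict(self) -> dict:
        return {
            "rows": self.rows,
            "max_error_pct": self.max_error_pct,
            "passed": self.passed,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def to_table(self) -> str:
        hdr = f"{'response':<10}{'estimated':>12}{'expected':>12}{'error %':>10}  ok"
        lines = [hdr, "-" * len(hdr)]
        for r in self.rows:
            lines.append(
                f"{r['response']:<10}{r['estimated']:>12.4g}{r['expected']:>12.4g}"
                f"{r['prediction_error_pct']:>10.1f}  {'yes' if r['within_tolerance'] else 'NO'}"
            )
        return "\n".join(lines)


def validate_checkpoint(
    measured: Mapping[str, float],
    models: Mapping[str, FittedModel],
    coded_point: Sequence[float],
    max_error_pct: float = 10.0,
) -> ValidationReport:
    """Compare measured checkpoint responses with model predictions.

    Expected values are the model predictions at ``coded_point``; each
    response's |error| above ``max_error_pct`` is flagged as a validation
    failure.
    """
    point = np.asarray(coded_point, dtype=float)
    report = ValidationReport(max_error_pct=max_error_pct)
    for name in measured:
        if name not in models:
            raise KeyError(f"no fitted model for measured response {name!r}")
    for name, model in models.items():
        if name not in measured:
            raise KeyError(f"missing measured value for response {name!r}")
        est = float(measured[name])
        exp = float(predict(model, point))
        err = prediction_error_pct(est, exp)
        report.rows.append(
            {
                "response": name,
                "estimated": est,
                "expected": exp,
                "prediction_error_pct": err,
                "within_tolerance": err <= max_error_pct,
            }
        )
    return report
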