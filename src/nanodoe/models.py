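"""Reduced response-surface models fitted by OLS in coded units.

The model family is the full quadratic polynomial in the three coded
factors,

    y = b0 + sum_i b_i x_i + sum_{i<j} b_ij x_i x_j + sum_i b_ii x_i^2,

or any hierarchical subset of it, optionally after a natural-log transform
of the response (used for zeta potential, whose effects are multiplicative).
Because the Box-Behnken coded columns are orthogonal, main-effect estimates
are simple contrasts and are unchanged by adding or removing orthogonal
terms.

Fitting is ordinary least squares via an orthogonal (SVD) decomposition.
Standard errors come from the unbiased residual variance and the diagonal
of the inverse Gram matrix; standardized effects are t = coef/SE.  The
lack-of-fit test splits the residual sum of squares into pure error
(within replicated design points, here the center replicates) and
lack-of-fit, and refers their variance ratio to an F distribution.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .design import DesignTable

__all__ = [
    "FULL_QUADRATIC",
    "ResponseSet",
    "ModelSpec",
    "FittedModel",
    "term_column",
    "model_matrix",
    "fit_rsm",
    "select_terms",
    "lack_of_fit",
    "standardized_effects",
    "predict",
    "surface_grid",
]

# Canonical term names for the 3-factor quadratic model.
MAIN_TERMS = ("x1", "x2", "x3")
INTERACTION_TERMS = ("x1:x2", "x1:x3", "x2:x3")
QUADRATIC_TERMS = ("x1^2", "x2^2", "x3^2")
FULL_QUADRATIC = ("1",) + MAIN_TERMS + INTERACTION_TERMS + QUADRATIC_TERMS


def _parents(term: str) -> tuple[str, ...]:
    """Main effects a higher-order term depends on under model hierarchy."""
    if ":" in term:
        return tuple(term.split(":"))
    if term.endswith("^2"):
        return (term[:-2],)
    return ()


def term_column(term: str, coded: np.ndarray) -> np.ndarray:
    """Evaluate one model term on an (n, 3) coded matrix."""
    coded = np.asarray(coded, dtype=float)
    if coded.ndim == 1:
        coded = coded[None, :]
    if term == "1":
        return np.ones(coded.shape[0])
    if term in MAIN_TERMS:
        return coded[:, MAIN_TERMS.index(term)]
    if term in INTERACTION_TERMS:
        a, b = term.split(":")
        return coded[:, MAIN_TERMS.index(a)] * coded[:, MAIN_TERMS.index(b)]
    if term in QUADRATIC_TERMS:
        return coded[:, MAIN_TERMS.index(term[:-2])] ** 2
    raise ValueError(f"unknown model term {term!r}")


def model_matrix(terms: Sequence[str], coded: np.ndarray) -> np.ndarray:
    return np.column_stack([term_column(t, coded) for t in terms])


@dataclass
class ResponseSet:
    """Measured responses aligned to the runs of a DesignTable.

    ``responses`` maps response name -> list of (mean, sd) pairs, one per
    run; ``sd`` may be None when replicate spread was not recorded.
    """

    design: DesignTable
    responses: dict[str, list[tuple[float, float | None]]]
    units: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = self.design.n_runs
        for name, vals in self.responses.items():
            if len(vals) != n:
                raise ValueError(
                    f"response {name!r} has {len(vals)} values for {n} runs"
                )
            for _, sd in vals:
                if sd is not None and sd < 0:
                    raise ValueError(f"response {name!r}: negative sd {sd}")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.responses)

    def means(self, response: str) -> np.ndarray:
        return np.array([m for m, _ in self.responses[response]], dtype=float)

    def sds(self, response: str) -> np.ndarray:
        return np.array(
            [np.nan if s is None else s for _, s in self.responses[response]],
            dtype=float,
        )

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for name, vals in self.responses.items():
            for run, (m, s) in zip(self.design.runs, vals):
                rows.append(
                    {"run_id": run.run_id, "response": name, "mean": m, "sd": s}
                )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, design: DesignTable, units: dict | None = None) -> "ResponseSet":
        df = pd.read_csv(path)
        required = {"run_id", "response", "mean"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"response CSV missing columns: {sorted(missing)}")
        order = {r.run_id: i for i, r in enumerate(design.runs)}
        responses: dict[str, list] = {}
        for name, grp in df.groupby("response", sort=False):
            if set(grp["run_id"]) != set(order):
                raise ValueError(f"response {name!r} does not cover all run_ids")
            vals: list[tuple[float, float | None]] = [None] * design.n_runs  # type: ignore
            for _, row in grp.iterrows():
                sd = row.get("sd", np.nan)
                sd = None if pd.isna(sd) else float(sd)
                vals[order[int(row["run_id"])]] = (float(row["mean"]), sd)
            responses[str(name)] = vals
        return cls(design=design, responses=responses, units=units or {})


@dataclass(frozen=True)
class ModelSpec:
    """Which terms to fit, on which transform scale."""

    response: str
    transform: str = "identity"  # "identity" | "ln"
    terms: tuple[str, ...] = FULL_QUADRATIC
    selection: str = "fixed"  # "fixed" | "backward"

    def __post_init__(self) -> None:
        if self.transform not in ("identity", "ln"):
            raise ValueError(f"unknown transform {self.transform!r}")
        if self.selection not in ("fixed", "backward"):
            raise ValueError(f"unknown selection {self.selection!r}")
        terms = tuple(self.terms)
        if "1" not in terms:
            terms = ("1",) + terms
        # canonical order: follow FULL_QUADRATIC ordering
        terms = tuple(t for t in FULL_QUADRATIC if t in terms)
        unknown = set(self.terms) - set(FULL_QUADRATIC)
        if unknown:
            raise ValueError(f"unknown terms {sorted(unknown)}")
        object.__setattr__(self, "terms", terms)


@dataclass
class FittedModel:
    spec: ModelSpec
    coefficients: dict[str, float]
    standard_errors: dict[str, float]
    t_statistics: dict[str, float]
    residual_df: int
    r2: float
    anova: dict[str, float]
    factor_names: tuple[str, ...] = ("x1", "x2", "x3")

    @property
    def terms(self) -> tuple[str, ...]:
        return self.spec.terms

    def coef_vector(self) -> np.ndarray:
        return np.array([self.coefficients[t] for t in self.terms])

    def to_dict(self) -> dict:
        return {
            "response": self.spec.response,
            "transform": self.spec.transform,
            "terms": list(self.terms),
            "coefficients": self.coefficients,
            "standard_errors": self.standard_errors,
            "t_statistics": self.t_statistics,
            "residual_df": self.residual_df,
            "r2": self.r2,
            "anova": self.anova,
            "factor_names": list(self.factor_names),
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), indent=2, **kw)


def _transform(y: np.ndarray, transform: str, response: str) -> np.ndarray:
    if transform == "ln":
        if np.any(y <= 0):
            raise ValueError(
                f"ln transform requires positive response values for {response!r}"
            )
        return np.log(y)
    return y


def _replicate_groups(coded: np.ndarray) -> list[np.ndarray]:
    """Indices of runs sharing an identical coded row (size >= 2 only)."""
    seen: dict[tuple, list[int]] = {}
    for i, row in enumerate(coded):
        seen.setdefault(tuple(row), []).append(i)
    return [np.array(ix) for ix in seen.values() if len(ix) >= 2]


def _pure_error(coded: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    ss = 0.0
    df = 0
    for ix in _replicate_groups(coded):
        g = y[ix]
        ss += float(np.sum((g - g.mean()) ** 2))
        df += len(ix) - 1
    return ss, df


def fit_rsm(data: ResponseSet, spec: ModelSpec) -> FittedModel:
    """Fit a response-surface model by OLS on the coded model matrix.

    The response is transformed (identity or natural log) before fitting;
    coefficients, SEs and t-statistics are reported on the transform scale
    in coded units.  The ANOVA block carries the sums of squares needed for
    the lack-of-fit test when the design contains replicated runs.
    """
    if spec.response not in data.responses:
        raise KeyError(f"response {spec.response!r} not in data")
    coded = data.design.coded_matrix
    y = _transform(data.means(spec.response), spec.transform, spec.response)
    X = model_matrix(spec.terms, coded)
    n, p = X.shape
    if n < p + 1:
        raise ValueError(f"need at least {p + 1} runs to fit {p} terms, have {n}")
    if np.linalg.matrix_rank(X) < p:
        raise np.linalg.LinAlgError("singular model matrix for the given terms")

    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    fittedvals = X @ beta
    resid = y - fittedvals
    residual_df = n - p
    rss = float(resid @ resid)
    tss = float(np.sum((y - y.mean()) ** 2))
    model_ss = tss - rss
    sigma2 = rss / residual_df if residual_df > 0 else np.nan
    gram_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(sigma2 * np.diag(gram_inv))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = beta / se

    anova: dict[str, float] = {
        "model_ss": model_ss,
        "model_df": p - 1,
        "residual_ss": rss,
        "residual_df": residual_df,
        "total_ss": tss,
    }
    pe_ss, pe_df = _pure_error(coded, y)
    if pe_df > 0:
        lof_ss = rss - pe_ss
        lof_df = residual_df - pe_df
        anova.update(
            pure_error_ss=pe_ss,
            pure_error_df=pe_df,
            lack_of_fit_ss=lof_ss,
            lack_of_fit_df=lof_df,
        )
        if lof_df > 0 and pe_ss > 0:
            F = (lof_ss / lof_df) / (pe_ss / pe_df)
            anova["lack_of_fit_F"] = float(F)
            anova["lack_of_fit_p"] = float(stats.f.sf(F, lof_df, pe_df))

    return FittedModel(
        spec=spec,
        coefficients={t: float(b) for t, b in zip(spec.terms, beta)},
        standard_errors={t: float(s) for t, s in zip(spec.terms, se)},
        t_statistics={t: float(v) for t, v in zip(spec.terms, tvals)},
        residual_df=residual_df,
        r2=1.0 - rss / tss if tss > 0 else 1.0,
        anova=anova,
        factor_names=data.design.factor_names,
    )


def lack_of_fit(fitted: FittedModel, data: ResponseSet) -> dict[str, float]:
    """Lack-of-fit F-test against pure error from replicated runs.

    Raises if the design holds no replicated coded points: without pure
    error the test is undefined (never silently zero).
    """
    coded = data.design.coded_matrix
    y = _transform(data.means(fitted.spec.response), fitted.spec.transform,
                   fitted.spec.response)
    pe_ss, pe_df = _pure_error(coded, y)
    if pe_df == 0:
        raise ValueError(
            "lack-of-fit test undefined: the design has no replicated runs"
        )
    X = model_matrix(fitted.terms, coded)
    resid = y - X @ fitted.coef_vector()
    rss = float(resid @ resid)
    lof_ss = rss - pe_ss
    lof_df = (len(y) - X.shape[1]) - pe_df
    if lof_df <= 0:
        raise ValueError("model saturates the distinct design points; no lack-of-fit df")
    F = (lof_ss / lof_df) / (pe_ss / pe_df)
    return {
        "F": float(F),
        "p": float(stats.f.sf(F, lof_df, pe_df)),
        "lack_of_fit_ss": lof_ss,
        "lack_of_fit_df": lof_df,
        "pure_error_ss": pe_ss,
        "pure_error_df": pe_df,
    }


def select_terms(
    data: ResponseSet,
    response: str,
    transform: str = "identity",
    alpha: float = 0.05,
    hierarchy: bool = True,
) -> ModelSpec:
    """Backward elimination from the full quadratic model.

    Repeatedly drops the least-significant removable term with p > alpha
    (two-sided t-test) until every retained non-intercept term is
    significant.  Under hierarchy enforcement a main effect cannot leave
    while any interaction or square involving it remains.  Ties in p-value
    break alphabetically by term name, so selection is deterministic.
    """
    terms = list(FULL_QUADRATIC)
    while True:
        fitted = fit_rsm(data, ModelSpec(response, transform, tuple(terms), "fixed"))
        df = fitted.residual_df
        pvals = {
            t: 2.0 * stats.t.sf(abs(fitted.t_statistics[t]), df)
            for t in fitted.terms
            if t != "1"
        }
        needed: set[str] = set()
        if hierarchy:
            for t in fitted.terms:
                if t != "1":
                    needed.update(_parents(t))
        candidates = [
            t for t, p in pvals.items() if p > alpha and t not in needed
        ]
        if not candidates:
            return fitted.spec
        # drop the worst p; alphabetical tie-break
        drop = max(sorted(candidates), key=lambda t: pvals[t])
        terms.remove(drop)


def standardized_effects(
    fitted: FittedModel, alpha: float = 0.05
) -> list[tuple[str, float, bool]]:
    """Pareto-ordered standardized effects (t = coef/SE), intercept excluded.

    Returns (term, t, significant) sorted by |t| descending; a term is
    significant when |t| exceeds the two-sided critical t at level alpha
    with the model's residual degrees of freedom.
    """
    if fitted.residual_df < 1:
        raise ValueError("standardized effects require residual_df >= 1")
    t_crit = stats.t.ppf(1.0 - alpha / 2.0, fitted.residual_df)
    rows = [
        (term, fitted.t_statistics[term], bool(abs(fitted.t_statistics[term]) > t_crit))
        for term in fitted.terms
        if term != "1"
    ]
    return sorted(rows, key=lambda r: -abs(r[1]))


def predict(
    fitted: FittedModel,
    coded_point: Sequence[float] | np.ndarray,
    extrapolate: bool = False,
) -> float | np.ndarray:
    """Evaluate the model at coded point(s) on the original response scale.

    Applies exp() when the model was fitted on the ln scale (plain
    back-transform, no bias correction).  Points outside the [-1, 1] cube
    raise unless ``extrapolate=True``.
    """
    pts = np.asarray(coded_point, dtype=float)
    scalar = pts.ndim == 1
    if scalar:
        pts = pts[None, :]
    if not extrapolate and np.any(np.abs(pts) > 1.0 + 1e-9):
        raise ValueError(
            "coded point outside the [-1, 1] design cube; pass extrapolate=True"
        )
    X = model_matrix(fitted.terms, pts)
    yhat = X @ fitted.coef_vector()
    if fitted.spec.transform == "ln":
        yhat = np.exp(yhat)
    return float(yhat[0]) if scalar else yhat


def surface_grid(
    fitted: FittedModel,
    vary: tuple[str, str],
    fixed_value: float = 0.0,
    resolution: int = 21,
) -> pd.DataFrame:
    """Predicted response on a regular coded grid over two factors.

    ``vary`` names two factors (design names or "x1"/"x2"/"x3"); the third
    is held at ``fixed_value`` (coded).  Returns a long-format table with
    the coded coordinates and the prediction, ready for external plotting.
    """
    if resolution < 2:
        raise ValueError("resolution must be >= 2")
    names = list(fitted.factor_names)

    def _axis(name: str) -> int:
        if name in names:
            return names.index(name)
        if name in MAIN_TERMS:
            return MAIN_TERMS.index(name)
        raise KeyError(f"unknown factor {name!r}; have {names}")

    ia, ib = _axis(vary[0]), _axis(vary[1])
    if ia == ib:
        raise ValueError("vary must name two distinct factors")
    ic = ({0, 1, 2} - {ia, ib}).pop()
    g = np.linspace(-1.0, 1.0, resolution)
    A, B = np.meshgrid(g, g, indexing="ij")
    pts = np.zeros((resolution * resolution, 3))
    pts[:, ia] = A.ravel()
    pts[:, ib] = B.ravel()
    pts[:, ic] = fixed_value
    pred = predict(fitted, pts)
    return pd.DataFrame(
        {
            names[ia]: pts[:, ia],
            names[ib]: pts[:, ib],
            names[ic]: pts[:, ic],
            fitted.spec.response: pred,
        }
    )
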