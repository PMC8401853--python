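"""Bundled study data: the 17-run nanoparticle formulation experiment.

The fixtures ship the published run table of a berberine-loaded
lecithin-chitosan nanoparticle study: three factors (lecithin amount,
chitosan amount, isopropyl-myristate concentration), a 17-run Box-Behnken
design, three responses (particle size PS in nm, zeta potential ZP in mV,
entrapment efficiency EE in %), and the optimized checkpoint formulation
with its measured and model-expected values.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .design import DesignTable, FactorSpec, Run, code_level
from .models import ModelSpec, ResponseSet
from .synthetic import TruthModel

__all__ = [
    "load_factors",
    "load_study",
    "load_checkpoint",
    "load_run_order",
    "STUDY_MODEL_SPECS",
    "RESPONSE_DIRECTIONS",
    "RESPONSE_UNITS",
    "STUDY_TRUTHS",
]

# Reduced model term sets identified for the study's three responses.
STUDY_MODEL_SPECS: dict[str, ModelSpec] = {
    "PS": ModelSpec("PS", "identity", ("1", "x1", "x2", "x3"), "fixed"),
    "ZP": ModelSpec("ZP", "ln", ("1", "x1", "x2", "x3", "x2^2"), "fixed"),
    "EE": ModelSpec("EE", "identity", ("1", "x1", "x2", "x3", "x2:x3", "x3^2"), "fixed"),
}

# Optimization goals: small particles, high surface charge, high entrapment.
RESPONSE_DIRECTIONS: dict[str, str] = {
    "PS": "minimize",
    "ZP": "maximize",
    "EE": "maximize",
}

RESPONSE_UNITS: dict[str, str] = {"PS": "nm", "ZP": "mV", "EE": "%"}

# Generating models for the synthetic-data module: the study's fitted
# equations, with noise SDs set to each fit's residual SD on its transform
# scale (PS 6.4 nm, ln-ZP 0.026, EE 0.88 %).
STUDY_TRUTHS: tuple[TruthModel, ...] = (
    TruthModel(
        "PS",
        {"1": 178.382, "x1": 4.1125, "x2": 43.475, "x3": 13.5625},
        "identity",
        6.4,
    ),
    TruthModel(
        "ZP",
        {"1": 3.36885, "x1": -0.0713389, "x2": 0.278543, "x3": 0.00321433,
         "x2^2": -0.10896},
        "ln",
        0.026,
    ),
    TruthModel(
        "EE",
        {"1": 72.5489, "x1": 0.87625, "x2": 3.995, "x3": 16.9863,
         "x2:x3": -1.1175, "x3^2": -7.47264},
        "identity",
        0.88,
    ),
)


def _read(name: str) -> pd.DataFrame:
    with resources.files("nanodoe.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def load_factors() -> tuple[FactorSpec, FactorSpec, FactorSpec]:
    """The three formulation factors with their low/center/high levels."""
    df = _read("table1_factors.csv")
    return tuple(FactorSpec.from_dict(row) for row in df.to_dict("records"))  # type: ignore[return-value]


def load_study() -> tuple[DesignTable, ResponseSet]:
    """The 17-run design (published run order) and its measured responses."""
    factors = load_factors()
    df = _read("table2_runs.csv")
    runs = []
    for _, row in df.iterrows():
        actual = tuple(float(row[f.name]) for f in factors)
        coded = tuple(code_level(f, a) for f, a in zip(factors, actual))
        runs.append(Run(int(row["run_id"]), coded, actual))
    n_center = sum(1 for r in runs if all(c == 0 for c in r.coded))
    design = DesignTable(factors=factors, runs=runs, n_center=n_center)
    design.validate()
    responses = {
        name: [
            (float(row[f"{name}_mean"]), float(row[f"{name}_sd"]))
            for _, row in df.iterrows()
        ]
        for name in ("PS", "ZP", "EE")
    }
    return design, ResponseSet(design=design, responses=responses,
                               units=dict(RESPONSE_UNITS))


def load_checkpoint() -> dict[str, dict[str, float]]:
    """The optimized checkpoint formulation and its validation numbers.

    Returns a mapping with keys ``optimum`` (actual factor levels),
    ``estimated`` (measured responses), ``expected`` (model predictions as
    published) and ``error_pct`` (published prediction errors).
    """
    df = _read("table3_checkpoint.csv")
    out: dict[str, dict[str, float]] = {}
    for _, row in df.iterrows():
        out.setdefault(row["record"], {})[row["name"]] = float(row["value"])
    return out


def load_run_order() -> dict[int, int]:
    """Permutation from canonical build_bbd run ids to published run ids."""
    df = _read("table2_run_order.csv")
    return dict(zip(df["canonical_run_id"].astype(int),
                    df["printed_run_id"].astype(int)))
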