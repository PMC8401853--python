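"""Study configuration, file I/O and full-pipeline orchestration.

``run_study`` drives the whole analysis: read (or build) the design and
response table, fit one reduced model per response, run the lack-of-fit
ANOVA and Pareto analysis, export surface grids, optimize the overall
desirability, and validate an optional checkpoint formulation.  All
numeric artifacts are written as JSON/CSV so plotting stays external, and
a stage-level log records the SHA-256 of every input file for provenance.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .design import DesignTable, FactorSpec, build_bbd, code_level
from .models import (
    FittedModel,
    ModelSpec,
    ResponseSet,
    fit_rsm,
    lack_of_fit,
    select_terms,
    standardized_effects,
    surface_grid,
)
from .optimize import (
    DesirabilityGoal,
    goals_from_observed,
    optimize_desirability,
    validate_checkpoint,
)

__all__ = ["StudyConfig", "run_study", "load_config"]

logger = logging.getLogger("nanodoe")


@dataclass
class StudyConfig:
    """Everything needed to run a complete design/fit/optimize study."""

    factors: list[FactorSpec]
    responses_csv: str | None = None
    design_csv: str | None = None
    n_center: int = 5
    # response name -> {"transform": ..., "terms": [...]}, or "auto"
    model_specs: dict = field(default_factory=dict)
    directions: dict[str, str] = field(default_factory=dict)
    anchors: dict[str, tuple[float, float]] = field(default_factory=dict)
    weights: dict[str, float] = field(default_factory=dict)
    resolution: float = 0.01
    checkpoint_measured: dict[str, float] = field(default_factory=dict)
    checkpoint_actual: dict[str, float] = field(default_factory=dict)
    surface_resolution: int = 21
    out_dir: str = "study_out"
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.factors) != 3:
            raise ValueError("exactly three factors required")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        for name, d in self.directions.items():
            if d not in ("minimize", "maximize"):
                raise ValueError(f"direction for {name!r} must be minimize/maximize")


def load_config(path: str | Path) -> StudyConfig:
    """Read a StudyConfig from JSON."""
    with open(path) as fh:
        raw = json.load(fh)
    raw["factors"] = [FactorSpec.from_dict(f) for f in raw["factors"]]
    if "anchors" in raw:
        raw["anchors"] = {k: tuple(v) for k, v in raw["anchors"].items()}
    return StudyConfig(**raw)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _resolve_spec(config: StudyConfig, data: ResponseSet, name: str) -> ModelSpec:
    raw = config.model_specs.get(name, "auto")
    if raw == "auto":
        transform = "ln" if name in config.model_specs.get("_ln_responses", ()) else "identity"
        return select_terms(data, name, transform)
    if isinstance(raw, ModelSpec):
        return raw
    transform = raw.get("transform", "identity")
    if raw.get("terms") is None:
        return select_terms(data, name, transform)
    return ModelSpec(name, transform, tuple(raw["terms"]), "fixed")


def run_study(config: StudyConfig) -> dict:
    """Execute the full pipeline and write the report bundle.

    Returns a summary dict with the fitted models, optimization result and
    (if a checkpoint was configured) the validation report.  Any stage
    failure raises with the stage name attached, so CLI callers can exit
    nonzero with a useful message.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {}
    stage = "setup"
    try:
        # --- design -----------------------------------------------------
        stage = "design"
        if config.design_csv:
            logger.info("design: reading %s (sha256 %s)", config.design_csv,
                        _sha256(config.design_csv))
            design = DesignTable.from_csv(config.design_csv, config.factors)
        else:
            logger.info("design: building BBD with %d center runs", config.n_center)
            design = build_bbd(config.factors, config.n_center)
        design.to_csv(out / "design.csv")

        # --- responses --------------------------------------------------
        stage = "responses"
        if not config.responses_csv:
            raise ValueError("responses_csv is required to fit models")
        logger.info("responses: reading %s (sha256 %s)", config.responses_csv,
                    _sha256(config.responses_csv))
        data = ResponseSet.from_csv(config.responses_csv, design)

        # --- model fitting ----------------------------------------------
        stage = "fit"
        models: dict[str, FittedModel] = {}
        for name in data.names:
            spec = _resolve_spec(config, data, name)
            fitted = fit_rsm(data, spec)
            models[name] = fitted
            (out / f"model_{name}.json").write_text(fitted.to_json())
            logger.info("fit: %s terms=%s r2=%.4f", name, spec.terms, fitted.r2)
        summary["models"] = models

        # --- ANOVA / lack of fit ----------------------------------------
        stage = "anova"
        anova_rows = []
        for name, fitted in models.items():
            row = {"response": name, **fitted.anova}
            try:
                row.update({f"lof_{k}": v for k, v in lack_of_fit(fitted, data).items()})
            except ValueError:
                logger.warning("anova: no replicated runs; lack-of-fit skipped")
            anova_rows.append(row)
        pd.DataFrame(anova_rows).to_csv(out / "anova.csv", index=False)

        # --- Pareto (standardized effects) ------------------------------
        stage = "pareto"
        pareto_rows = [
            {"response": name, "term": t, "t": tval, "significant": sig}
            for name, fitted in models.items()
            for t, tval, sig in standardized_effects(fitted)
        ]
        pd.DataFrame(pareto_rows).to_csv(out / "pareto.csv", index=False)

        # --- surface grids ----------------------------------------------
        stage = "surfaces"
        fnames = design.factor_names
        for name, fitted in models.items():
            for a, b in ((0, 1), (0, 2), (1, 2)):
                grid = surface_grid(fitted, (fnames[a], fnames[b]),
                                    resolution=config.surface_resolution)
                grid.to_csv(out / f"surface_{name}_{fnames[a]}_{fnames[b]}.csv",
                            index=False)

        # --- optimization ------------------------------------------------
        stage = "optimize"
        directions = config.directions or {n: "maximize" for n in data.names}
        goals = []
        for name, direction in directions.items():
            if name in config.anchors:
                lo, hi = config.anchors[name]
                goals.append(DesirabilityGoal(name, direction, lo, hi,
                                              config.weights.get(name, 1.0)))
            else:
                goals.extend(goals_from_observed(
                    {name: data.means(name)}, {name: direction},
                    {name: config.weights.get(name, 1.0)}))
        result = optimize_desirability(
            {g.response: models[g.response] for g in goals},
            goals, resolution=config.resolution, design=design)
        (out / "optimization.json").write_text(result.to_json())
        summary["optimization"] = result
        logger.info("optimize: D=%.4f at coded %s", result.overall_D,
                    result.coded_optimum)

        # --- checkpoint validation ---------------------------------------
        if config.checkpoint_measured:
            stage = "validate"
            if config.checkpoint_actual:
                coded_point = [
                    code_level(f, config.checkpoint_actual[f.name])
                    for f in design.factors
                ]
            else:
                coded_point = list(result.coded_optimum)
            report = validate_checkpoint(config.checkpoint_measured, models,
                                         coded_point)
            (out / "validation.json").write_text(report.to_json())
            summary["validation"] = report
            logger.info("validate:\n%s", report.to_table())
    except Exception as exc:
        raise RuntimeError(f"study stage {stage!r} failed: {exc}") from exc
    return summary
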