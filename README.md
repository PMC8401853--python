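# nanodoe

Design-of-experiments toolkit for nanoparticle formulation optimization:
Box–Behnken design construction, reduced response-surface model fitting by
ordinary least squares in coded units (with lack-of-fit ANOVA and
standardized-effect Pareto analysis), Derringer–Suich desirability
optimization, checkpoint validation, and the closed-form formulation and
wound-healing metrics used in such studies.

It is aimed at formulation scientists running three-factor, three-level
response-surface studies — the bundled example is a berberine-loaded
lecithin–chitosan nanoparticle study with factors lecithin amount
(X₁, 100–200 mg), chitosan amount (X₂, 10–40 mg) and isopropyl-myristate
concentration (X₃, 1–3 % w/v), and responses particle size (PS, nm), zeta
potential (ZP, mV) and entrapment efficiency (EE, %).

## The model

Each response is fitted in coded units (levels rescaled to [−1, 1]) with a
hierarchical subset of the quadratic polynomial

```
y = β₀ + Σᵢ βᵢxᵢ + Σᵢ<ⱼ βᵢⱼxᵢxⱼ + Σᵢ βᵢᵢxᵢ² + ε,
```

optionally after a natural-log transform of y (used for ZP).  Because the
Box–Behnken coded columns are orthogonal, β₀ is the grand mean and each main
effect is a simple contrast.  Model adequacy is judged by the lack-of-fit
F-test, which splits the residual sum of squares into pure error (from the
five replicated center runs) and lack of fit.  Factor influence is ranked by
standardized effects t = β̂/SE(β̂) against the two-sided critical t.

For multi-response optimization each predicted response is mapped to a
desirability d ∈ [0, 1] by a one-sided ramp between its anchors (by default
the observed response extremes), with the goal weight as ramp exponent; the
overall desirability D — the geometric mean of the d's — is maximized over
the coded cube by an exhaustive grid search plus a bounded Nelder–Mead
polish, which is fully deterministic.

## Worked example

```python
import nanodoe as nd

design, data = nd.datasets.load_study()          # the 17-run study table
models = {name: nd.fit_rsm(data, spec)
          for name, spec in nd.datasets.STUDY_MODEL_SPECS.items()}

ps = models["PS"]
print({t: round(c, 4) for t, c in ps.coefficients.items()})
# {'1': 178.3824, 'x1': 4.1125, 'x2': 43.475, 'x3': 13.5625}
print(round(nd.lack_of_fit(ps, data)["p"], 3))
# 0.212   (p >= 0.1: no evidence of lack of fit)

goals = nd.goals_from_observed({n: data.means(n) for n in data.names},
                               nd.datasets.RESPONSE_DIRECTIONS)
result = nd.optimize_desirability(models, goals, resolution=0.01,
                                  design=design)
print([round(v, 2) for v in result.actual_optimum])
# [100.0, 25.55, 2.59]
print({k: round(v, 1) for k, v in result.predicted.items()})
# {'PS': 183.9, 'ZP': 31.6, 'EE': 79.2}
```

The fitted PS equation says particle size averages 178.4 nm at the center of
the design and grows by 43.5 nm per coded unit of chitosan — chitosan is the
dominant size driver.  The optimizer puts lecithin at its 100 mg lower bound
(low lecithin favors both small particles and high surface charge) with
chitosan and IPM at intermediate levels, predicting ~184 nm particles,
+32 mV charge and 79 % entrapment.

A `nanodoe` console script exposes the same pipeline
(`nanodoe design|fit|optimize|simulate|run`); see `nanodoe --help`.

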