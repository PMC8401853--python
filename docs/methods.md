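# Methods

## Design construction and coding

`build_bbd` constructs the three-factor Box–Behnken design: the 12 edge
midpoints of the cube — every (±1, ±1) combination of each factor pair with
the third factor at 0 — plus `n_center` center replicates (default 5,
giving the standard 17-run layout).  Runs are emitted in a fixed canonical
order (pair blocks (1,2), (1,3), (2,3), signs (−,−), (+,−), (−,+), (+,+),
then centers) so output is deterministic; the bundled study's published run
order is shipped as a permutation fixture (`table2_run_order.csv`) rather
than imposed on the constructor, since published run tables are typically
randomized and their order carries no information.

Coding is exact rational arithmetic, `coded = (actual − center) /
((high − low)/2)`, with `decode_level` its exact inverse.  Centers that are
not the low/high midpoint are allowed — the coding formula still applies —
but warned about, since they break the ±1 symmetry most BBD intuition
assumes.  Coding a level outside [−1, 1] warns rather than fails: the value
is legitimate for checkpoint formulations near the boundary but deserves
attention.

## Model fitting

`fit_rsm` fits any hierarchical subset of the ten-term quadratic model by
OLS on the coded model matrix, via `numpy.linalg.lstsq` (SVD); the test
suite holds it to an explicit normal-equations oracle (Gram-matrix
inversion) at 1e-9 relative tolerance, and cross-checks coefficients and
standard errors against statsmodels OLS.  Standard errors use the unbiased
residual variance times the inverse Gram diagonal; t-statistics are
coefficient/SE.  All fitting is in coded units — on the orthogonal BBD the
intercept is then the grand mean and each main effect a ±1 contrast, which
the tests verify directly.  Actual-unit equations are derivable but not
canonical.

The `ln` transform (used for zeta potential, whose factor effects act
multiplicatively) is the natural log applied before fitting; point
predictions back-transform with a plain `exp()` and no smearing/bias
correction, matching how such models are conventionally reported in
formulation work.

Replicate groups for pure error are identified by exact coded-row equality
(the center replicates in a standard BBD).  The lack-of-fit F statistic is
(lof_ss/lof_df)/(pe_ss/pe_df) with p from the upper F tail; a design
without replicates raises rather than silently reporting zero pure error.

`select_terms` backward-eliminates from the full quadratic model at
α = 0.05, preserving hierarchy (a main effect cannot leave while one of its
interactions or its square remains) with alphabetical tie-breaks, so
selection is deterministic.  Note that on the bundled study's PS response
this rule drops the lecithin main effect (p = 0.091); the published
three-term sets are therefore shipped as fixed specs
(`datasets.STUDY_MODEL_SPECS`) and used for all headline numbers, with
automatic selection available for new data.

### Known discrepancy in the bundled study

Refitting the published EE term set to the published run table reproduces
all orthogonal-contrast coefficients exactly but gives intercept 72.566 and
x₃² −7.489 versus the published 72.5489 and −7.47264; likewise the
published "model expected" PS at the optimum (179.1 nm) differs slightly
from evaluating the published PS equation there (≈178.1 nm).  These are
consistent with rounding in the published responses/optimum or prediction
from an unreduced model; the two coefficients and the three expected values
are reported but not treated as exactly reproducible.

## Desirability optimization

Individual desirabilities are one-sided Derringer–Suich ramps: 0 below the
lower anchor, `((v − lo)/(hi − lo))^weight` between, 1 above (mirrored for
minimization).  Anchors default to each response's observed min/max over
the run table — the convention of common DoE software, used because the
study states goals but not anchors — and weights default to 1.  The weight
enters once, as the ramp exponent; the overall score is the plain geometric
mean of the individual desirabilities (weighting both the ramp and the mean
would double-count importance).

The optimizer evaluates D on an exhaustive coded grid (default step 0.01,
8.1M points, vectorized; ~8 s on one CPU) and then polishes the best grid
point with Nelder–Mead confined to the cube.  Exact ties break toward the
lower predicted value of the first minimized response, then toward the
lexicographically smallest coded point, so flat surfaces still return a
documented canonical optimum.  Checkpoint validation reports
|estimated − expected|/estimated × 100 as an absolute percentage (the
published table prints the magnitude for a negative signed error) and flags
errors above 10 %.

## Formulation and wound metrics

Entrapment efficiency and wound closure are literal closed forms,
`(total − free)/total × 100` and `(W₀ − W_t)/W₀ × 100`.  Cumulative release
defaults to the literal assay formula Q_i/Q_r × 100 with
Q_i = concentration × receptor volume, because that is how such release
percentages are conventionally computed; the sampling correction (adding
back the drug mass removed in earlier 1 mL samples) is an explicit opt-in
flag.  The corrected series is nondecreasing for dilution-consistent
profiles (each concentration at least the previous one diluted by the
sample replacement); an arbitrary concentration crash can still produce a
decrease, which is a data problem, not a formula one.  A release percentage
above 100 plus a 0.5-point allowance (absorbing assay noise near complete
release) raises an input-consistency error.

## Synthetic data

`simulate_bbd_responses` draws each run's response as the truth
polynomial's value plus homoscedastic Gaussian noise on the transform
scale; ln-scale truths exponentiate after adding noise, giving log-normal
responses.  Homoscedastic-per-response is the simplest structure faithful
to a replicate-free run table; a per-run SD vector is accepted for
heteroscedastic scenarios.  The default truths (`datasets.STUDY_TRUTHS`)
are the bundled study's fitted equations with noise SDs set to each fit's
residual SD: 6.4 nm for PS, 0.026 on the ln scale for ZP, 0.88 % for EE.
What the generator does **not** emulate: run-to-run SD heterogeneity,
measurement rounding (0.1 nm / 0.1 mV / 0.01 %), correlation between
responses measured on the same batch, and any curvature absent from the
truth polynomial — so passing recovery tests demonstrate correctness of
the estimator under the stated model, not robustness to those features of
real data.

`recovery_study` repeats simulate→fit with replicate r seeded as
`default_rng([seed, r])` — a counter scheme that is reproducible and
order-independent — and reports per-coefficient bias, Monte-Carlo SE, RMSE
and 95 % t-interval coverage; failed fits are counted, never dropped
silently.  The suite runs 500 replicates at the PS noise scale (a few
seconds), where coverage must land in the binomial band 0.95 ± 0.03.

## Pipeline and I/O

`run_study` orchestrates design → fit → ANOVA → Pareto → surfaces →
optimization → checkpoint validation from a JSON `StudyConfig`, writing
only JSON/CSV (plots are external) and logging each stage with input-file
SHA-256 for provenance.  Two runs on identical inputs produce byte-identical
numeric outputs.  CSV dialect is comma-separated, period decimal, UTF-8,
header mandatory.  Coefficients are kept in full double precision
internally; display rounding (6 significant figures for coefficients, 1
decimal for percentages) only happens at the formatting layer.

## Problem sizes

Default test and acceptance runs use the 17-run design throughout, a
0.01-coded-unit optimization grid (8.1M points), 100 randomized
fit-vs-oracle problems, and 500-replicate recovery studies — sizes chosen
to make every statistical check sharp while keeping the whole suite around
half a minute.
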