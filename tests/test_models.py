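"""OLS fitting, ANOVA/lack-of-fit, term selection, prediction, surfaces."""

import numpy as np
import pytest
from scipy import stats

from nanodoe import (
    FULL_QUADRATIC,
    ModelSpec,
    build_bbd,
    fit_rsm,
    lack_of_fit,
    model_matrix,
    predict,
    select_terms,
    standardized_effects,
    surface_grid,
)
from nanodoe.datasets import STUDY_MODEL_SPECS, STUDY_TRUTHS
from nanodoe.synthetic import simulate_bbd_responses

from conftest import normal_equations_fit


# ---------------------------------------------------------------- fitting

def test_fit_matches_normal_equations_oracle_on_study_data(study):
    _, data = study
    for name, spec in STUDY_MODEL_SPECS.items():
        fitted = fit_rsm(data, spec)
        y = data.means(name)
        if spec.transform == "ln":
            y = np.log(y)
        X = model_matrix(spec.terms, data.design.coded_matrix)
        oracle = normal_equations_fit(X, y)
        assert np.allclose(fitted.coef_vector(), oracle, rtol=1e-9)


def test_fit_matches_normal_equations_oracle_on_random_problems(factors):
    """Random designs, term sets and responses: OLS == explicit oracle."""
    rng = np.random.default_rng(7)
    design = build_bbd(factors, n_center=5)
    for _ in range(30):
        n_terms = rng.integers(1, 8)
        terms = ("1",) + tuple(
            sorted(rng.choice(FULL_QUADRATIC[1:], size=n_terms, replace=False))
        )
        truth = simulate_bbd_responses(
            design,
            [_random_truth(rng)],
            seed=int(rng.integers(2**31)),
        )
        spec = ModelSpec("y", "identity", terms, "fixed")
        fitted = fit_rsm(truth, spec)
        X = model_matrix(fitted.terms, design.coded_matrix)
        oracle = normal_equations_fit(X, truth.means("y"))
        assert np.allclose(fitted.coef_vector(), oracle, rtol=1e-9)


def _random_truth(rng):
    from nanodoe import TruthModel
    coefs = {"1": float(rng.normal(100, 10))}
    for t in FULL_QUADRATIC[1:]:
        if rng.random() < 0.6:
            coefs[t] = float(rng.normal(0, 10))
    return TruthModel("y", coefs, "identity", float(rng.uniform(0.5, 5)))


def test_fit_agrees_with_statsmodels(study):
    """Cross-check coefficients and SEs against an independent OLS library."""
    sm = pytest.importorskip("statsmodels.api")
    _, data = study
    for name, spec in STUDY_MODEL_SPECS.items():
        fitted = fit_rsm(data, spec)
        y = data.means(name)
        if spec.transform == "ln":
            y = np.log(y)
        X = model_matrix(spec.terms, data.design.coded_matrix)
        res = sm.OLS(y, X).fit()
        assert np.allclose(fitted.coef_vector(), res.params, rtol=1e-9)
        se = np.array([fitted.standard_errors[t] for t in fitted.terms])
        assert np.allclose(se, res.bse, rtol=1e-9)


def test_noiseless_synthetic_fit_recovers_truth_exactly(factors):
    design = build_bbd(factors, n_center=5)
    for truth in STUDY_TRUTHS:
        noiseless = type(truth)(truth.response, truth.coefficients,
                                truth.transform, 0.0)
        data = simulate_bbd_responses(design, [noiseless], seed=0)
        fitted = fit_rsm(data, noiseless.spec())
        for term, coef in truth.coefficients.items():
            assert fitted.coefficients[term] == pytest.approx(coef, abs=1e-9)


def test_intercept_equals_grand_mean_for_linear_model_on_bbd(study):
    """On the orthogonal BBD a linear fit's intercept is the grand mean and
    each main effect is the (+1 sum - (-1) sum)/8 contrast."""
    _, data = study
    fitted = fit_rsm(data, STUDY_MODEL_SPECS["PS"])
    y = data.means("PS")
    coded = data.design.coded_matrix
    assert fitted.coefficients["1"] == pytest.approx(y.mean(), rel=1e-12)
    for j, term in enumerate(("x1", "x2", "x3")):
        contrast = (y[coded[:, j] == 1].sum() - y[coded[:, j] == -1].sum()) / 8.0
        assert fitted.coefficients[term] == pytest.approx(contrast, rel=1e-12)


def test_orthogonal_term_addition_leaves_main_effects_unchanged(study):
    _, data = study
    base = fit_rsm(data, ModelSpec("PS", "identity", ("1", "x1", "x2", "x3")))
    bigger = fit_rsm(data, ModelSpec("PS", "identity",
                                     ("1", "x1", "x2", "x3", "x1:x2", "x2:x3")))
    for term in ("x1", "x2", "x3"):
        assert bigger.coefficients[term] == pytest.approx(
            base.coefficients[term], rel=1e-12)


def test_fit_errors():
    import nanodoe as nd
    factors = nd.datasets.load_factors()
    design = build_bbd(factors, n_center=5)
    data = simulate_bbd_responses(design, [STUDY_TRUTHS[0]], seed=3)
    with pytest.raises(KeyError):
        fit_rsm(data, ModelSpec("nope", "identity", ("1", "x1")))
    negative = nd.ResponseSet(
        design=design,
        responses={"y": [(-1.0, None)] * design.n_runs},
    )
    with pytest.raises(ValueError, match="ln transform"):
        fit_rsm(negative, ModelSpec("y", "ln", ("1", "x1")))
    with pytest.raises(ValueError, match="unknown terms"):
        ModelSpec("y", "identity", ("1", "x9"))


# ------------------------------------------------------------------ ANOVA

def test_residual_decomposes_into_lack_of_fit_plus_pure_error(study):
    _, data = study
    for name, spec in STUDY_MODEL_SPECS.items():
        fitted = fit_rsm(data, spec)
        a = fitted.anova
        assert a["residual_ss"] == pytest.approx(
            a["lack_of_fit_ss"] + a["pure_error_ss"], rel=1e-9)
        assert fitted.residual_df == data.design.n_runs - len(fitted.terms)
        assert 0.0 <= fitted.r2 <= 1.0


def test_pure_error_df_and_brute_force_ss(study):
    """Five center replicates give 4 pure-error df; SS matches a direct
    sum over replicate groups of (y - group mean)^2."""
    _, data = study
    fitted = fit_rsm(data, STUDY_MODEL_SPECS["PS"])
    lof = lack_of_fit(fitted, data)
    assert lof["pure_error_df"] == 4
    y = data.means("PS")
    center = np.all(data.design.coded_matrix == 0.0, axis=1)
    brute = np.sum((y[center] - y[center].mean()) ** 2)
    assert lof["pure_error_ss"] == pytest.approx(brute, rel=1e-12)


def test_lack_of_fit_requires_replicates(factors):
    import nanodoe as nd
    design = build_bbd(factors, n_center=1)
    data = simulate_bbd_responses(design, [STUDY_TRUTHS[0]], seed=1)
    fitted = fit_rsm(data, ModelSpec("PS", "identity", ("1", "x1", "x2", "x3")))
    with pytest.raises(ValueError, match="replicated"):
        lack_of_fit(fitted, data)


def test_lack_of_fit_p_matches_scipy_f_tail(study):
    _, data = study
    fitted = fit_rsm(data, STUDY_MODEL_SPECS["EE"])
    lof = lack_of_fit(fitted, data)
    expected_p = stats.f.sf(lof["F"], lof["lack_of_fit_df"], lof["pure_error_df"])
    assert lof["p"] == pytest.approx(expected_p, rel=1e-12)


# -------------------------------------------------------------- selection

def test_selection_on_noiseless_linear_truth_returns_linear_terms(factors):
    from nanodoe import TruthModel
    design = build_bbd(factors, n_center=5)
    truth = TruthModel("y", {"1": 50.0, "x1": 5.0, "x2": -3.0, "x3": 8.0},
                       "identity", 0.0)
    data = simulate_bbd_responses(design, [truth], seed=0)
    spec = select_terms(data, "y", "identity")
    assert set(spec.terms) == {"1", "x1", "x2", "x3"}


def test_selection_for_entrapment_retains_ipm_and_its_square(study):
    _, data = study
    spec = select_terms(data, "EE", "identity")
    assert "x3" in spec.terms and "x3^2" in spec.terms


def test_selection_leaves_retained_main_effect_estimates_unchanged(study):
    """Orthogonality: main effects surviving backward elimination carry the
    same estimates as in the full quadratic model.  Chitosan and IPM, the
    strong size drivers, always survive."""
    _, data = study
    spec = select_terms(data, "PS", "identity")
    assert {"x2", "x3"} <= set(spec.terms)
    selected = fit_rsm(data, spec)
    full = fit_rsm(data, ModelSpec("PS", "identity", FULL_QUADRATIC))
    for term in ("x1", "x2", "x3"):
        if term in spec.terms:
            assert selected.coefficients[term] == pytest.approx(
                full.coefficients[term], rel=1e-9)


# ---------------------------------------------------- standardized effects

def test_standardized_effects_are_coef_over_se_sorted_descending(study_models):
    for fitted in study_models.values():
        effects = standardized_effects(fitted)
        mags = [abs(t) for _, t, _ in effects]
        assert mags == sorted(mags, reverse=True)
        for term, t, _ in effects:
            assert t == pytest.approx(
                fitted.coefficients[term] / fitted.standard_errors[term],
                rel=1e-12)


def test_chitosan_dominates_size_and_charge_ipm_dominates_entrapment(study_models):
    def top_main(fitted):
        ranked = [t for t, _, _ in standardized_effects(fitted)
                  if t in ("x1", "x2", "x3")]
        return ranked[0]

    assert top_main(study_models["PS"]) == "x2"
    assert top_main(study_models["ZP"]) == "x2"
    assert top_main(study_models["EE"]) == "x3"


def test_significance_flag_uses_critical_t(study_models):
    fitted = study_models["PS"]
    t_crit = stats.t.ppf(0.975, fitted.residual_df)
    for term, t, sig in standardized_effects(fitted):
        assert sig == (abs(t) > t_crit)


# ------------------------------------------------------------- prediction

def test_center_prediction_is_intercept_for_identity_model(study_models):
    fitted = study_models["PS"]
    assert predict(fitted, (0.0, 0.0, 0.0)) == pytest.approx(
        fitted.coefficients["1"], rel=1e-12)


def test_ln_model_back_transforms_with_exp(study_models):
    fitted = study_models["ZP"]
    assert predict(fitted, (0.0, 0.0, 0.0)) == pytest.approx(
        np.exp(fitted.coefficients["1"]), rel=1e-12)


def test_prediction_outside_cube_requires_extrapolate_flag(study_models):
    with pytest.raises(ValueError, match="extrapolate"):
        predict(study_models["PS"], (1.5, 0.0, 0.0))
    assert predict(study_models["PS"], (1.5, 0.0, 0.0), extrapolate=True) > 0


# ----------------------------------------------------------------- grids

def test_surface_corners_match_predict(study_models):
    fitted = study_models["PS"]
    grid = surface_grid(fitted, ("lecithin_mg", "chitosan_mg"),
                        fixed_value=0.0, resolution=2)
    assert len(grid) == 4
    for _, row in grid.iterrows():
        point = (row["lecithin_mg"], row["chitosan_mg"], row["ipm_pct"])
        assert row["PS"] == pytest.approx(predict(fitted, point), rel=1e-12)


def test_size_surface_increases_with_chitosan_and_ipm(study_models):
    """The fitted PS surface rises with both chitosan and IPM levels."""
    grid = surface_grid(study_models["PS"], ("chitosan_mg", "ipm_pct"),
                        fixed_value=0.0, resolution=11)
    wide = grid.pivot(index="chitosan_mg", columns="ipm_pct", values="PS")
    assert (wide.diff().dropna() > 0).all().all()          # along chitosan
    assert (wide.T.diff().dropna() > 0).all().all()        # along IPM


def test_surface_values_equal_polynomial_evaluation(study_models):
    fitted = study_models["EE"]
    grid = surface_grid(fitted, ("chitosan_mg", "ipm_pct"),
                        fixed_value=0.5, resolution=5)
    c = fitted.coefficients
    for _, row in grid.sample(6, random_state=0).iterrows():
        x1, x2, x3 = row["lecithin_mg"], row["chitosan_mg"], row["ipm_pct"]
        manual = (c["1"] + c["x1"] * x1 + c["x2"] * x2 + c["x3"] * x3
                  + c["x2:x3"] * x2 * x3 + c["x3^2"] * x3**2)
        assert row["EE"] == pytest.approx(manual, rel=1e-12)


def test_surface_rejects_unknown_factor(study_models):
    with pytest.raises(KeyError, match="unknown factor"):
        surface_grid(study_models["PS"], ("nope", "chitosan_mg"))
    with pytest.raises(ValueError, match="resolution"):
        surface_grid(study_models["PS"], ("lecithin_mg", "chitosan_mg"),
                     resolution=1)
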