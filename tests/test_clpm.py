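"""Cross-lagged panel model: structure, ML/FIML estimation, fit indices."""

import numpy as np
import pandas as pd
import pytest

from frailpanel import (
    CLPMSpec,
    CovariateEffect,
    PanelTruth,
    build_model,
    classify_hypothesis,
    fit_fiml,
    fit_indices_from_chi2,
    fit_ml,
    generate_panel,
    standardized_paths,
    wald_ci,
)

CORE = CLPMSpec(covariates=[])
PATHS = [
    ("frailty_t2", "frailty_t1"),
    ("frailty_t2", "behaviour_t1"),
    ("behaviour_t2", "frailty_t1"),
    ("behaviour_t2", "behaviour_t1"),
]


def _ols(y, X):
    X1 = np.column_stack([np.ones(len(y))] + list(X))
    return np.linalg.lstsq(X1, y, rcond=None)[0][1:]


class TestBuildModel:
    def test_core_structure_is_just_identified(self):
        panel = generate_panel(PanelTruth(n=100, seed=0))
        model = build_model(CORE, panel)
        assert model.free.sum() == 4            # 2 autoregressive + 2 cross paths
        assert model.p == 2
        # saturated: free params = saturated moment count
        assert model.n_free_params == model.d + model.d * (model.d + 1) // 2

    def test_categorical_covariate_expands_to_indicators(self):
        panel = generate_panel(PanelTruth(n=200, seed=0))
        model = build_model(CLPMSpec(covariates=["education"]), panel)
        edu_cols = [c for c in model.x_names if c.startswith("education_")]
        assert len(edu_cols) == 2               # 3 levels -> 2 reference-coded columns

    def test_duplicated_covariate_rejected(self):
        panel = generate_panel(PanelTruth(n=100, seed=0))
        with pytest.raises(ValueError, match="duplicated"):
            build_model(CLPMSpec(covariates=["age", "age"]), panel)

    def test_collinear_design_names_aliased_column(self):
        panel = generate_panel(PanelTruth(n=100, seed=0))
        panel["age_copy"] = panel["age_t1"]
        with pytest.raises(ValueError, match="age_copy"):
            build_model(CLPMSpec(covariates=["age", "age_copy"]), panel)


class TestMLEstimation:
    def test_paths_equal_per_equation_least_squares(self):
        """Recursive-model oracle: ML path estimates coincide with OLS."""
        for seed in range(10):
            panel = generate_panel(PanelTruth(n=400, seed=seed))
            res = fit_ml(panel, spec=CORE)
            f1, b1 = panel.frailty_t1.to_numpy(), panel.behaviour_t1.to_numpy()
            bf = _ols(panel.frailty_t2.to_numpy(), [f1, b1])
            bb = _ols(panel.behaviour_t2.to_numpy(), [b1, f1])
            assert res.path("frailty_t2", "frailty_t1").estimate == pytest.approx(bf[0], abs=1e-6)
            assert res.path("frailty_t2", "behaviour_t1").estimate == pytest.approx(bf[1], abs=1e-6)
            assert res.path("behaviour_t2", "behaviour_t1").estimate == pytest.approx(bb[0], abs=1e-6)
            assert res.path("behaviour_t2", "frailty_t1").estimate == pytest.approx(bb[1], abs=1e-6)

    def test_large_sample_recovery_of_cohort_style_truth(self):
        truth = PanelTruth(
            n=100_000, a_frailty=0.6, c_behaviour_to_frailty=-0.126,
            c_frailty_to_behaviour=0.0, seed=8,
        )
        res = fit_ml(generate_panel(truth), spec=CORE)
        assert res.path("frailty_t2", "frailty_t1").estimate == pytest.approx(0.6, abs=0.02)
        assert res.path("frailty_t2", "behaviour_t1").estimate == pytest.approx(-0.126, abs=0.02)

    def test_constrained_model_matches_optimizer_free_fit(self):
        """Dropping a covariate from one equation makes the model
        non-saturated; the optimizer must still match OLS per equation
        (the removed path is simply absent)."""
        truth = PanelTruth(n=3000, seed=11)
        panel = generate_panel(truth)
        spec = CLPMSpec(covariates_frailty=["age"], covariates_behaviour=[])
        res = fit_ml(panel, spec=spec)
        names = {(r.outcome, r.predictor) for _, r in res.params.iterrows()}
        assert ("behaviour_t2", "age_t2") not in names
        assert ("frailty_t2", "age_t2") in names
        assert res.converged
        assert res.fit.df_model > 0

    def test_degenerate_noise_free_data(self):
        rng = np.random.default_rng(0)
        f1 = rng.standard_normal(500)
        b1 = rng.standard_normal(500)
        panel = pd.DataFrame(
            {
                "participant_id": [f"P{i}" for i in range(500)],
                "frailty_t1": f1,
                "behaviour_t1": b1,
                "frailty_t2": 0.6 * f1 - 0.2 * b1,
                "behaviour_t2": 0.5 * b1 + 0.1 * f1,
            }
        )
        res = fit_ml(panel, spec=CORE)
        assert res.fit.chi2_model < 1e-6
        assert res.path("frailty_t2", "frailty_t1").estimate == pytest.approx(0.6, abs=1e-8)
        assert any("degenerate" in w for w in res.warnings)
        assert res.path("frailty_t2", "frailty_t1").se == 0.0


class TestFIML:
    def test_reduces_to_ml_without_missingness(self):
        panel = generate_panel(PanelTruth(n=800, seed=12))
        r_ml = fit_ml(panel, spec=CORE)
        r_fi = fit_fiml(panel, spec=CORE)
        assert np.allclose(r_ml.params.estimate, r_fi.params.estimate, atol=1e-6)
        assert np.allclose(r_ml.params.se, r_fi.params.se, atol=1e-6)

    def test_mcar_consistency(self):
        truth = PanelTruth(n=10_000, missing_rate=0.3, missing_mechanism="MCAR", seed=13)
        res = fit_fiml(generate_panel(truth), spec=CORE)
        for (out, pred), tv in zip(PATHS, (0.6, -0.126, 0.167, 0.5)):
            row = res.path(out, pred)
            assert abs(row.estimate - tv) < 3 * row.se

    def test_fiml_less_biased_than_complete_case_under_mar(self):
        """Wave-level MAR dropout depends on observed wave-1 variables;
        complete-case standardized estimates are then distorted by the
        selection of the wave-1 distribution, while FIML recovers the
        full-population covariance.  Averaged over replicates, FIML's
        standardized cross-path bias must be the smaller one."""
        tv = -0.126
        fiml_est, cc_est = [], []
        for seed in range(200):
            truth = PanelTruth(
                n=2000, missing_rate=0.595, missing_mechanism="MAR",
                behaviour_name="sb", seed=seed,
            )
            panel = generate_panel(truth)
            fiml_est.append(
                fit_fiml(panel, spec=CORE).path("frailty_t2", "behaviour_t1").std_estimate
            )
            cc_est.append(
                fit_ml(panel, spec=CORE).path("frailty_t2", "behaviour_t1").std_estimate
            )
        bias_fiml = abs(np.mean(fiml_est) - tv)
        bias_cc = abs(np.mean(cc_est) - tv)
        assert bias_fiml < bias_cc

    def test_inestimable_variable_rejected(self):
        panel = generate_panel(PanelTruth(n=50, seed=14))
        panel["frailty_t2"] = np.nan
        with pytest.raises(ValueError):
            fit_fiml(panel, spec=CORE)


class TestStandardization:
    def test_prestandardized_data_equal_unstandardized(self):
        panel = generate_panel(PanelTruth(n=200_000, seed=15))
        res = fit_ml(panel, spec=CORE)
        for out, pred in PATHS:
            row = res.path(out, pred)
            assert row.std_estimate == pytest.approx(row.estimate, abs=0.01)

    def test_scale_invariance_of_standardized_paths(self):
        panel = generate_panel(PanelTruth(n=1500, seed=16))
        res1 = fit_ml(panel, spec=CORE)
        rescaled = panel.copy()
        rescaled["behaviour_t1"] = panel["behaviour_t1"] / 60.0  # minutes -> hours
        rescaled["behaviour_t2"] = panel["behaviour_t2"] * 3.0 + 7.0
        res2 = fit_ml(rescaled, spec=CORE)
        for out, pred in PATHS:
            assert res2.path(out, pred).std_estimate == pytest.approx(
                res1.path(out, pred).std_estimate, abs=1e-6
            )

    def test_against_covariance_algebra_oracle(self):
        """Hand computation on a 4-variable toy model: with
        y = Gamma x + e, Var(y) = Gamma Sxx Gamma' + Psi and the
        standardized path is b * sd(x)/sd(y), expanded element by element."""
        Gamma = np.array([[0.5, -0.2], [0.1, 0.4]])
        Sxx = np.array([[4.0, 1.0], [1.0, 9.0]])
        Psi = np.array([[2.0, 0.3], [0.3, 1.5]])
        got = standardized_paths(Gamma, Sxx, Psi)
        var_y0 = (
            0.5**2 * 4.0 + (-0.2) ** 2 * 9.0 + 2 * 0.5 * (-0.2) * 1.0 + 2.0
        )
        var_y1 = 0.1**2 * 4.0 + 0.4**2 * 9.0 + 2 * 0.1 * 0.4 * 1.0 + 1.5
        assert got[0, 0] == pytest.approx(0.5 * 2.0 / np.sqrt(var_y0), abs=1e-12)
        assert got[0, 1] == pytest.approx(-0.2 * 3.0 / np.sqrt(var_y0), abs=1e-12)
        assert got[1, 0] == pytest.approx(0.1 * 2.0 / np.sqrt(var_y1), abs=1e-12)
        assert got[1, 1] == pytest.approx(0.4 * 3.0 / np.sqrt(var_y1), abs=1e-12)

    def test_zero_implied_variance_rejected(self):
        with pytest.raises(ValueError):
            standardized_paths(
                np.zeros((2, 2)), np.eye(2), np.zeros((2, 2))
            )


class TestInference:
    def test_wald_duality_ci_excludes_zero_iff_significant(self):
        panel = generate_panel(PanelTruth(n=600, seed=17))
        res = fit_ml(panel, spec=CORE)
        for _, row in res.params.iterrows():
            excludes = row.ci_low > 0 or row.ci_high < 0
            assert excludes == (row.pvalue < res.alpha)

    def test_degenerate_se_gives_point_interval(self):
        lo, hi = wald_ci(1.3, 0.0)
        assert lo == hi == 1.3

    def test_ci_brackets_estimate(self):
        lo, hi = wald_ci(-0.126, 0.0536)
        assert lo < -0.126 < hi
        assert lo == pytest.approx(-0.231, abs=0.001)
        assert hi == pytest.approx(-0.021, abs=0.001)


class TestFitIndices:
    def test_just_identified_model_has_perfect_fit(self):
        panel = generate_panel(PanelTruth(n=500, seed=18))
        res = fit_ml(panel, spec=CORE)
        assert res.fit.df_model == 0
        assert res.fit.chi2_model < 1e-6
        assert res.fit.rmsea == 0.0
        assert res.fit.cfi == 1.0
        assert res.fit.srmr < 1e-6

    def test_formula_oracle_on_printed_chi_squares(self):
        fi = fit_indices_from_chi2(12.0, 5, 100.0, 9, 200)
        assert fi.rmsea == pytest.approx(np.sqrt(7.0 / (5 * 200)), abs=1e-8)
        assert fi.cfi == pytest.approx(1 - 7.0 / 91.0, abs=1e-8)
        rb, rm = 100.0 / 9, 12.0 / 5
        assert fi.tli == pytest.approx((rb - rm) / (rb - 1), abs=1e-8)

    def test_chi2_equal_df_gives_zero_rmsea(self):
        fi = fit_indices_from_chi2(5.0, 5, 50.0, 9, 100)
        assert fi.rmsea == 0.0

    def test_baseline_must_be_restrictive(self):
        with pytest.raises(ValueError):
            fit_indices_from_chi2(1.0, 1, 10.0, 0, 100)


class TestVerdicts:
    @pytest.mark.parametrize(
        "p_bf, p_fb, expected",
        [
            (0.03, 0.48, "H2"),   # MVPA-model outcome pattern
            (0.18, 0.02, "H1"),   # SB-model outcome pattern
            (0.50, 0.50, "H0"),
            (0.01, 0.01, "H3"),
        ],
    )
    def test_truth_table(self, p_bf, p_fb, expected):
        assert classify_hypothesis(p_bf, p_fb, alpha=0.05) == expected

    def test_all_verdicts_reachable(self):
        verdicts = {
            classify_hypothesis(pb, pf)
            for pb in (0.01, 0.5)
            for pf in (0.01, 0.5)
        }
        assert verdicts == {"H0", "H1", "H2", "H3"}
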