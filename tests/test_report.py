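"""Cohort flow accounting, descriptive tests, and the pipeline driver."""

import numpy as np
import pandas as pd
import pytest

from frailpanel import (
    CohortFlow,
    PanelTruth,
    apply_exclusion_cascade,
    attrition_compare,
    generate_panel,
    paired_t,
)
from frailpanel.report import bundle_to_json, descriptive_table, run_pipeline


class TestCohortFlow:
    def test_stage_arithmetic_enforced(self):
        flow = CohortFlow(494, 42, 225, 27, 9, 2, 3)
        assert flow.completed_followup == 200
        assert flow.final_n == 186

    def test_no_exclusions_identity(self):
        flow = CohortFlow(100, 0, 0, 0, 0, 0, 0)
        assert flow.final_n == flow.baseline_valid == 100

    def test_overdrawn_cascade_rejected(self):
        with pytest.raises(ValueError):
            CohortFlow(10, 5, 5, 5, 0, 0, 0)
        with pytest.raises(ValueError):
            CohortFlow(10, -1, 0, 0, 0, 0, 0)


class TestExclusionCascade:
    def _panel(self, n=20):
        return pd.DataFrame(
            {
                "participant_id": [f"P{i}" for i in range(n)],
                "frailty_t1": 1.0,
                "frailty_t2": 1.0,
                "behaviour_t1": 1.0,
                "behaviour_t2": 1.0,
                "dropout": False,
            }
        )

    def test_planted_exclusions_recovered(self):
        panel = self._panel(20)
        panel.loc[:4, "dropout"] = True
        panel.loc[:4, ["frailty_t2", "behaviour_t2"]] = np.nan
        panel["loss_reason"] = ""
        panel.loc[:1, "loss_reason"] = "death"
        panel.loc[2:3, "loss_reason"] = "refusal"
        panel.loc[4, "loss_reason"] = "not_located"
        activity_valid = pd.Series({"P5": False, "P6": False})
        fts_valid = pd.Series({"P7": False})
        flow, analytic = apply_exclusion_cascade(panel, activity_valid, fts_valid)
        assert flow.to_dict() == {
            "baseline_valid": 20, "deaths": 2, "refusals": 2, "not_located": 1,
            "completed_followup": 15, "excluded_wear_time": 2,
            "excluded_frailty_missing": 1, "excluded_covariates": 0,
            "final_n": 12, "attrition_pct": 25.0,
        }
        assert len(analytic) == 12
        assert "P5" not in set(analytic.participant_id)

    def test_covariate_missingness_rule(self):
        panel = self._panel(10)
        for c in ["age_t1", "age_t2", "sex", "bmi_t1", "bmi_t2"]:
            panel[c] = 1.0
        panel.loc[0, ["age_t1", "age_t2"]] = np.nan  # 2/5 = 40% missing
        panel.loc[1, "age_t1"] = np.nan              # 20%, retained
        flow, analytic = apply_exclusion_cascade(
            panel, covariate_cols=["age_t1", "age_t2", "sex", "bmi_t1", "bmi_t2"]
        )
        assert flow.excluded_covariates == 1
        assert "P0" not in set(analytic.participant_id)
        assert "P1" in set(analytic.participant_id)

    def test_duplicate_ids_rejected(self):
        panel = self._panel(5)
        panel.loc[4, "participant_id"] = "P0"
        with pytest.raises(ValueError, match="duplicate"):
            apply_exclusion_cascade(panel)


class TestPairedT:
    def test_identical_waves_null(self):
        t, p, degen = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 1.0 and not degen

    def test_constant_difference_degenerate(self):
        t, p, degen = paired_t([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
        assert np.isinf(t) and p == 0.0 and degen

    def test_matches_textbook_formula(self, rng):
        x1 = rng.normal(size=50)
        x2 = x1 + rng.normal(0.3, 1.0, size=50)
        t, p, _ = paired_t(x1, x2)
        d = x2 - x1
        t_ref = d.mean() / (d.std(ddof=1) / np.sqrt(50))
        from scipy import stats

        p_ref = 2 * stats.t.sf(abs(t_ref), df=49)
        assert t == pytest.approx(t_ref, abs=1e-10)
        assert p == pytest.approx(p_ref, abs=1e-10)

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            paired_t([1.0], [2.0])


class TestAttritionCompare:
    def test_identical_distributions_nonsignificant(self, rng):
        x = rng.normal(size=400)
        t, p = attrition_compare(x, x)
        assert abs(t) < 1e-12 and p > 0.99

    def test_chi2_matches_hand_computation(self):
        # 2x2 table [[30, 10], [20, 40]]
        retained = ["a"] * 30 + ["b"] * 10
        dropped = ["a"] * 20 + ["b"] * 40
        chi2, p = attrition_compare(retained, dropped, categorical=True)
        n = 100
        observed = np.array([[30, 20], [10, 40]])  # rows: level a/b, cols: retained/dropped
        expected = np.outer(observed.sum(axis=1), observed.sum(axis=0)) / n
        chi2_ref = ((observed - expected) ** 2 / expected).sum()
        assert chi2 == pytest.approx(chi2_ref, abs=1e-10)

    def test_welch_t_on_mar_cohort_detects_age_difference(self):
        panel = generate_panel(
            PanelTruth(n=10_000, missing_rate=0.5, missing_mechanism="MAR", seed=21)
        )
        drop = panel.dropout
        t, p = attrition_compare(panel.age_t1[~drop], panel.age_t1[drop])
        assert p < 0.05
        assert t < 0  # retained younger

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            attrition_compare([1.0, 2.0], [])


class TestDescriptives:
    def test_reproduces_generator_means(self):
        panel = generate_panel(PanelTruth(n=30_000, seed=22), scale="natural")
        table = descriptive_table(
            panel,
            continuous=[("frailty_t1", "frailty_t2"), ("behaviour_t1", "behaviour_t2")],
            categorical=["sex"],
        )
        frailty = table[table.variable == "frailty"].iloc[0]
        assert frailty.baseline_mean == pytest.approx(35.35, rel=0.02)
        assert frailty.paired_p < 0.05  # configured wave-2 shift is real
        sex = table[table.variable == "sex"].iloc[0]
        assert "female" in sex.levels

    def test_categorical_percentages_sum_to_100(self):
        panel = generate_panel(PanelTruth(n=5000, seed=23))
        table = descriptive_table(panel, categorical=["education", "marital"])
        for _, row in table.iterrows():
            pcts = [float(part.split("(")[1].rstrip("%)")) for part in row.levels.split("; ")]
            assert sum(pcts) == pytest.approx(100.0, abs=0.2)


class TestPipeline:
    CFG = {
        "seed": 7,
        "synth": {"n": 60, "scale": "natural", "missing_rate": 0.3},
        "accel": {"enabled": True, "days": 7},
        "fts": {"enabled": True},
        "report": {
            "planted_invalid_accel": 3,
            "planted_invalid_fts": 2,
            "planted_missing_covariates": 1,
        },
    }

    def test_end_to_end_deterministic_and_balanced(self, tmp_path):
        b1 = run_pipeline(self.CFG, out_dir=tmp_path / "run1")
        b2 = run_pipeline(self.CFG)
        assert bundle_to_json(b1) == bundle_to_json(b2)
        for m in b1["models"].values():
            flow = m["flow"]
            assert (
                flow["baseline_valid"]
                - flow["deaths"] - flow["refusals"] - flow["not_located"]
                == flow["completed_followup"]
            )
            assert flow["excluded_wear_time"] == 3
            assert flow["excluded_frailty_missing"] == 2
            assert flow["excluded_covariates"] == 1
        for name in ("flow.json", "descriptives.csv", "clpm_mvpa.json",
                     "clpm_sb.json", "report.md"):
            assert (tmp_path / "run1" / name).exists()

    def test_bad_config_aborts_with_stage_name(self):
        from frailpanel import PipelineError

        cfg = {"seed": 1, "synth": {"n": 50, "mvpa": {"a_frailty": 2.0}}}
        with pytest.raises(PipelineError) as err:
            run_pipeline(cfg)
        assert err.value.stage == "synth"

    def test_null_cross_paths_mostly_h0(self):
        """With both cross paths at zero the verdict is H0 unless one of
        the two 5%-level tests rejects: P(H0) = (1-alpha)^2 ~ 0.90."""
        cfg = {
            "seed": 0,
            "synth": {
                "n": 1000, "scale": "standardized", "missing_rate": 0.0,
                "mvpa": {"c_behaviour_to_frailty": 0.0, "c_frailty_to_behaviour": 0.0},
                "sb": {"c_behaviour_to_frailty": 0.0, "c_frailty_to_behaviour": 0.0},
            },
        }
        verdicts = []
        for seed in range(60):
            b = run_pipeline({**cfg, "seed": seed})
            verdicts += [m["clpm"]["verdict"] for m in b["models"].values()]
        rate = np.mean([v == "H0" for v in verdicts])
        assert rate == pytest.approx(0.95**2, abs=0.06)
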