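"""G-computation identities, prescreen behaviour, bootstrap contracts,
effect sizes."""

import numpy as np
import pandas as pd
import pytest

import ecdtrial as et
from ecdtrial.estimation import EstimationError


def brute_force_gcompute(model, X, scale):
    """Independent oracle: edit every record's arm column, predict row by
    row from the fitted coefficients, and average the counterfactuals."""
    preds = {0.0: [], 1.0: []}
    for arm_value in (1.0, 0.0):
        for i in range(X.shape[0]):
            row = X[i].copy()
            row[1] = arm_value
            eta = float(row @ model.params)
            preds[arm_value].append(
                eta if scale == "continuous" else 1.0 / (1.0 + np.exp(-eta)))
    return float(np.mean(preds[1.0]) - np.mean(preds[0.0]))


class TestGComputation:
    def test_no_covariates_equals_raw_mean_difference(self, scored_trial):
        spec = et.OutcomeSpec("cesd", "continuous")
        est = et.gcompute(scored_trial, spec, [], ("group", "control"))
        sub = scored_trial[scored_trial.followed_up].dropna(subset=["cesd"])
        raw = (sub.loc[sub.arm == "group", "cesd"].mean()
               - sub.loc[sub.arm == "control", "cesd"].mean())
        assert est.estimate == pytest.approx(raw, abs=1e-12)

    def test_binary_no_covariates_equals_prevalence_difference(self, scored_trial):
        spec = et.OutcomeSpec("lead_knowledge", "binary")
        est = et.gcompute(scored_trial, spec, [], ("combined", "control"))
        sub = scored_trial[scored_trial.followed_up].dropna(subset=["lead_knowledge"])
        raw = (sub.loc[sub.arm == "combined", "lead_knowledge"].mean()
               - sub.loc[sub.arm == "control", "lead_knowledge"].mean())
        assert est.estimate == pytest.approx(raw, abs=1e-8)

    def test_linear_adjusted_equals_arm_coefficient(self, scored_trial):
        # no arm x covariate interaction: the marginal difference is the
        # arm coefficient itself (linear collapsibility)
        spec = et.OutcomeSpec("cesd", "continuous")
        covs = ["child_age_months_endline", "cesd_baseline"]
        est = et.gcompute(scored_trial, spec, covs, ("group", "control"),
                          return_model=True)
        assert est.estimate == pytest.approx(est.model.params[1], abs=1e-10)

    def test_logistic_gcomputation_is_not_collapsible(self):
        # strong binary confounder with unbalanced prevalence: the marginal
        # (standardised) difference differs from the one implied by setting
        # the covariate to any fixed level
        rng = np.random.default_rng(4)
        n = 4000
        w = rng.random(n) < 0.5
        arm = np.where(rng.random(n) < 0.5, "group", "control")
        logit = -2.0 + 3.0 * w + 1.0 * (arm == "group")
        y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(float)
        df = pd.DataFrame({"arm": arm, "cluster_id": np.arange(n) % 50,
                           "y": y, "w": w.astype(float), "followed_up": True})
        spec = et.OutcomeSpec("y", "binary")
        est = et.gcompute(df, spec, ["w"], ("group", "control"), return_model=True)
        b0, b_arm, b_w = est.model.params

        def expit(x):
            return 1 / (1 + np.exp(-x))

        conditional_at_w0 = expit(b0 + b_arm) - expit(b0)
        conditional_at_w1 = expit(b0 + b_arm + b_w) - expit(b0 + b_w)
        assert not est.estimate == pytest.approx(conditional_at_w0, abs=1e-3)
        assert not est.estimate == pytest.approx(conditional_at_w1, abs=1e-3)
        # but it must still match the counterfactual-averaging oracle
        sub = df.dropna()
        X = np.column_stack([np.ones(n), (sub.arm == "group").to_numpy(float),
                             sub.w.to_numpy()])
        assert est.estimate == pytest.approx(
            brute_force_gcompute(est.model, X, "binary"), abs=1e-10)

    def test_empty_arm_raises(self, scored_trial):
        only_control = scored_trial[scored_trial.arm == "control"]
        with pytest.raises(EstimationError, match="empty arm"):
            et.gcompute(only_control, et.OutcomeSpec("cesd", "continuous"),
                        [], ("group", "control"))

    def test_consistency_large_trial_recovers_effect(self):
        # 200 clusters, additive effect on an unbounded scale
        delta = 1.0
        ds = et.simulate_trial(
            n_clusters_per_arm_per_stratum={"A": {"group": 80, "control": 120}},
            outcome_effects={"cdi_receptive": {"group": delta}},
            clip_scores=False, attrition_rate=0.0, outlier_rate=0.0, seed=31)
        spec = et.OutcomeSpec("cdi_receptive", "continuous")
        est = et.gcompute(ds.df, spec, ["child_age_months_endline"],
                          ("group", "control"))
        # MC error of the arm contrast at 200 clusters of 20, rho=.2
        se = 16.0 * np.sqrt(4.8 * (1 / 1600 + 1 / 2400))
        assert est.estimate == pytest.approx(delta, abs=3 * se)


class TestPrescreen:
    def test_perfect_predictor_always_retained(self, scored_trial):
        df = scored_trial.copy()
        rng = np.random.default_rng(0)
        df["cesd_baseline"] = df["cesd"] + rng.normal(0, 0.1, len(df))
        spec = et.OutcomeSpec("cesd", "continuous",
                              candidate_covariates=("cesd_baseline",))
        assert et.prescreen_covariates(df, spec) == ["cesd_baseline"]

    def test_empty_candidates_empty_result(self, scored_trial):
        spec = et.OutcomeSpec("cesd", "continuous")
        assert et.prescreen_covariates(scored_trial, spec) == []

    def test_retained_in_registered_order(self, scored_trial):
        spec = et.OutcomeSpec(
            "cesd", "continuous",
            candidate_covariates=("cesd_baseline", "child_age_months_endline"))
        retained = et.prescreen_covariates(scored_trial, spec, alpha_screen=1.0)
        assert retained == ["cesd_baseline", "child_age_months_endline"]

    def test_constant_covariate_dropped_with_warning(self, scored_trial, caplog):
        df = scored_trial.copy()
        df["wall_material"] = True
        spec = et.OutcomeSpec("cesd", "continuous",
                              candidate_covariates=("wall_material",))
        with caplog.at_level("WARNING"):
            assert et.prescreen_covariates(df, spec) == []
        assert "constant" in caplog.text

    def test_binary_outcome_prescreen_runs(self, scored_trial):
        spec = et.OutcomeSpec(
            "lead_knowledge", "binary",
            candidate_covariates=("maternal_primary_education", "electricity"))
        retained = et.prescreen_covariates(scored_trial, spec)
        assert set(retained) <= {"maternal_primary_education", "electricity"}


class TestClusterBootstrap:
    def test_constant_estimator_degenerate_ci(self, scored_trial):
        lo, hi = et.cluster_bootstrap(scored_trial, lambda d: 3.14, B=50, seed=0)
        assert lo == hi == 3.14

    def test_same_seed_same_ci(self, scored_trial):
        est = lambda d: d.loc[d.arm == "group", "cesd"].mean()
        a = et.cluster_bootstrap(scored_trial, est, B=100, seed=42)
        b = et.cluster_bootstrap(scored_trial, est, B=100, seed=42)
        assert a == b
        c = et.cluster_bootstrap(scored_trial, est, B=100, seed=43)
        assert a != c

    def test_resampling_is_stratified_by_arm(self, scored_trial):
        # every replicate must keep each arm's cluster count
        def checker(d):
            counts = d.groupby("arm")["cluster_id"].nunique()
            # with-replacement draws can repeat villages, never exceed
            assert counts["control"] <= 15 and counts["group"] <= 8
            assert set(counts.index) == {"control", "group", "combined"}
            return 0.0

        et.cluster_bootstrap(scored_trial, checker, B=20, seed=1)

    def test_failure_budget_exceeded_raises(self, scored_trial):
        def flaky(d):
            raise RuntimeError("boom")

        with pytest.raises(EstimationError, match="replicates failed"):
            et.cluster_bootstrap(scored_trial, flaky, B=50, seed=0)

    def test_single_cluster_arm_rejected(self, scored_trial):
        df = scored_trial[scored_trial.cluster_id.isin(["V001", "V009"])]
        with pytest.raises(ValueError, match="fewer than 2 clusters"):
            et.cluster_bootstrap(df, lambda d: 0.0, B=10, seed=0)


class TestCohensD:
    def test_identical_groups_zero(self):
        d, lo, hi = et.cohens_d(5.0, 1.0, 50, 5.0, 1.0, 50)
        assert d == 0.0 and lo < 0 < hi

    def test_zero_pooled_sd_error(self):
        with pytest.raises(ValueError, match="pooled SD"):
            et.cohens_d(5.0, 0.0, 50, 4.0, 0.0, 50)

    def test_known_value(self):
        d, _, _ = et.cohens_d(1.0, 1.0, 100, 0.0, 1.0, 100)
        assert d == pytest.approx(1.0)


class TestAdjustedMeans:
    def test_constant_age_reduces_to_raw_arm_means(self, scored_trial):
        df = scored_trial.copy()
        df["child_age_months_endline"] = 15.0
        spec = et.OutcomeSpec("cesd", "continuous")
        res = et.adjusted_means(df, spec, B=0)
        sub = df[df.followed_up].dropna(subset=["cesd"])
        for _, row in res.iterrows():
            assert row["mean"] == pytest.approx(
                sub.loc[sub.arm == row["arm"], "cesd"].mean(), abs=1e-9)

    def test_output_ordered_control_group_combined(self, scored_trial):
        res = et.adjusted_means(scored_trial, et.OutcomeSpec("cesd", "continuous"),
                                B=50, seed=0)
        assert list(res["arm"]) == ["control", "group", "combined"]
        assert ((res["ci_low"] <= res["mean"]) & (res["mean"] <= res["ci_high"])).all()


class TestRunOrchestration:
    def test_estimate_effects_manifest_reproduces(self, scored_trial):
        specs = [et.OutcomeSpec("cesd", "continuous",
                                candidate_covariates=("cesd_baseline",)),
                 et.OutcomeSpec("lead_knowledge", "binary")]
        eff1, man1 = et.estimate_effects(scored_trial, specs, B=60, seed=5)
        eff2, man2 = et.estimate_effects(scored_trial, specs, B=60, seed=5)
        assert man1 == man2
        assert [e.estimate for e in eff1] == [e.estimate for e in eff2]
        assert [e.ci_low for e in eff1] == [e.ci_low for e in eff2]
        # two comparisons per outcome, no multiplicity adjustment
        assert len(eff1) == 4
        for e in eff1:
            assert e.comparison[1] == "control"
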