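"""Batch merging, lasso Cox signature, risk scoring and survival evaluation."""

import numpy as np
import pandas as pd
import pytest

from subpathnet._cox import cox_newton
from subpathnet.errors import (
    AlignmentError,
    CollinearityError,
    InvalidArgumentError,
    NoEventsError,
)
from subpathnet.prognosis import (
    SurvivalCohort,
    _standardize,
    batch_merge,
    km_logrank,
    lambda_max,
    lasso_cox_path,
    lasso_kkt_violation,
    lasso_survival_fit,
    multivariate_cox,
    risk_score_and_split,
)
from subpathnet.synthetic_data import (
    SyntheticTruth,
    generate_activity_matrix,
    generate_study,
    generate_survival,
)


@pytest.fixture(scope="module")
def planted_fit():
    ids = [f"P{i:02d}" for i in range(50)]
    activity = generate_activity_matrix(ids, 300, seed=1)
    coef = {ids[i]: (1.0 if i % 2 == 0 else -1.0) for i in range(5)}
    cohort = generate_survival(activity, coef, baseline_hazard=0.1, censor_rate=0.3, seed=2)
    model = lasso_survival_fit(activity, cohort, cv_folds=5, seed=3)
    return ids, activity, coef, cohort, model


class TestBatchMerge:
    def _studies(self, shift=2.0, seed=1, n_genes=50):
        genes = [f"G{i:05d}" for i in range(n_genes)]
        truth = SyntheticTruth()
        s1 = generate_study("B1", {"MicT": 10, "MacT": 10}, truth, 0.0, seed=seed, genes=genes)
        s2 = generate_study("B2", {"MicT": 10, "MacT": 10}, truth, 0.0, seed=seed + 100, genes=genes)
        s2.values = (s2.values * 2**shift).astype(int)  # pure location batch effect
        return s1, s2

    def test_single_batch_returned_unadjusted(self):
        s1, _ = self._studies()
        merged = batch_merge([s1])
        assert np.allclose(merged, s1.log_values().loc[merged.index])

    def test_planted_batch_shift_removed(self):
        s1, s2 = self._studies(shift=2.0)
        pre = np.abs(
            s1.log_values().mean(axis=1) - s2.log_values().mean(axis=1)
        ).max()
        merged = batch_merge([s1, s2])
        b1 = merged[s1.samples].mean(axis=1)
        b2 = merged[s2.samples].mean(axis=1)
        post = np.abs(b1 - b2).max()
        assert pre > 1.5  # the planted shift is really there
        assert post < 0.15
        assert post < 0.1 * pre

    def test_sample_order_within_batch_does_not_matter(self):
        s1, s2 = self._studies()
        merged = batch_merge([s1, s2])
        s1p = type(s1)(
            dataset_id=s1.dataset_id,
            values=s1.values[list(reversed(s1.samples))],
            scale_tag=s1.scale_tag,
            sample_annotations=s1.sample_annotations,
        )
        merged_p = batch_merge([s1p, s2])
        assert np.allclose(merged_p[merged.columns], merged)

    def test_no_shared_genes_raises(self):
        s1, s2 = self._studies()
        s2.values.index = [f"OTHER{i}" for i in range(len(s2.values))]
        with pytest.raises(InvalidArgumentError):
            batch_merge([s1, s2])


class TestLassoCox:
    def test_lambda_above_lambda_max_gives_empty_model(self, planted_fit):
        ids, activity, coef, cohort, _ = planted_fit
        X, _, _ = _standardize(activity.to_numpy().T)
        t, e = cohort.time.to_numpy(), cohort.event.to_numpy(float)
        lmax = lambda_max(X, t, e)
        betas = lasso_cox_path(X, t, e, [lmax * 1.001])
        assert np.all(betas[0] == 0.0)

    def test_lambda_to_zero_matches_newton_oracle(self, planted_fit):
        ids, activity, coef, cohort, _ = planted_fit
        X, _, _ = _standardize(activity.iloc[:5].to_numpy().T)
        t, e = cohort.time.to_numpy(), cohort.event.to_numpy(float)
        grid = np.geomspace(lambda_max(X, t, e), 1e-8, 60)
        betas = lasso_cox_path(X, t, e, grid)
        oracle = cox_newton(X, t, e)
        assert np.max(np.abs(betas[-1] - oracle.beta)) < 1e-3

    def test_kkt_conditions_hold_along_the_path(self, planted_fit):
        ids, activity, coef, cohort, _ = planted_fit
        X, _, _ = _standardize(activity.to_numpy().T)
        t, e = cohort.time.to_numpy(), cohort.event.to_numpy(float)
        lmax = lambda_max(X, t, e)
        grid = np.geomspace(lmax, lmax * 1e-4, 40)
        betas = lasso_cox_path(X, t, e, grid)
        for i in (5, 15, 25, 39):
            assert lasso_kkt_violation(betas[i], X, t, e, grid[i]) < 1e-6

    def test_objective_non_increasing_across_outer_sweeps(self, planted_fit):
        from subpathnet.prognosis import _coordinate_descent_fit

        ids, activity, coef, cohort, _ = planted_fit
        X, _, _ = _standardize(activity.to_numpy().T)
        t, e = cohort.time.to_numpy(), cohort.event.to_numpy(float)
        lam = lambda_max(X, t, e) * 0.05
        trace = []
        _coordinate_descent_fit(X, t, e, lam, np.zeros(X.shape[1]),
                                objective_trace=trace)
        assert len(trace) >= 2
        assert all(b <= a + 1e-12 for a, b in zip(trace, trace[1:]))

    def test_true_support_recovered(self, planted_fit):
        ids, activity, coef, cohort, model = planted_fit
        assert len(set(model.coefficients) & set(coef)) >= 4
        for sid in set(model.coefficients) & set(coef):
            assert np.sign(model.coefficients[sid]) == np.sign(coef[sid])

    def test_cv_curve_reproducible_given_seed(self, planted_fit):
        ids, activity, coef, cohort, model = planted_fit
        again = lasso_survival_fit(activity, cohort, cv_folds=5, seed=3)
        assert np.allclose(model.cv_deviance, again.cv_deviance)
        assert model.selected_lambda == again.selected_lambda

    def test_no_events_raises(self):
        ids = ["a", "b", "c"]
        activity = generate_activity_matrix(ids, 20, seed=0)
        data = pd.DataFrame({"time": np.arange(1, 21), "event": 0}, index=activity.columns)
        with pytest.raises(NoEventsError):
            lasso_survival_fit(activity, SurvivalCohort(data), cv_folds=2, seed=0)


class TestRiskScore:
    def test_linearity_under_doubling(self, planted_fit):
        ids, activity, coef, cohort, model = planted_fit
        r1 = risk_score_and_split(model, activity)
        r2 = risk_score_and_split(model, activity * 2)
        assert np.allclose(r2.scores, 2 * r1.scores)

    def test_training_split_balanced(self, planted_fit):
        ids, activity, coef, cohort, model = planted_fit
        risk = risk_score_and_split(model, activity)
        sizes = risk.groups.value_counts()
        assert abs(sizes.get("high", 0) - sizes.get("low", 0)) <= 1

    def test_empty_model_is_degenerate(self, planted_fit):
        ids, activity, coef, cohort, model = planted_fit
        from subpathnet.prognosis import LassoModel

        empty = LassoModel(coefficients={}, lambda_grid=model.lambda_grid,
                           selected_lambda=model.selected_lambda,
                           cv_deviance=model.cv_deviance)
        risk = risk_score_and_split(empty, activity)
        assert risk.degenerate
        assert np.all(risk.scores == 0.0)

    def test_missing_signature_rows_raise(self, planted_fit):
        ids, activity, coef, cohort, model = planted_fit
        with pytest.raises(AlignmentError):
            risk_score_and_split(model, activity.iloc[10:12])


class TestKMLogrank:
    def test_identical_groups_give_zero_statistic(self):
        rng = np.random.default_rng(0)
        time = np.concatenate([rng.exponential(1, 20)] * 2)
        event = np.concatenate([(rng.random(20) < 0.8).astype(int)] * 2)
        cohort = SurvivalCohort(pd.DataFrame(
            {"time": time, "event": event}, index=[f"s{i}" for i in range(40)]))
        groups = pd.Series(["a"] * 20 + ["b"] * 20, index=cohort.samples)
        res = km_logrank(cohort, groups)
        assert res.statistic == pytest.approx(0.0, abs=1e-10)
        assert res.p_value == pytest.approx(1.0)

    def test_km_curve_starts_at_one_and_never_increases(self):
        rng = np.random.default_rng(1)
        cohort = SurvivalCohort(pd.DataFrame(
            {"time": rng.exponential(1, 30), "event": (rng.random(30) < 0.7).astype(int)},
            index=[f"s{i}" for i in range(30)]))
        groups = pd.Series(["a"] * 15 + ["b"] * 15, index=cohort.samples)
        res = km_logrank(cohort, groups)
        for curve in res.curves.values():
            surv = curve["survival"].to_numpy()
            assert surv[0] == pytest.approx(1.0)
            assert np.all(np.diff(surv) <= 1e-12)

    def test_km_without_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(2)
        time = rng.exponential(1, 40)
        cohort = SurvivalCohort(pd.DataFrame(
            {"time": time, "event": 1}, index=[f"s{i}" for i in range(40)]))
        groups = pd.Series(["a"] * 20 + ["b"] * 20, index=cohort.samples)
        res = km_logrank(cohort, groups)
        curve = res.curves["a"]
        t_a = np.sort(time[:20])
        for _, row in curve.iterrows():
            if row["time"] == 0:
                continue
            empirical = np.mean(t_a > row["time"])
            assert row["survival"] == pytest.approx(empirical, abs=1e-10)

    def test_single_group_raises(self):
        cohort = SurvivalCohort(pd.DataFrame(
            {"time": [1.0, 2.0], "event": [1, 1]}, index=["a", "b"]))
        with pytest.raises(InvalidArgumentError):
            km_logrank(cohort, pd.Series(["g", "g"], index=["a", "b"]))


class TestMultivariateCox:
    def _cohort_with_score_and_age(self, seed=0, n=250):
        rng = np.random.default_rng(seed)
        score = rng.normal(size=n)
        age = rng.normal(size=n)  # independent of score
        rate = 0.1 * np.exp(0.8 * score + 0.5 * age)
        time = rng.exponential(1 / rate)
        idx = [f"s{i}" for i in range(n)]
        cohort = SurvivalCohort(pd.DataFrame({"time": time, "event": 1}, index=idx))
        cov = pd.DataFrame({"score": score, "age": age}, index=idx)
        return cohort, cov

    def test_independent_effects_both_retained(self):
        cohort, cov = self._cohort_with_score_and_age()
        res = multivariate_cox(cohort, cov)
        assert res["score"].p_value < 0.01 and res["score"].hr > 1
        assert res["age"].p_value < 0.01 and res["age"].hr > 1

    def test_duplicated_column_raises_collinearity(self):
        cohort, cov = self._cohort_with_score_and_age()
        cov["score_copy"] = cov["score"]
        with pytest.raises(CollinearityError) as err:
            multivariate_cox(cohort, cov)
        assert "score_copy" in err.value.columns

    def test_single_covariate_matches_univariate(self):
        from subpathnet.diffexpr import univariate_cox

        cohort, cov = self._cohort_with_score_and_age(seed=5, n=120)
        joint = multivariate_cox(cohort, cov[["score"]])
        single = univariate_cox(cohort, cov["score"], name="score")
        assert joint["score"].log_hr == pytest.approx(single.log_hr, abs=1e-6)
        assert joint["score"].p_value == pytest.approx(single.p_value, abs=1e-8)

    def test_matches_lifelines_on_tie_free_fixture(self):
        """Independent cross-check: same fit from lifelines (ties are absent,
        so Breslow and Efron coincide)."""
        from lifelines import CoxPHFitter

        cohort, cov = self._cohort_with_score_and_age(seed=9, n=150)
        mine = multivariate_cox(cohort, cov)
        df = cov.copy()
        df["time"] = cohort.time
        df["event"] = cohort.event
        cph = CoxPHFitter().fit(df, duration_col="time", event_col="event")
        for name in ("score", "age"):
            assert mine[name].log_hr == pytest.approx(cph.params_[name], abs=1e-4)
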