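"""Differential expression, BH adjustment, consensus signatures and Cox screens."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from subpathnet._cox import breslow_loglik, cox_newton
from subpathnet.diffexpr import (
    DEResult,
    benjamini_hochberg,
    consensus_signatures,
    differential_expression,
    risk_gene_screen,
    risk_gene_sets,
    univariate_cox,
)
from subpathnet.errors import (
    AlignmentError,
    InsufficientReplicatesError,
    InvalidArgumentError,
    NoEventsError,
)
from subpathnet.prognosis import SurvivalCohort
from subpathnet.synthetic_data import (
    GeneExpressionStudy,
    SyntheticTruth,
    generate_study,
    generate_survival,
)


def make_cohort(time, event):
    idx = [f"s{i}" for i in range(len(time))]
    return SurvivalCohort(pd.DataFrame({"time": time, "event": event}, index=idx))


class TestBenjaminiHochberg:
    def test_step_up_worked_example(self):
        assert benjamini_hochberg([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_equal_inputs_unchanged(self):
        assert benjamini_hochberg([0.2] * 5) == pytest.approx([0.2] * 5)

    def test_single_value_unchanged(self):
        assert benjamini_hochberg([0.7]) == pytest.approx([0.7])

    def test_adjusted_never_below_raw_and_capped_at_one(self):
        rng = np.random.default_rng(0)
        p = rng.random(200)
        adj = benjamini_hochberg(p)
        assert np.all(adj >= p - 1e-12)
        assert np.all(adj <= 1.0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40), st.randoms(use_true_random=False))
    def test_order_equivariant_under_permutation(self, p, rnd):
        perm = list(range(len(p)))
        rnd.shuffle(perm)
        adj = benjamini_hochberg(p)
        adj_perm = benjamini_hochberg([p[i] for i in perm])
        assert np.allclose([adj[i] for i in perm], adj_perm)

    def test_out_of_range_rejected(self):
        with pytest.raises(InvalidArgumentError):
            benjamini_hochberg([0.1, 1.5])


def _manual_study(a_block, b_block, genes=None):
    """Two-group log-scale study from explicit per-group value blocks."""
    a_block, b_block = np.atleast_2d(a_block), np.atleast_2d(b_block)
    genes = genes or [f"g{i}" for i in range(a_block.shape[0])]
    cols = [f"A{i}" for i in range(a_block.shape[1])] + [
        f"B{i}" for i in range(b_block.shape[1])
    ]
    values = pd.DataFrame(np.hstack([a_block, b_block]), index=genes, columns=cols)
    ann = pd.DataFrame(
        {"cell": "bulk", "condition": "x", "batch": "d1",
         "group": ["A"] * a_block.shape[1] + ["B"] * b_block.shape[1]},
        index=pd.Index(cols, name="sample"),
    )
    return GeneExpressionStudy("d1", values, "log", ann)


class TestDifferentialExpression:
    def test_null_study_flags_nothing(self):
        rng = np.random.default_rng(1)
        base = rng.normal(5, 0.01, size=(50, 1))
        study = _manual_study(base + rng.normal(0, 1e-3, (50, 4)),
                              base + rng.normal(0, 1e-3, (50, 4)))
        results = differential_expression(study, ("A", "B"), lfc_cutoff=1.5, alpha=0.05)
        assert all(r.direction == "none" for r in results)

    def test_fold_change_cutoff_is_conjunctive_with_significance(self):
        """A gene at log2FC 1.4 with vanishing p stays unflagged at cutoff 1.5."""
        rng = np.random.default_rng(2)
        a = 5.0 + 1.4 + rng.normal(0, 1e-4, (1, 10))
        b = 5.0 + rng.normal(0, 1e-4, (1, 10))
        study = _manual_study(a, b)
        (res,) = differential_expression(study, ("A", "B"), lfc_cutoff=1.5, alpha=0.05)
        assert res.adjusted_p < 1e-9
        assert res.direction == "none"
        (res,) = differential_expression(study, ("A", "B"), lfc_cutoff=1.3, alpha=0.05)
        assert res.direction == "up"

    def test_planted_signature_recovered_with_correct_direction(self):
        genes = [f"G{i:05d}" for i in range(300)]
        plan = {g: ("up" if i % 2 == 0 else "down") for i, g in enumerate(genes[:40])}
        truth = SyntheticTruth(planted_de_genes={"MicT/MacT": plan})
        rates = []
        for seed in range(10):
            study = generate_study("d", {"MicT": 10, "MacT": 10}, truth, 2.0,
                                   dispersion=0.1, seed=seed, genes=genes)
            results = {r.gene: r for r in differential_expression(
                study, ("MicT", "MacT"), lfc_cutoff=1.5, alpha=0.05)}
            ok = sum(1 for g, d in plan.items() if results[g].direction == d)
            rates.append(ok / len(plan))
        assert np.median(rates) >= 0.9

    def test_too_few_replicates_raises(self):
        study = _manual_study(np.ones((5, 1)), np.ones((5, 4)))
        with pytest.raises(InsufficientReplicatesError):
            differential_expression(study, ("A", "B"))


class TestConsensus:
    def _de(self, flags):
        return [
            DEResult(gene=g, log2fc=2.0 if d == "up" else -2.0, p_value=1e-4,
                     adjusted_p=1e-3, direction=d)
            for g, d in flags.items()
        ]

    def test_gene_shared_by_all_datasets_included_with_support(self):
        results = {f"d{i}": self._de({"gx": "up"}) for i in range(4)}
        cons = consensus_signatures(results, min_support=4, group="MicT/MacT")
        (sig,) = cons.signatures
        assert sig.gene == "gx" and sig.support == 4 and sig.direction == "up"

    def test_conflicting_directions_excluded_and_reported(self):
        results = {
            "d1": self._de({"gx": "up"}),
            "d2": self._de({"gx": "up"}),
            "d3": self._de({"gx": "down"}),
        }
        cons = consensus_signatures(results, min_support=2, group="g")
        assert cons.signatures == []
        assert cons.conflicting == {"gx": {"up": 2, "down": 1}}

    def test_min_support_one_gives_union(self):
        results = {"d1": self._de({"a": "up"}), "d2": self._de({"b": "down"})}
        cons = consensus_signatures(results, min_support=1, group="g")
        assert cons.genes() == {"a", "b"}

    def test_support_counts_match_brute_force_recount(self):
        rng = np.random.default_rng(6)
        genes = [f"g{i}" for i in range(30)]
        per_dataset = {
            f"d{k}": {g: "up" for g in rng.choice(genes, size=10, replace=False)}
            for k in range(4)
        }
        results = {k: self._de(v) for k, v in per_dataset.items()}
        cons = consensus_signatures(results, min_support=2, group="g")
        for sig in cons.signatures:
            recount = sum(1 for v in per_dataset.values() if v.get(sig.gene) == "up")
            assert sig.support == recount
            assert recount >= 2

    def test_empty_or_undersized_input_raises(self):
        with pytest.raises(InvalidArgumentError):
            consensus_signatures({}, 1, "g")
        with pytest.raises(InvalidArgumentError):
            consensus_signatures({"d1": []}, 2, "g")


class TestUnivariateCox:
    def test_maximizer_matches_grid_search_on_small_fixture(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=10)
        time = rng.exponential(1 / np.exp(0.8 * x))
        cohort = make_cohort(time, np.ones(10, dtype=int))
        res = univariate_cox(cohort, x)
        grid = np.arange(-5, 5, 1e-4)
        ll = [breslow_loglik(b * x, time, np.ones(10)) for b in grid]
        assert res.log_hr == pytest.approx(grid[int(np.argmax(ll))], abs=1e-3)

    def test_sign_equivariance(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=60)
        time = rng.exponential(1 / np.exp(0.5 * x))
        event = (rng.random(60) < 0.8).astype(int)
        event[0] = 1
        a = univariate_cox(make_cohort(time, event), x)
        b = univariate_cox(make_cohort(time, event), -x)
        assert a.log_hr == pytest.approx(-b.log_hr, abs=1e-8)
        assert a.p_value == pytest.approx(b.p_value, abs=1e-10)

    def test_partial_likelihood_never_below_null(self):
        rng = np.random.default_rng(5)
        for seed in range(5):
            r = np.random.default_rng(seed)
            x = r.normal(size=40)
            time = r.exponential(1.0, size=40)
            event = (r.random(40) < 0.7).astype(int)
            event[0] = 1
            fit = cox_newton(x[:, None], time, event.astype(float))
            assert fit.loglik >= fit.loglik_null - 1e-10

    def test_type_one_error_calibrated(self):
        """Null covariates at n=200: rejection rate at 0.05 stays near nominal."""
        rng = np.random.default_rng(7)
        n_reject, reps = 0, 400
        for _ in range(reps):
            x = rng.normal(size=200)
            time = rng.exponential(1.0, size=200)
            event = (rng.random(200) < 0.8).astype(int)
            res = univariate_cox(make_cohort(time, event), x, p_threshold=0.05)
            n_reject += res.p_value < 0.05
        assert 0.025 <= n_reject / reps <= 0.075

    def test_zero_events_and_constant_covariate_rejected(self):
        with pytest.raises(NoEventsError):
            univariate_cox(make_cohort([1, 2, 3], [0, 0, 0]), [1.0, 2.0, 3.0])
        with pytest.raises(InvalidArgumentError):
            univariate_cox(make_cohort([1, 2, 3], [1, 1, 0]), [2.0, 2.0, 2.0])

    def test_hazard_ratio_consistent_with_log_hr(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=80)
        time = rng.exponential(1 / np.exp(x))
        res = univariate_cox(make_cohort(time, np.ones(80, dtype=int)), x)
        assert res.hr == pytest.approx(np.exp(res.log_hr))
        assert res.classification == "risk"


class TestRiskGeneScreen:
    def _screen_fixture(self, seed=0, n=300):
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(30)]
        log_expr = pd.DataFrame(rng.normal(5, 1, size=(30, n)), index=genes,
                                columns=[f"s{i}" for i in range(n)])
        log_expr.iloc[5] = 5.0  # constant gene
        activity = log_expr.rename(index={g: g for g in genes})
        cohort = generate_survival(activity, {"g0": 1.0}, baseline_hazard=0.05,
                                   censor_rate=0.2, seed=seed + 1)
        ann = pd.DataFrame({"cell": "bulk", "condition": "tumor", "batch": "d",
                            "group": "tumor"}, index=log_expr.columns)
        study = GeneExpressionStudy("d", log_expr, "log", ann)
        return study, cohort

    def test_hazard_driving_gene_classified_risk_null_rate_low(self, caplog):
        study, cohort = self._screen_fixture()
        screen = risk_gene_screen(study, cohort, p_threshold=0.01)
        assert screen["g0"].classification == "risk"
        assert "g5" not in screen  # constant gene skipped
        assert any("constant" in r.message for r in caplog.records)
        null_flagged = sum(
            1 for g, r in screen.items() if g != "g0" and r.classification != "none"
        )
        assert null_flagged / (len(screen) - 1) < 0.05
        sets = risk_gene_sets(screen)
        assert "g0" in sets["risk"]

    def test_sample_mismatch_raises(self):
        study, cohort = self._screen_fixture()
        bad = SurvivalCohort(cohort.data.rename(index={"s0": "other"}))
        with pytest.raises(AlignmentError):
            risk_gene_screen(study, bad)
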