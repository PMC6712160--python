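"""Survival and stage screens: median split, log-rank, Cox score test, ANOVA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from triplexnet import (ClinicalTable, annotate_triplets, cox_score_test,
                        median_split, multivariate_cox_p, stage_anova,
                        univariate_logrank)
from triplexnet.assoc_stats import km_curves
from triplexnet.clique_mine import Triplet

from conftest import make_expr


def clinical_from(times, events, stages=None, ids=None):
    ids = ids or [f"S{i}" for i in range(len(times))]
    return ClinicalTable(pd.DataFrame(
        {"os_months": times, "event": events,
         "stage": stages if stages is not None else [np.nan] * len(times)},
        index=pd.Index(ids, name="sample_id")))


def logrank_oracle(time, event, group):
    """Independent log-rank implementation via the hypergeometric expectation
    at each distinct event time."""
    time, event, group = map(np.asarray, (time, event, group))
    o_minus_e, var = 0.0, 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n, n1 = at_risk.sum(), (at_risk & (group == 1)).sum()
        d = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & (group == 1)).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    chi2 = o_minus_e**2 / var
    return chi2, sps.chi2.sf(chi2, 1)


class TestMedianSplit:
    def test_even_split(self):
        assert median_split([1, 2, 3, 4]).tolist() == ["LOW", "LOW", "HIGH", "HIGH"]

    def test_ties_at_median_go_high(self):
        assert median_split([1, 2, 2, 3]).tolist() == ["LOW", "HIGH", "HIGH", "HIGH"]

    def test_constant_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            median_split([5, 5, 5, 5])

    def test_invariant_under_monotone_transform(self, rng):
        x = rng.normal(size=41)
        assert (median_split(x) == median_split(np.exp(x))).all()

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=4, max_size=60))
    def test_groups_partition_and_ties_go_high(self, values):
        x = np.asarray(values)
        if np.ptp(x) == 0:
            return
        try:
            labels = median_split(x)
        except ValueError:
            return  # heavy median ties emptied the LOW group
        med = np.median(x)
        assert ((labels == "HIGH") == (x >= med)).all()
        assert {"LOW", "HIGH"} == set(labels)


class TestUnivariateLogrank:
    def test_identical_groups_give_p_one(self):
        expr = pd.Series([1, 1, 2, 2], index=[f"S{i}" for i in range(4)])
        clin = clinical_from([5, 7, 5, 7], [1, 1, 1, 1])
        assert univariate_logrank(expr, clin) == pytest.approx(1.0)

    def test_matches_hand_computed_logrank(self):
        """Early-death group vs late-death group, all events observed."""
        expr = pd.Series([1, 1, 1, 9, 9, 9], index=[f"S{i}" for i in range(6)])
        times, events = [1, 2, 3, 10, 20, 30], [1, 1, 1, 1, 1, 1]
        clin = clinical_from(times, events)
        p = univariate_logrank(expr, clin)
        _, p_oracle = logrank_oracle(times, events, [0, 0, 0, 1, 1, 1])
        assert p == pytest.approx(p_oracle, rel=1e-6)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_oracle_on_random_data(self, seed):
        rng = np.random.default_rng(seed)
        n = 30
        expr = pd.Series(rng.normal(size=n), index=[f"S{i}" for i in range(n)])
        times = rng.exponential(10, size=n)  # continuous: no ties
        events = rng.integers(0, 2, size=n)
        events[0] = 1
        clin = clinical_from(times, events)
        p = univariate_logrank(expr, clin)
        group = (expr.to_numpy() >= np.median(expr)).astype(int)
        _, p_oracle = logrank_oracle(times, events, group)
        assert p == pytest.approx(p_oracle, rel=1e-6)

    def test_no_events_returns_missing(self, caplog):
        expr = pd.Series([1, 2, 3, 4], index=[f"S{i}" for i in range(4)])
        clin = clinical_from([5, 6, 7, 8], [0, 0, 0, 0])
        with caplog.at_level("WARNING"):
            assert np.isnan(univariate_logrank(expr, clin))

    def test_km_curves_cover_both_groups(self):
        rng = np.random.default_rng(1)
        n = 40
        expr = pd.Series(rng.normal(size=n), index=[f"S{i}" for i in range(n)])
        clin = clinical_from(rng.exponential(12, n), rng.integers(0, 2, n))
        low, high = km_curves(expr, clin)
        assert low.event_observed.shape[0] + high.event_observed.shape[0] == n


class TestCoxScoreTest:
    @pytest.mark.parametrize("seed", range(50))
    def test_binary_covariate_reproduces_logrank(self, seed):
        """Cox score test with a 0/1 covariate equals the log-rank statistic
        on tie-free data (classical equivalence, cross-checked vs lifelines)."""
        from lifelines.statistics import logrank_test

        rng = np.random.default_rng(seed)
        n = rng.integers(12, 40)
        time = rng.exponential(10, size=n)
        event = rng.integers(0, 2, size=n)
        event[:2] = 1
        group = rng.integers(0, 2, size=n)
        group[:2] = [0, 1]
        res = cox_score_test(group.astype(float).reshape(-1, 1), time, event)
        lr = logrank_test(time[group == 0], time[group == 1],
                          event_observed_A=event[group == 0],
                          event_observed_B=event[group == 1])
        assert res.chi2 == pytest.approx(lr.test_statistic, abs=1e-6)
        assert res.p_value == pytest.approx(lr.p_value, abs=1e-6)

    def test_invariant_to_covariate_scaling(self, rng):
        n = 80
        X = rng.normal(size=(n, 3))
        time = rng.exponential(10, size=n)
        event = rng.integers(0, 2, size=n)
        event[:5] = 1
        a = cox_score_test(X, time, event)
        b = cox_score_test(X * np.array([3.0, 0.5, 100.0]), time, event)
        assert a.chi2 == pytest.approx(b.chi2, rel=1e-9)

    def test_prognostic_covariate_detected(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 400
            X = rng.normal(size=(n, 3))
            t_true = rng.exponential(1.0, size=n) / np.exp(X[:, 0])
            censored = rng.random(n) < 0.3
            time = np.where(censored, rng.uniform(0, 1, n) * t_true, t_true)
            event = (~censored).astype(int)
            res = cox_score_test(X, time, event)
            hits += res.p_value < 0.05
        assert hits >= 18  # >= 90% power

    def test_collinear_covariates_ridge_stabilized(self, caplog):
        rng = np.random.default_rng(0)
        n = 50
        x = rng.normal(size=n)
        X = np.column_stack([x, x])
        with caplog.at_level("WARNING"):
            res = cox_score_test(X, rng.exponential(5, n), np.ones(n, dtype=int))
        assert res.ridge_stabilized
        assert np.isfinite(res.p_value)


class TestMultivariateCox:
    def test_too_few_events_missing(self, caplog):
        idx = [f"S{i}" for i in range(12)]
        exprs = [pd.Series(np.arange(12.0), index=idx) for _ in range(3)]
        clin = clinical_from(np.arange(1.0, 13.0), [1] + [0] * 11, ids=idx)
        with caplog.at_level("WARNING"):
            assert np.isnan(multivariate_cox_p(exprs, clin))

    def test_median_coding_option(self, rng):
        n = 60
        idx = [f"S{i}" for i in range(n)]
        exprs = [pd.Series(rng.normal(size=n), index=idx) for _ in range(3)]
        clin = clinical_from(rng.exponential(10, n), rng.integers(0, 2, n), ids=idx)
        p_cont = multivariate_cox_p(exprs, clin, coding="continuous")
        p_med = multivariate_cox_p(exprs, clin, coding="median")
        assert np.isfinite(p_cont) and np.isfinite(p_med)
        with pytest.raises(ValueError):
            multivariate_cox_p(exprs, clin, coding="bogus")


class TestStageAnova:
    def _stages(self, labels):
        return pd.Series(labels, index=[f"S{i}" for i in range(len(labels))])

    def test_identical_group_means_give_p_one(self):
        expr = pd.Series([1, 2, 3] * 3, index=[f"S{i}" for i in range(9)])
        stages = self._stages(["II"] * 3 + ["III"] * 3 + ["IV"] * 3)
        assert stage_anova(expr, stages) == pytest.approx(1.0)

    def test_separated_means_give_tiny_p(self, rng):
        vals = np.concatenate([np.zeros(4), np.ones(4), 2 * np.ones(4)])
        vals += rng.normal(0, 1e-6, 12)
        expr = pd.Series(vals, index=[f"S{i}" for i in range(12)])
        stages = self._stages(["II"] * 4 + ["III"] * 4 + ["IV"] * 4)
        assert stage_anova(expr, stages) < 1e-10

    def test_matches_hand_computed_sums_of_squares(self):
        """Groups (1,2),(2,3),(3,4): SSB=4 (df 2), SSW=1.5 (df 3) -> F=4."""
        expr = pd.Series([1, 2, 2, 3, 3, 4], index=[f"S{i}" for i in range(6)])
        stages = self._stages(["II", "II", "III", "III", "IV", "IV"])
        assert stage_anova(expr, stages) == pytest.approx(sps.f.sf(4.0, 2, 3))

    def test_affine_invariance(self, rng):
        expr = pd.Series(rng.normal(size=30), index=[f"S{i}" for i in range(30)])
        stages = self._stages((["II"] * 10 + ["III"] * 10 + ["IV"] * 10))
        assert stage_anova(expr, stages) == pytest.approx(
            stage_anova(-2.5 * expr + 7, stages), rel=1e-9)

    def test_missing_stages_excluded_and_single_group_missing(self, caplog):
        expr = pd.Series([1, 2, 3, 4, 5, 6], index=[f"S{i}" for i in range(6)])
        stages = self._stages(["III", "III", "III", np.nan, np.nan, np.nan])
        with caplog.at_level("WARNING"):
            assert np.isnan(stage_anova(expr, stages))


class TestAnnotateTriplets:
    def test_flags_follow_pvalues(self, rng):
        """A stage- and survival-linked triplet is flagged; a null one is not."""
        n = 120
        idx = [f"S{i}" for i in range(n)]
        stage_labels = np.array(["II"] * 20 + ["III"] * 70 + ["IV"] * 30)
        ordinal = np.array([0] * 20 + [1] * 70 + [2] * 30)

        def linked():
            return 2.0 * ordinal + rng.normal(0, 0.3, n)

        def null():
            return rng.normal(0, 0.3, n)

        rows = {"m1": linked(), "l1": linked(), "r1": linked(),
                "m2": null(), "l2": null(), "r2": null()}
        expr = make_expr({k: v.tolist() for k, v in rows.items()},
                         biotypes={"m1": "mRNA", "l1": "lncRNA", "r1": "miRNA",
                                   "m2": "mRNA", "l2": "lncRNA", "r2": "miRNA"},
                         samples=idx)
        risk = rows["m1"] - rows["m1"].mean()
        t_true = rng.exponential(1.0, n) / np.exp(risk)
        clin = clinical_from(t_true, np.ones(n, dtype=int), stages=stage_labels, ids=idx)

        flags = annotate_triplets([Triplet("m1", "l1", "r1"), Triplet("m2", "l2", "r2")],
                                  expr, clin)
        linked_row = flags.iloc[0]
        null_row = flags.iloc[1]
        assert linked_row["multivariate_flag"] == 1
        assert linked_row["stage_flag"] == 1
        assert linked_row["both_significant"] == 1
        assert null_row["stage_flag"] == 0
        assert null_row["both_significant"] == 0

    def test_stage_rule_any_vs_all(self, rng):
        n = 100
        idx = [f"S{i}" for i in range(n)]
        ordinal = np.array([0] * 15 + [1] * 60 + [2] * 25)
        stage_labels = np.array(["II"] * 15 + ["III"] * 60 + ["IV"] * 25)
        rows = {"m": (2.0 * ordinal + rng.normal(0, 0.2, n)),
                "l": rng.normal(size=n), "r": rng.normal(size=n)}
        expr = make_expr({k: v.tolist() for k, v in rows.items()},
                         biotypes={"m": "mRNA", "l": "lncRNA", "r": "miRNA"},
                         samples=idx)
        clin = clinical_from(rng.exponential(10, n), rng.integers(0, 2, n),
                             stages=stage_labels, ids=idx)
        t = [Triplet("m", "l", "r")]
        assert annotate_triplets(t, expr, clin, stage_rule="all").iloc[0]["stage_flag"] == 0
        assert annotate_triplets(t, expr, clin, stage_rule="any").iloc[0]["stage_flag"] == 1

    def test_missing_member_rejected(self, rng):
        expr = make_expr({"m": rng.normal(size=20).tolist()})
        clin = clinical_from(rng.exponential(10, 20), np.ones(20, dtype=int))
        with pytest.raises(ValueError, match="absent"):
            annotate_triplets([Triplet("m", "ghost", "r")], expr, clin)

    def test_planted_cohort_flags_enrich_survival_triplets(self):
        """Triplets wired to the hazard are preferentially flagged (Fisher)."""
        import triplexnet as tx

        expr, clinical, truth = tx.generate_cohort(tx.SimConfig(seed=0))
        logged = tx.preprocess(expr)
        triplets = [Triplet(*key) for key in sorted(truth.planted_triplets)]
        flags = annotate_triplets(triplets, logged, clinical)
        tied = np.array([t.mrna_id in truth.survival_rnas for t in triplets])
        flagged = flags["multivariate_flag"].to_numpy().astype(bool)
        table = [[int((tied & flagged).sum()), int((tied & ~flagged).sum())],
                 [int((~tied & flagged).sum()), int((~tied & ~flagged).sum())]]
        _, p = sps.fisher_exact(table, alternative="greater")
        assert p < 0.01
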