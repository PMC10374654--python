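import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from met53.cohort_io import MutationTable
from met53.errors import DegenerateVarianceError, ValidationError
from met53.signature_scoring import ActivationCall, ActivationThreshold
from met53.stratification_survival import (
    assign_tp53_status,
    compare_scores,
    crosstab,
    km_estimate,
    logrank_test,
    stratify,
)


def _mut_table(records):
    return MutationTable(
        pd.DataFrame(records, columns=["sample_id", "gene", "variant_class"])
    )


def _calls(mapping):
    return ActivationCall(
        labels=pd.Series(mapping, name="met_class"),
        threshold=ActivationThreshold(0.0, 1.5, 0.0, 0.0, 2),
    )


class TestTP53Status:
    def test_missense_is_mutant_not_null(self):
        st = assign_tp53_status(_mut_table([("S1", "TP53", "missense")]), ["S1"])
        assert st.table.loc["S1", "status"] == "mutant"
        assert not st.table.loc["S1", "is_null"]

    def test_truncating_is_mutant_and_null(self):
        st = assign_tp53_status(_mut_table([("S1", "TP53", "truncating")]), ["S1"])
        assert st.table.loc["S1", "status"] == "mutant"
        assert st.table.loc["S1", "is_null"]

    def test_absent_sample_is_wild_type(self):
        st = assign_tp53_status(_mut_table([("S1", "TP53", "missense")]), ["S1", "S2"])
        assert st.table.loc["S2", "status"] == "wild_type"

    def test_other_gene_does_not_count(self):
        st = assign_tp53_status(_mut_table([("S1", "CTNNB1", "missense")]), ["S1"])
        assert st.table.loc["S1", "status"] == "wild_type"

    def test_custom_null_definition(self):
        st = assign_tp53_status(
            _mut_table([("S1", "TP53", "missense")]), ["S1"],
            null_definition={"missense"},
        )
        assert st.table.loc["S1", "is_null"]


class TestStratify:
    def test_one_sample_per_stratum(self):
        status = assign_tp53_status(
            _mut_table([("A", "TP53", "missense"), ("B", "TP53", "splice")]),
            ["A", "B", "C", "D"],
        )
        calls = _calls({"A": "high", "B": "low", "C": "high", "D": "low"})
        strata = stratify(status, calls)
        assert strata.counts().to_dict() == {
            "mut_high": 1, "mut_low": 1, "wt_high": 1, "wt_low": 1
        }

    def test_disjoint_sets_error(self):
        status = assign_tp53_status(_mut_table([("A", "TP53", "missense")]), ["A"])
        with pytest.raises(ValidationError, match="disjoint"):
            stratify(status, _calls({"X": "high"}))

    def test_partial_overlap_counted_excluded(self):
        status = assign_tp53_status(_mut_table([]), ["A", "B"])
        strata = stratify(status, _calls({"B": "high", "C": "low"}))
        assert list(strata.table.index) == ["B"]
        assert strata.n_excluded == 2  # A lacks a call, C lacks a status


class TestCrossTab:
    def _strata_from_counts(self, mh, ml, wh, wl):
        rows = (
            [("mutant", "high")] * mh + [("mutant", "low")] * ml
            + [("wild_type", "high")] * wh + [("wild_type", "low")] * wl
        )
        df = pd.DataFrame(rows, columns=["tp53_status", "met_class"])
        df["stratum"] = (
            df["tp53_status"].map({"mutant": "mut", "wild_type": "wt"})
            + "_" + df["met_class"]
        )
        df.index = pd.Index([f"S{i}" for i in range(len(df))], name="sample_id")
        from met53.stratification_survival import StratumTable

        return StratumTable(df)

    def test_cohort_proportions(self):
        # 79/111 mutant tumors high, 136/249 wild-type tumors high
        ct = crosstab(self._strata_from_counts(79, 32, 136, 113))
        assert ct.row_proportions.loc["mutant", "high"] == pytest.approx(79 / 111)
        assert ct.row_proportions.loc["wild_type", "high"] == pytest.approx(136 / 249)
        assert ct.total == 360
        assert not ct.haldane_corrected
        assert ct.odds_ratio == pytest.approx((79 * 113) / (32 * 136))

    def test_zero_cell_flags_correction(self):
        ct = crosstab(self._strata_from_counts(5, 0, 3, 2))
        assert ct.haldane_corrected
        assert np.isfinite(ct.odds_ratio)

    def test_margins_reconcile_with_strata(self):
        strata = self._strata_from_counts(3, 4, 5, 6)
        ct = crosstab(strata)
        assert ct.counts.to_numpy().sum() == len(strata.table)
        assert ct.counts.loc["mutant"].sum() == 7


class TestKaplanMeier:
    def test_all_events_product_limit_by_hand(self):
        km = km_estimate([1, 2, 3], [1, 1, 1])
        np.testing.assert_allclose(km.table["survival"], [2 / 3, 1 / 3, 0.0])

    def test_censoring_shrinks_risk_set_only(self):
        km = km_estimate([1, 2, 3], [0, 1, 1])
        assert km.survival_at(2) == pytest.approx(1 / 2)
        assert km.survival_at(3) == pytest.approx(0.0)
        assert km.survival_at(1) == 1.0  # censored-only time: no drop

    def test_all_censored_is_flat_one(self):
        km = km_estimate([1, 2, 3], [0, 0, 0])
        assert km.table.empty
        assert km.survival_at(99) == 1.0

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(2)
        t = rng.exponential(10, size=40)
        km = km_estimate(t, np.ones(40, dtype=int))
        for _, row in km.table.iterrows():
            assert row["survival"] == pytest.approx(np.mean(t > row["time"]))

    def test_empty_input_error(self):
        with pytest.raises(ValidationError):
            km_estimate([], [])


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        t, e = [1, 2, 3, 4], [1, 0, 1, 1]
        res = logrank_test([(t, e), (t, e)])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_tabulated_two_group_instance(self):
        # groups A: times (1,2) both events; B: times (3,4) both events.
        # Per-event-time 2x2 tables give O_A=2, E_A=5/6, V=17/36,
        # chi-square = (7/6)^2 / (17/36) = 49/17.
        res = logrank_test([([1, 2], [1, 1]), ([3, 4], [1, 1])])
        assert res.statistic == pytest.approx(49 / 17, abs=1e-9)
        assert res.p_value == pytest.approx(stats.chi2.sf(49 / 17, 1), abs=1e-12)

    def test_event_conservation(self):
        rng = np.random.default_rng(8)
        groups = [
            (rng.exponential(10, 15), rng.integers(0, 2, 15)) for _ in range(3)
        ]
        if not any(e.sum() for _, e in groups):  # pragma: no cover
            groups[0][1][0] = 1
        res = logrank_test(groups)
        assert res.observed.sum() == pytest.approx(res.expected.sum(), abs=1e-9)

    def test_invariant_under_monotone_time_transform(self):
        rng = np.random.default_rng(9)
        g = [(rng.exponential(10, 12) + 0.1, rng.integers(0, 2, 12)) for _ in range(2)]
        g[0][1][0] = 1
        res_lin = logrank_test(g)
        res_sq = logrank_test([(t**2, e) for t, e in g])
        assert res_sq.statistic == pytest.approx(res_lin.statistic, rel=1e-12)

    def test_matches_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        from lifelines.statistics import multivariate_logrank_test

        rng = np.random.default_rng(4)
        sizes = (20, 15, 25)
        groups = [
            (rng.exponential(s, n), rng.integers(0, 2, n))
            for s, n in zip((10, 15, 30), sizes)
        ]
        mine = logrank_test(groups)
        df = pd.DataFrame(
            {
                "t": np.concatenate([t for t, _ in groups]),
                "e": np.concatenate([e for _, e in groups]),
                "g": np.repeat(np.arange(3), sizes),
            }
        )
        ref = multivariate_logrank_test(df["t"], df["g"], df["e"])
        assert mine.statistic == pytest.approx(ref.test_statistic, rel=1e-9)
        assert mine.p_value == pytest.approx(ref.p_value, rel=1e-9)

    def test_no_events_error(self):
        with pytest.raises(ValidationError):
            logrank_test([([1, 2], [0, 0]), ([3], [0])])


class TestCompareScores:
    def test_identical_vectors_t_zero(self):
        a = [1.0, 2.0, 3.0]
        stat, p = compare_scores(a, a, method="student")
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_large_shift_is_significant(self):
        rng = np.random.default_rng(12)
        a = rng.normal(0, 1, 50)
        b = rng.normal(10, 1, 50)
        for method in ("student", "welch", "mann_whitney"):
            _, p = compare_scores(a, b, method=method)
            assert p < 1e-6

    def test_textbook_formula_oracle(self):
        rng = np.random.default_rng(123)
        x, y = rng.normal(0, 1, 10), rng.normal(0.8, 1.5, 10)
        n = 10
        # Student: pooled variance
        sp2 = ((n - 1) * x.var(ddof=1) + (n - 1) * y.var(ddof=1)) / (2 * n - 2)
        t_s = (x.mean() - y.mean()) / np.sqrt(sp2 * 2 / n)
        p_s = 2 * stats.t.sf(abs(t_s), 2 * n - 2)
        stat, p = compare_scores(x, y, method="student")
        assert (stat, p) == (pytest.approx(t_s, abs=1e-9), pytest.approx(p_s, abs=1e-9))
        # Welch: Satterthwaite df
        vx, vy = x.var(ddof=1) / n, y.var(ddof=1) / n
        t_w = (x.mean() - y.mean()) / np.sqrt(vx + vy)
        df_w = (vx + vy) ** 2 / (vx**2 / (n - 1) + vy**2 / (n - 1))
        p_w = 2 * stats.t.sf(abs(t_w), df_w)
        stat, p = compare_scores(x, y, method="welch")
        assert (stat, p) == (pytest.approx(t_w, abs=1e-9), pytest.approx(p_w, abs=1e-9))
        # Mann-Whitney at 10 vs 10 (no ties): continuity-corrected normal
        # approximation, the standard large-sample formula
        ranks = stats.rankdata(np.concatenate([x, y]))
        u_obs = ranks[:n].sum() - n * (n + 1) / 2
        mu_u = n * n / 2
        sd_u = np.sqrt(n * n * (2 * n + 1) / 12)
        z = (abs(u_obs - mu_u) - 0.5) / sd_u
        p_mw = 2 * stats.norm.sf(z)
        stat, p = compare_scores(x, y, method="mann_whitney")
        assert max(stat, n * n - stat) == pytest.approx(max(u_obs, n * n - u_obs))
        assert p == pytest.approx(p_mw, abs=1e-9)
        # and the exact enumeration over all rank splits agrees closely
        count = total = 0
        for comb in itertools.combinations(range(2 * n), n):
            u = ranks[list(comb)].sum() - n * (n + 1) / 2
            count += abs(u - mu_u) >= abs(u_obs - mu_u) - 1e-12
            total += 1
        assert p == pytest.approx(count / total, abs=0.01)

    def test_degenerate_variance_directs_to_rank_test(self):
        with pytest.raises(DegenerateVarianceError, match="mann_whitney"):
            compare_scores([1.0, 1.0, 1.0], [2.0, 2.0, 2.0], method="student")
        stat, p = compare_scores([1.0, 1.0, 1.0], [2.0, 2.0, 2.0], method="mann_whitney")
        assert p < 0.2
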