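"""TP53 x signature-class stratification and survival comparison.

The four strata cross mutation status (mutant / wild_type) with activation
class (high / low).  The Kaplan-Meier product-limit estimator and the
log-rank (Mantel-Cox) test are implemented from first principles: at every
distinct event time a contingency table of events against groups is formed,
expected event counts and the hypergeometric covariance are accumulated, and
the chi-square statistic is the quadratic form of (observed - expected)
against the generalized inverse of that covariance.  Ties between an event
and a censoring at the same time are resolved with events first (the censored
subject is still at risk at that time).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_io import MutationTable
from .errors import DegenerateVarianceError, ValidationError
from .signature_scoring import ActivationCall

__all__ = [
    "DEFAULT_NULL_CLASSES",
    "TP53Status",
    "StratumTable",
    "CrossTab",
    "SurvivalCurve",
    "LogrankResult",
    "assign_tp53_status",
    "stratify",
    "crosstab",
    "km_estimate",
    "logrank_test",
    "compare_scores",
]

#: Variant classes counted as loss-of-function ("null") alterations.
DEFAULT_NULL_CLASSES = frozenset({"truncating", "splice", "deletion_null"})

STRATA = ("mut_high", "mut_low", "wt_high", "wt_low")


@dataclass
class TP53Status:
    """Per-sample mutation status for one gene.

    ``table`` columns: ``status`` ("mutant"/"wild_type"), ``is_null`` (bool,
    True iff any record's class falls in the null definition) and ``classes``
    (comma-joined observed classes, empty for wild_type).
    """

    table: pd.DataFrame  # index = sample ids
    gene: str
    null_definition: frozenset[str]


@dataclass
class StratumTable:
    """Four-way stratum assignment for samples with both calls.

    ``table`` columns: ``tp53_status``, ``met_class``, ``stratum``.  Samples
    missing either call are excluded and counted in ``n_excluded``.
    """

    table: pd.DataFrame  # index = sample ids
    n_excluded: int = 0

    def counts(self) -> pd.Series:
        return self.table["stratum"].value_counts().reindex(STRATA, fill_value=0)


@dataclass
class CrossTab:
    """2x2 mutation-status x activation-class table with proportions and OR."""

    counts: pd.DataFrame  # rows mutant/wild_type, cols high/low
    row_proportions: pd.DataFrame
    odds_ratio: float
    haldane_corrected: bool = False

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())


@dataclass
class SurvivalCurve:
    """Product-limit estimate tabulated at distinct event times."""

    table: pd.DataFrame  # columns: time, n_at_risk, n_events, survival

    def survival_at(self, t: float) -> float:
        tab = self.table
        past = tab[tab["time"] <= t]
        return 1.0 if past.empty else float(past["survival"].iloc[-1])


@dataclass
class LogrankResult:
    statistic: float
    df: int
    p_value: float
    observed: np.ndarray  # per-group observed event counts
    expected: np.ndarray  # per-group expected event counts
    group_labels: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# stratification
# ---------------------------------------------------------------------------

def assign_tp53_status(
    mutations: MutationTable,
    samples: Iterable[str],
    gene: str = "TP53",
    null_definition: Iterable[str] = DEFAULT_NULL_CLASSES,
) -> TP53Status:
    """Call each sample mutant iff it has >= 1 record for ``gene``.

    Samples absent from the mutation table are wild_type by contract (the
    table is assumed to cover the cohort).  A mutant sample is additionally
    flagged null iff any of its records' classes is in ``null_definition``.
    """
    null_def = frozenset(null_definition)
    recs = mutations.records_for_gene(gene)
    by_sample = recs.groupby("sample_id")["variant_class"].agg(list)
    rows = []
    for s in samples:
        classes = by_sample.get(s, [])
        rows.append(
            {
                "status": "mutant" if classes else "wild_type",
                "is_null": bool(set(classes) & null_def),
                "classes": ",".join(sorted(set(classes))),
            }
        )
    table = pd.DataFrame(rows, index=pd.Index(list(samples), name="sample_id"))
    return TP53Status(table=table, gene=gene, null_definition=null_def)


def stratify(status: TP53Status, calls: ActivationCall) -> StratumTable:
    """Combine mutation status and activation class into four strata."""
    common = [s for s in calls.labels.index if s in status.table.index]
    n_excluded = (
        len(set(calls.labels.index) ^ set(status.table.index))
    )
    if not common:
        raise ValidationError(
            "mutation-status and activation-call sample sets are disjoint"
        )
    st = status.table.loc[common, "status"].map({"mutant": "mut", "wild_type": "wt"})
    met = calls.labels[common]
    table = pd.DataFrame(
        {
            "tp53_status": status.table.loc[common, "status"],
            "met_class": met,
            "stratum": st.str.cat(met, sep="_"),
        },
        index=pd.Index(common, name="sample_id"),
    )
    return StratumTable(table=table, n_excluded=n_excluded)


def crosstab(strata: StratumTable) -> CrossTab:
    """Counts, within-row proportions and odds ratio for the 2x2 table.

    A 0.5 Haldane-Anscombe correction is applied to the odds ratio only when
    a cell is zero, and the result is flagged as corrected.
    """
    if strata.table.empty:
        raise ValidationError("empty stratum table")
    counts = (
        pd.crosstab(strata.table["tp53_status"], strata.table["met_class"])
        .reindex(index=["mutant", "wild_type"], columns=["high", "low"], fill_value=0)
    )
    row_tot = counts.sum(axis=1)
    props = counts.div(row_tot.replace(0, np.nan), axis=0).fillna(0.0)
    a = float(counts.loc["mutant", "high"])
    b = float(counts.loc["mutant", "low"])
    c = float(counts.loc["wild_type", "high"])
    d = float(counts.loc["wild_type", "low"])
    corrected = min(a, b, c, d) == 0
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    odds_ratio = (a * d) / (b * c)
    return CrossTab(
        counts=counts,
        row_proportions=props,
        odds_ratio=odds_ratio,
        haldane_corrected=corrected,
    )


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------

def _clean_surv(times, events) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size == 0:
        raise ValidationError("empty survival input")
    if t.shape != e.shape:
        raise ValidationError("times and events have different lengths")
    if (t < 0).any():
        raise ValidationError("negative survival times")
    if not set(np.unique(e)) <= {0, 1}:
        raise ValidationError("event indicators must be 0 or 1")
    return t, e


def km_estimate(times: Sequence[float], events: Sequence[int]) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimator.

    The curve is tabulated at distinct event times; censored-only times enter
    only through the risk sets.  With no censoring the estimate coincides with
    the empirical survival function.
    """
    t, e = _clean_surv(times, events)
    event_times = np.unique(t[e == 1])
    rows = []
    s = 1.0
    for et in event_times:
        n_risk = int(np.sum(t >= et))
        d = int(np.sum((t == et) & (e == 1)))
        s *= 1.0 - d / n_risk
        rows.append({"time": et, "n_at_risk": n_risk, "n_events": d, "survival": s})
    return SurvivalCurve(pd.DataFrame(rows, columns=["time", "n_at_risk", "n_events", "survival"]))


def logrank_test(
    groups: Sequence[tuple[Sequence[float], Sequence[int]]],
    labels: Sequence[str] | None = None,
) -> LogrankResult:
    """k-sample log-rank (Mantel-Cox) test.

    At each distinct event time, expected per-group event counts are
    ``d * n_j / n`` and the covariance of observed counts is the multivariate
    hypergeometric one; the statistic is the quadratic form over the first
    k - 1 groups, chi-square with k - 1 df under the null.
    """
    if len(groups) < 2:
        raise ValidationError("log-rank test needs at least 2 groups")
    cleaned = [_clean_surv(t, e) for t, e in groups]
    if any(t.size == 0 for t, _ in cleaned):
        raise ValidationError("log-rank test groups must be non-empty")
    k = len(cleaned)
    all_t = np.concatenate([t for t, _ in cleaned])
    all_e = np.concatenate([e for _, e in cleaned])
    if all_e.sum() == 0:
        raise ValidationError("no events in any group")
    event_times = np.unique(all_t[all_e == 1])

    observed = np.zeros(k)
    expected = np.zeros(k)
    cov = np.zeros((k, k))
    for et in event_times:
        n_j = np.array([np.sum(t >= et) for t, _ in cleaned], dtype=float)
        d_j = np.array(
            [np.sum((t == et) & (e == 1)) for t, e in cleaned], dtype=float
        )
        n, d = n_j.sum(), d_j.sum()
        if n == 0 or d == 0:
            continue
        p = n_j / n
        observed += d_j
        expected += d * p
        if n > 1:
            scale = d * (n - d) / (n - 1)
            cov += scale * (np.diag(p) - np.outer(p, p))

    delta = (observed - expected)[: k - 1]
    v = cov[: k - 1, : k - 1]
    stat = float(delta @ np.linalg.pinv(v) @ delta) if delta.size else 0.0
    df = k - 1
    p_value = float(stats.chi2.sf(stat, df))
    return LogrankResult(
        statistic=stat,
        df=df,
        p_value=p_value,
        observed=observed,
        expected=expected,
        group_labels=tuple(labels) if labels is not None else tuple(f"group{i}" for i in range(k)),
    )


# ---------------------------------------------------------------------------
# group-score comparisons
# ---------------------------------------------------------------------------

def compare_scores(
    a: Sequence[float],
    b: Sequence[float],
    method: str = "student",
) -> tuple[float, float]:
    """Two-sided two-sample comparison of score vectors.

    ``method`` is ``"student"`` (pooled-variance t), ``"welch"`` (unequal
    variances) or ``"mann_whitney"`` (rank based).  A t-variant on data with
    zero variance in both groups is refused with a pointer to the rank test.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if method in ("student", "welch"):
        if x.size < 2 or y.size < 2:
            raise ValidationError("t-tests require at least 2 values per group")
        if np.var(x) == 0 and np.var(y) == 0:
            raise DegenerateVarianceError(
                "both groups have zero variance; use method='mann_whitney'"
            )
        res = stats.ttest_ind(x, y, equal_var=(method == "student"))
    elif method == "mann_whitney":
        if x.size < 1 or y.size < 1:
            raise ValidationError("rank test requires at least 1 value per group")
        res = stats.mannwhitneyu(x, y, alternative="two-sided")
    else:
        raise ValidationError(f"unknown method {method!r}")
    return float(res.statistic), float(res.pvalue)
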