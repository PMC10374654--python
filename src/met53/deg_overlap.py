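"""DEG filtering, cross-species symbol mapping, set overlap and
over-representation testing.

This module consumes per-gene statistic tables produced by any upstream
differential-expression fitter and owns everything after the fit: multiple-
testing adjustment (Benjamini-Hochberg), threshold filtering (fold change
strictly > 1.5 and adjusted p strictly < 0.05 by default), mouse-to-human
symbol mapping, exact set algebra for Venn overlaps, and an upper-tail
hypergeometric over-representation test with BH adjustment across categories.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cohort_io import DEGTable, GeneSet
from .errors import ValidationError

__all__ = [
    "FilterSpec",
    "OverlapResult",
    "MOUSE_HUMAN_EXCEPTIONS",
    "bh_adjust",
    "filter_degs",
    "map_orthologs",
    "overlap",
    "ora_test",
]


@dataclass(frozen=True)
class FilterSpec:
    """Thresholds for calling a gene differentially expressed.

    ``fold_change`` is a linear ratio cutoff (strict: retained iff
    FC > cutoff for "up", FC < 1/cutoff for "down", either for "both").
    ``p_adj`` is the strict adjusted-p cutoff.  ``p_raw`` optionally adds a
    raw-p gate on top of the adjusted one; by default only the adjusted gate
    applies.
    """

    fold_change: float = 1.5
    p_adj: float = 0.05
    direction: str = "up"
    p_raw: float | None = None

    def __post_init__(self) -> None:
        if self.fold_change <= 0:
            raise ValidationError("fold-change cutoff must be > 0")
        if not (0 < self.p_adj <= 1):
            raise ValidationError("adjusted-p cutoff must be in (0, 1]")
        if self.direction not in ("up", "down", "both"):
            raise ValidationError(f"unknown direction {self.direction!r}")


@dataclass(frozen=True)
class OverlapResult:
    """Exact set-algebra summary of two gene lists."""

    n_a: int
    n_b: int
    n_intersection: int
    n_union: int
    n_a_only: int
    n_b_only: int
    intersection: tuple[str, ...]
    universe_size: int | None = None


#: Mouse -> human symbol pairs the simple uppercase rule gets wrong.
MOUSE_HUMAN_EXCEPTIONS: Mapping[str, str] = {
    "Trp53": "TP53",
    "Trp63": "TP63",
    "Trp73": "TP73",
    "Trp53bp1": "TP53BP1",
    "Trp53inp1": "TP53INP1",
}


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, capped at 1, original order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def filter_degs(table: DEGTable, spec: FilterSpec = FilterSpec()) -> list[str]:
    """Genes passing the fold-change and adjusted-p gates, in input order.

    If the table carries no ``p_adj`` column it is computed with
    :func:`bh_adjust` first.  All comparisons are strict, so a fold change of
    exactly the cutoff is excluded.
    """
    df = table.table
    if df.empty:
        raise ValidationError("empty DEG table")
    if "p_adj" in df.columns:
        p_adj = df["p_adj"].to_numpy(dtype=float)
    else:
        p_adj = bh_adjust(df["p_value"].to_numpy(dtype=float))
    fc = df["fold_change"].to_numpy(dtype=float)
    up = fc > spec.fold_change
    down = fc < 1.0 / spec.fold_change
    if spec.direction == "up":
        fc_ok = up
    elif spec.direction == "down":
        fc_ok = down
    else:
        fc_ok = up | down
    keep = fc_ok & (p_adj < spec.p_adj)
    if spec.p_raw is not None:
        keep &= df["p_value"].to_numpy(dtype=float) < spec.p_raw
    return df.loc[keep, "gene"].tolist()


def map_orthologs(
    mouse_symbols: Iterable[str],
    mapping: Mapping[str, str] | None = None,
) -> tuple[list[str], list[str]]:
    """Map mouse symbols to human symbols.

    With ``mapping`` supplied, a pure table lookup: symbols absent from the
    table go to the unmapped report.  Without one, the default rule uppercases
    the symbol, with a built-in exception list for known non-trivial pairs
    (e.g. Trp53 -> TP53).  Returns ``(human_symbols, unmapped)``; mapped
    symbols keep input order with duplicates (after mapping) removed.
    """
    symbols = list(mouse_symbols)
    if not symbols:
        raise ValidationError("no symbols to map")
    mapped: list[str] = []
    unmapped: list[str] = []
    for s in symbols:
        if mapping is not None:
            if s in mapping:
                mapped.append(mapping[s])
            else:
                unmapped.append(s)
        else:
            mapped.append(MOUSE_HUMAN_EXCEPTIONS.get(s, s.upper()))
    return list(dict.fromkeys(mapped)), unmapped


def overlap(
    a: Iterable[str],
    b: Iterable[str],
    universe: Iterable[str] | None = None,
) -> OverlapResult:
    """Venn counts for two gene lists (exact set algebra)."""
    sa, sb = set(a), set(b)
    inter = sa & sb
    return OverlapResult(
        n_a=len(sa),
        n_b=len(sb),
        n_intersection=len(inter),
        n_union=len(sa | sb),
        n_a_only=len(sa - sb),
        n_b_only=len(sb - sa),
        intersection=tuple(sorted(inter)),
        universe_size=None if universe is None else len(set(universe)),
    )


def ora_test(
    hits: Iterable[str],
    categories: Sequence[GeneSet],
    universe: Iterable[str],
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation test per category.

    Categories are intersected with the universe before testing; the p-value
    is P(X >= overlap) for X hypergeometric(universe, category, hits), fold
    enrichment is (overlap/hits)/(category/universe), and p-values are BH-
    adjusted across categories.  ``hits`` must be a subset of ``universe``.
    """
    uni = set(universe)
    hit_set = set(hits)
    if not uni:
        raise ValidationError("empty universe")
    if not hit_set:
        raise ValidationError("empty hit list")
    stray = hit_set - uni
    if stray:
        raise ValidationError(f"hits outside the universe: {sorted(stray)[:5]}")
    m, n_hits = len(uni), len(hit_set)
    rows = []
    for cat in categories:
        members = set(cat.genes) & uni
        k = len(members & hit_set)
        n_cat = len(members)
        # P(X >= k); sf(k-1) is the exact upper tail
        p = float(stats.hypergeom.sf(k - 1, m, n_cat, n_hits)) if n_cat else 1.0
        fe = (
            (k / n_hits) / (n_cat / m) if n_cat and k else 0.0
        )
        rows.append(
            {
                "category": cat.name,
                "category_size": n_cat,
                "hits": n_hits,
                "overlap": k,
                "universe": m,
                "fold_enrichment": fe,
                "p_value": min(p, 1.0),
            }
        )
    out = pd.DataFrame(rows)
    out["p_adj"] = bh_adjust(out["p_value"].to_numpy()) if len(out) else []
    return out
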