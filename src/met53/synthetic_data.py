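"""Seeded generators for synthetic cohorts, RNA-seq count tables, and
dose-response plates with the statistical structure the analysis assumes.

Every generator is a pure function of its configuration: the same seed gives
bit-identical output.  One global seed expands into per-component child
streams through ``numpy.random.SeedSequence.spawn`` in a fixed order (gene
parameters, mutation/activation labels, expression noise, survival), so each
sub-generator is independently reproducible.

The cohort generator emulates the structure of a tumor/adjacent-tissue bulk
expression study: 360 tumor (HCC) and 50 surrounding-tissue (ST) samples,
~31% of tumors TP53-mutant, a planted "activated" tumor fraction whose
signature genes are shifted upward, a configurable odds ratio coupling
activation to mutation status, and exponential survival with an elevated
hazard in double-altered (mutant and activated) tumors.  Truth labels are
emitted in a separate table and never leak into the analyst-facing outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq

from .cohort_io import ClinicalTable, DEGTable, ExpressionMatrix, MutationTable
from .dose_response import DoseResponseTable, four_pl
from .errors import ValidationError

__all__ = [
    "CohortSimConfig",
    "SimulatedCohort",
    "conditional_activation_probs",
    "simulate_cohort",
    "simulate_deg_counts",
    "simulate_dose_response",
]

#: Relative frequencies of TP53 variant classes among mutant tumors
#: (missense-dominated, as in typical tumor sequencing cohorts).
VARIANT_CLASS_PROBS = {
    "missense": 0.60,
    "truncating": 0.25,
    "splice": 0.07,
    "inframe": 0.05,
    "deletion_null": 0.03,
}


@dataclass(frozen=True)
class CohortSimConfig:
    """Study-condition parameters for the cohort generator.

    Defaults mirror the analyzed human cohort: 360 tumors + 50 surrounding
    tissues, 111/360 tumors mutant, 215/360 tumors with the activated
    signature, and a mutation-activation odds ratio of 2 (the odds ratio
    implied by the cohort's 79/32 vs 136/113 high/low split is ~2.05).
    """

    n_hcc: int = 360
    n_st: int = 50
    mutant_fraction: float = 111 / 360
    activated_fraction: float = 215 / 360
    n_signature_genes: int = 18
    n_background_genes: int = 200
    signature_shift: float = 2.0  # in per-gene reference-SD units
    odds_ratio: float = 2.0
    baseline_hazard: float = 0.015  # events per month
    hazard_multiplier: float = 2.5  # for double-altered tumors
    censoring_rate: float = 0.01  # per month; plus administrative cap
    followup_cap: float = 120.0  # months
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("mutant_fraction", "activated_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must lie in [0, 1]")
        if self.odds_ratio <= 0:
            raise ValidationError("odds_ratio must be > 0")
        for name in ("n_hcc", "n_st", "n_signature_genes", "n_background_genes"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")


@dataclass
class SimulatedCohort:
    expression: ExpressionMatrix
    clinical: ClinicalTable
    mutations: MutationTable
    truth: pd.DataFrame  # index = HCC sample ids
    signature_genes: tuple[str, ...]
    config: CohortSimConfig


def conditional_activation_probs(
    mutant_fraction: float, activated_fraction: float, odds_ratio: float
) -> tuple[float, float]:
    """Solve P(activated | mutant), P(activated | wild-type) from the
    activation marginal and the odds ratio.

    With p_w = P(act | wt), the odds-ratio constraint gives
    p_m = OR * p_w / (1 + (OR - 1) * p_w); the marginal constraint
    f * p_m + (1 - f) * p_w = activated_fraction is monotone in p_w, so the
    root is unique and found by bisection on [0, 1].
    """
    f, m, r = mutant_fraction, activated_fraction, odds_ratio
    if not (0.0 <= m <= 1.0) or r <= 0:
        raise ValidationError(
            "infeasible marginals: activated_fraction must lie in [0, 1] "
            "and odds_ratio must be > 0"
        )
    if m in (0.0, 1.0):
        return m, m

    def p_mut(p_w: float) -> float:
        return r * p_w / (1.0 + (r - 1.0) * p_w)

    g = lambda p_w: f * p_mut(p_w) + (1.0 - f) * p_w - m
    p_w = brentq(g, 0.0, 1.0, xtol=1e-14)
    return p_mut(p_w), p_w


def simulate_cohort(config: CohortSimConfig | None = None) -> SimulatedCohort:
    """Generate a full synthetic tumor/adjacent-tissue cohort.

    Background genes are independent Gaussians with per-gene baseline mean
    and SD; in planted-activated tumors every signature gene is shifted
    upward by ``signature_shift`` gene SDs.  ST samples are drawn from the
    background (non-activated) distribution only.  Survival times are
    exponential with hazard ``baseline_hazard`` times ``hazard_multiplier``
    for tumors that are both mutant and activated; censoring is the minimum
    of an exponential dropout time and the administrative follow-up cap.
    """
    cfg = config if config is not None else CohortSimConfig()
    ss = np.random.SeedSequence(cfg.seed)
    rng_genes, rng_labels, rng_expr, rng_surv = (
        np.random.default_rng(child) for child in ss.spawn(4)
    )

    sig_genes = tuple(f"SIG{i + 1:02d}" for i in range(cfg.n_signature_genes))
    bg_genes = tuple(f"BG{i + 1:04d}" for i in range(cfg.n_background_genes))
    genes = list(sig_genes) + list(bg_genes)
    hcc = [f"HCC_{i + 1:03d}" for i in range(cfg.n_hcc)]
    st = [f"ST_{i + 1:03d}" for i in range(cfg.n_st)]
    samples = hcc + st

    n_genes = len(genes)
    gene_mu = rng_genes.normal(8.0, 2.0, size=n_genes)
    gene_sd = rng_genes.uniform(0.5, 1.5, size=n_genes)

    # mutation status: exact count, random assignment
    n_mut = int(round(cfg.n_hcc * cfg.mutant_fraction))
    mut_idx = rng_labels.choice(cfg.n_hcc, size=n_mut, replace=False)
    mutant = np.zeros(cfg.n_hcc, dtype=bool)
    mutant[mut_idx] = True

    # activation conditional on mutation status, at the configured odds ratio
    p_m, p_w = conditional_activation_probs(
        cfg.mutant_fraction, cfg.activated_fraction, cfg.odds_ratio
    )
    p_act = np.where(mutant, p_m, p_w)
    activated = rng_labels.random(cfg.n_hcc) < p_act

    # expression: background Gaussian; signature genes shifted in activated tumors
    values = gene_mu[:, None] + gene_sd[:, None] * rng_expr.normal(
        size=(n_genes, len(samples))
    )
    n_sig = cfg.n_signature_genes
    shift = cfg.signature_shift * gene_sd[:n_sig, None]
    values[:n_sig, : cfg.n_hcc] += shift * activated[None, :]
    expression = ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=samples)
    )

    # mutation table (TP53 records for mutant tumors)
    classes = list(VARIANT_CLASS_PROBS)
    probs = np.array(list(VARIANT_CLASS_PROBS.values()))
    drawn = rng_labels.choice(classes, size=n_mut, p=probs / probs.sum())
    mutations = MutationTable(
        pd.DataFrame(
            {
                "sample_id": [hcc[i] for i in np.sort(mut_idx)],
                "gene": "TP53",
                "variant_class": drawn,
            }
        )
    )

    # survival: exponential with elevated hazard in double-altered tumors
    double = mutant & activated
    hazard = cfg.baseline_hazard * np.where(double, cfg.hazard_multiplier, 1.0)
    hazard_all = np.concatenate([hazard, np.full(cfg.n_st, cfg.baseline_hazard)])
    t_event = rng_surv.exponential(1.0 / hazard_all)
    t_cens = np.minimum(
        rng_surv.exponential(1.0 / cfg.censoring_rate, size=len(samples)),
        cfg.followup_cap,
    )
    os_time = np.minimum(t_event, t_cens)
    os_event = (t_event <= t_cens).astype(int)
    clinical = ClinicalTable(
        pd.DataFrame(
            {
                "sample_id": samples,
                "sample_type": ["HCC"] * cfg.n_hcc + ["ST"] * cfg.n_st,
                "os_time": os_time,
                "os_event": os_event,
            }
        )
    )

    strat = np.where(
        mutant,
        np.where(activated, "mut_high", "mut_low"),
        np.where(activated, "wt_high", "wt_low"),
    )
    truth = pd.DataFrame(
        {
            "mutant": mutant,
            "activated": activated,
            "stratum": strat,
            "hazard": hazard,
        },
        index=pd.Index(hcc, name="sample_id"),
    )
    return SimulatedCohort(
        expression=expression,
        clinical=clinical,
        mutations=mutations,
        truth=truth,
        signature_genes=sig_genes,
        config=cfg,
    )


def simulate_deg_counts(
    n_genes: int = 2000,
    n_per_group: int = 5,
    de_fraction: float = 0.1,
    effect_log2fc: float = 3.0,
    dispersion: float = 0.05,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[str], DEGTable]:
    """Two-group negative-binomial count matrix with planted DE genes.

    Per-gene baseline means are log-normal (median ~100 counts); planted DE
    genes have the group-2 mean multiplied by ``2**effect_log2fc``.  Counts
    are NB with variance mu + dispersion * mu^2 (Poisson when dispersion is
    0).  Returns ``(counts, planted_genes, stat_table)`` where the statistic
    table carries the fold change estimated from the simulated counts and a
    Welch-test p on log2(count + 1) per gene, plus its BH adjustment — the
    planted truth stays in the separate gene list.
    """
    if not (0.0 <= de_fraction <= 1.0):
        raise ValidationError("de_fraction must lie in [0, 1]")
    if dispersion < 0:
        raise ValidationError("dispersion must be >= 0")
    if n_genes <= 0 or n_per_group <= 0:
        raise ValidationError("n_genes and n_per_group must be positive")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    genes = [f"G{i + 1:05d}" for i in range(n_genes)]
    mu = rng.lognormal(mean=np.log(100.0), sigma=1.0, size=n_genes)
    n_de = int(round(n_genes * de_fraction))
    de_idx = rng.choice(n_genes, size=n_de, replace=False) if n_de else np.array([], dtype=int)
    mu2 = mu.copy()
    mu2[de_idx] *= 2.0 ** effect_log2fc

    def draw(means: np.ndarray) -> np.ndarray:
        m = means[:, None] * np.ones((1, n_per_group))
        if dispersion == 0:
            return rng.poisson(m)
        r = 1.0 / dispersion
        p = r / (r + m)
        return rng.negative_binomial(r, p)

    c1, c2 = draw(mu), draw(mu2)
    counts = pd.DataFrame(
        np.hstack([c1, c2]),
        index=genes,
        columns=[f"ctrl_{j + 1}" for j in range(n_per_group)]
        + [f"case_{j + 1}" for j in range(n_per_group)],
    )

    m1, m2 = c1.mean(axis=1), c2.mean(axis=1)
    fc = (m2 + 0.5) / (m1 + 0.5)
    l1, l2 = np.log2(c1 + 1.0), np.log2(c2 + 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = stats.ttest_ind(l2, l1, axis=1, equal_var=False).pvalue
    p = np.where(np.isnan(p), 1.0, p)
    from .deg_overlap import bh_adjust

    table = DEGTable(
        pd.DataFrame(
            {"gene": genes, "fold_change": fc, "p_value": p, "p_adj": bh_adjust(p)}
        )
    )
    planted = [genes[i] for i in np.sort(de_idx)]
    return counts, planted, table


def simulate_dose_response(
    params: tuple[float, float, float, float] = (0.0, 100.0, 1.0, 16.0),
    concentrations: np.ndarray | None = None,
    noise_sd: float = 0.0,
    replicates: int = 3,
    seed: int = 0,
) -> DoseResponseTable:
    """Plate of OD readings generated from a 4PL curve.

    ``params`` is (bottom, top, hill, ic50) on the percent-viability scale.
    OD is the curve scaled so a vehicle well reads 0.8 absorbance units;
    Gaussian noise of ``noise_sd`` percent viability is added on the OD
    scale.  Vehicle (concentration 0) wells are included with ``replicates``
    wells, as is each positive concentration.
    """
    bottom, top, hill, ic50 = params
    if ic50 <= 0:
        raise ValidationError("ic50 must be > 0")
    if concentrations is None:
        concentrations = np.geomspace(0.03, 300.0, 8)
    conc = np.asarray(concentrations, dtype=float)
    if (conc <= 0).any():
        raise ValidationError("concentrations must be positive (vehicle is added automatically)")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    scale = 0.8 / top  # vehicle viability is `top`, mapped to OD 0.8
    rows = []
    for _ in range(replicates):
        rows.append({"concentration": 0.0, "od": 0.8})
    for c in conc:
        v = four_pl(np.array([c]), bottom, top, hill, ic50)[0]
        for _ in range(replicates):
            rows.append({"concentration": float(c), "od": float(v * scale)})
    df = pd.DataFrame(rows)
    if noise_sd > 0:
        df["od"] = df["od"] + rng.normal(0.0, noise_sd * scale, size=len(df))
    return DoseResponseTable(df)
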