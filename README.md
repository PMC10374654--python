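# met53

Co-occurrence analysis of **gene-signature activation and mutation status in
tumor cohorts**, built around the question of whether hepatocellular
carcinomas (HCC) carrying *TP53* mutations are enriched for a transcriptional
c-MET activation signature, and whether the double-altered tumors fare worse.
The package also covers the quantitative preclinical analyses that usually
accompany such a study: four-parameter-logistic IC50 estimation from
crystal-violet viability plates and caliper-based xenograft growth
comparison.

It is a library first (everything is importable and testable), with a thin
`met53` command-line interface on top, and ships a seeded synthetic-cohort
generator so the entire pipeline can be exercised end-to-end without any
external downloads.

## The method

**Signature score.** Given a gene × sample expression matrix, each gene is
standardized to a z-score, `z_gs = (x_gs − μ_g) / σ_g`, using the mean and
sample SD (ddof 1) of a reference population (all samples by default;
configurable). The score of sample *s* for gene set *G* is the unweighted
mean `score_s = (1/|G|) Σ_{g∈G} z_gs`. The default set of interest is the
18-gene c-MET activation signature (`KAPOSI_LIVER_CANCER_MET_UP`).

**Activation threshold.** Tumors are compared against the surrounding
(non-tumor) liver tissue samples (ST):

    τ = mean(score_ST) + k · SD(score_ST),   k = 1.5

A tumor is called *c-MET high* iff its score strictly exceeds τ.

**Stratification and survival.** Samples are crossed into four strata
(TP53 mutant/wild-type × c-MET high/low); the 2×2 table yields within-row
activation proportions and an odds ratio. Overall survival is compared with
the Kaplan–Meier product-limit estimator and the log-rank (Mantel–Cox) test
— both implemented from first principles — with the primary contrast being
double-altered (mutant & high) versus everyone else. Group score
comparisons use Student's t, Welch's t, or Mann–Whitney.

**Cross-species DEG overlap.** Differential-expression tables (any upstream
fitter) are filtered at linear fold change > 1.5 and Benjamini–Hochberg
adjusted p < 0.05, mouse symbols are mapped to human (lookup table, or an
uppercase rule with a Trp53→TP53-style exception list), set overlaps are
counted, and over-representation of pathway categories is tested with an
upper-tail hypergeometric p, BH-adjusted across categories.

**Dose-response and growth.** Viability is anchored to the vehicle-well mean
(=100%); `v(c) = bottom + (top − bottom)/(1 + (c/IC50)^hill)` is fit by
least squares on log10 concentration (relative IC50 = inflection; the
absolute 50% crossing is a derived field). Xenograft volumes use
`V = A·B²/2` from the two caliper diameters.

## Worked example

```python
from met53.cohort_io import GeneSet
from met53.signature_scoring import (standardize, signature_score,
                                     activation_threshold, classify_met)
from met53.stratification_survival import (assign_tp53_status, stratify,
                                           crosstab, logrank_test)
from met53.synthetic_data import CohortSimConfig, simulate_cohort

sim = simulate_cohort(CohortSimConfig(seed=1))          # 360 HCC + 50 ST
z = standardize(sim.expression)
scores = signature_score(z, GeneSet("SIM_SIGNATURE", sim.signature_genes))
thr = activation_threshold(scores, sim.clinical, k=1.5)
calls = classify_met(scores, sim.clinical, thr)
status = assign_tp53_status(sim.mutations, list(calls.labels.index))
ct = crosstab(stratify(status, calls))
```

This prints (via the obvious `print` statements):

```
threshold tau = -0.4037  (ST mean -0.6742, ST SD 0.1803, n_ST 50)
met_class    high  low
tp53_status
mutant         75   36
wild_type     129  120
mutant high: 67.6%   wild-type high: 51.8%   odds ratio: 1.94
log-rank (double-altered vs rest): chi2 = 29.03, df = 1, p = 7.13e-08
```

i.e. the activation threshold sits 1.5 ST standard deviations above the ST
score mean, mutant tumors are called high more often than wild-type ones
(67.6% vs 51.8%, odds ratio ≈ 2), and the double-altered stratum has clearly
worse survival. The same flow is available from the shell:

```sh
met53 simulate cohort --seed 1 --out cohort/
met53 score --expr cohort/expression.tsv --clinical cohort/clinical.csv \
            --gmt cohort/signature.gmt --set-name SIM_SIGNATURE --out scores.tsv
met53 stratify --scores scores.tsv --mutations cohort/mutations.tsv --out strata.tsv
met53 survive --strata strata.tsv --clinical cohort/clinical.csv --out surv/
```

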