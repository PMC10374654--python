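# Methods

## Signature scoring and activation calling

The per-sample signature score is the unweighted mean of per-gene z-scores
over the members of a gene set. Standardization is per gene:
`z = (x − μ_ref) / σ_ref` with the mean and *sample* SD (ddof 1) of a
reference population. The reference defaults to **all** samples (tumor +
surrounding tissue), matching the convention of standardizing the whole
displayed matrix; ST-only and HCC-only references are available because the
choice shifts and rescales scores (it never changes the within-gene sample
ranking, since the transform is affine per gene). Zero-variance genes have
no defined z-score; they are dropped and reported rather than imputed.

Activation is called against the non-tumor reference group:
`τ = mean(score_ST) + k·SD(score_ST)` with `k = 1.5` and the sample SD.
The inequality is strict ("more than"): a score exactly at τ is *low*. The
multiplier, the SD convention (ddof) and the reference population are all
explicit parameters, because each one moves the operating point of the
classifier; with Gaussian null scores, the default `k = 1.5` implies a
false-positive rate of about Φ̄(1.5) ≈ 6.7% among truly non-activated
tumors, which the synthetic null cohort reproduces.

Whether standardization happens before or after subsetting to the signature
genes is irrelevant as long as the reference population is unchanged (the
per-gene transform does not look at other genes); the implementation
standardizes the full matrix and subsets afterwards.

Missing signature genes are a hard error by default: with an 18-gene set,
silently scoring over a subset changes the statistic materially. A
`min_genes` escape hatch permits scoring over the present subset, with the
count and the missing symbols recorded.

## Stratification and survival

TP53 status is *mutant* iff the sample has at least one TP53 record of any
variant class; samples absent from the mutation table are wild-type by
contract (the table is assumed to cover the cohort). "Null"
(loss-of-function) status is a separate flag, defined by a parametric class
set defaulting to {truncating, splice, deletion_null}; the definition is a
logged parameter because the boundary between loss-of-function and other
alterations is a modelling choice, not a fact of the data.

The 2×2 crosstab reports within-row proportions and the odds ratio, with a
0.5 Haldane–Anscombe correction applied (and flagged) only when a cell is
zero.

The Kaplan–Meier estimator and the log-rank (Mantel–Cox) test are
implemented directly rather than delegated, since they are the analytical
core of the survival comparison. At each distinct event time the observed
per-group events are compared with expected counts `d·n_j/n`, and the
multivariate hypergeometric covariance is accumulated; the statistic is the
quadratic form over k−1 groups against the generalized inverse of that
covariance, referred to χ²(k−1). Events precede censoring at tied times
(the censored subject is still at risk). The implementation agrees with
lifelines to 1e-12 on random instances; lifelines is used only as a
cross-check, never as the implementation.

Small-sample caveat: the χ² reference is asymptotic. At n ≈ 20 the exact
permutation null of the statistic deviates from χ²(1) by up to a few
percentage points of tail mass (order 1/n), so permutation-based and
asymptotic p-values agree only approximately at that size; at the cohort
sizes the pipeline targets (hundreds of samples) the approximation error is
negligible. The primary contrast is double-altered vs the pooled remaining
strata; pairwise contrasts are available separately and are reported
without multiplicity adjustment.

Score comparisons between groups use Student's t (pooled variance),
Welch's t, or the Mann–Whitney test (scipy's default method, i.e. the exact
null for small tie-free samples where scipy selects it and the
continuity-corrected normal approximation otherwise). A t-variant on data
with zero variance in both groups is refused with a pointer to the rank
test.

## DEG filtering, mapping, overlap, enrichment

The module consumes per-gene statistic tables (gene, fold change, p,
optionally adjusted p) from any upstream fitter; the negative-binomial fit
itself is out of scope. Fold changes are linear ratios internally; a
`#fc_scale=log2` header (or an argument) declares log2 input. Filtering is
strict on both gates: FC > 1.5 (direction "up"; < 1/1.5 for "down") and
BH-adjusted p < 0.05. When no adjusted column is present it is computed by
Benjamini–Hochberg (statsmodels); an optional raw-p gate exists because
some pipelines apply both, but the default is adjusted-only.

Mouse→human symbol mapping uses a supplied lookup table when given
(unmatched symbols are reported, never dropped silently); otherwise an
uppercase rule with a built-in exception list for known non-trivial pairs
(Trp53→TP53 and relatives). Overlaps are exact set algebra.

Over-representation uses the upper-tail hypergeometric probability
P(X ≥ overlap) per category, fold enrichment
`(overlap/hits)/(category/universe)`, and BH adjustment across categories.
The universe defaults to the genes present in the statistic table — the
universe choice changes p substantially, so it is explicit and logged.

## Dose-response and xenograft growth

Viability is anchored to the vehicle (concentration 0) mean OD = 100%;
no background subtraction is applied (no blank wells are modelled). The
4PL `v(c) = bottom + (top−bottom)/(1+(c/IC50)^hill)` is fit by least squares
on log10 concentration with deterministic initialization (top = max v,
bottom = min v, hill = 1, IC50 = median log-concentration) plus a small
fixed restart grid over hill and the IC50 start; vehicle wells are excluded
from the fit. The reported IC50 is the inflection concentration (relative
IC50, the standard 4PL convention); the absolute-50% crossing is exposed as
a derived field. A flat response is returned with a degenerate flag rather
than an exception, since bottom ≈ top makes hill and IC50 unidentifiable.

Tumor volume is `V = A·B²/2` (mm³) with A the largest caliper diameter;
inputs with A < B are swapped with a warning. Endpoint comparisons
delegate to the same two-sample tests used for score comparisons.

## Synthetic data generator

The cohort generator emulates the structure of a tumor/adjacent-tissue bulk
expression study with defaults fixed to the study conditions: 360 HCC + 50
ST samples, 111/360 mutant tumors, 215/360 activated tumors, a
mutation–activation odds ratio of 2, an 18-gene signature shifted upward by
2 per-gene SDs in activated tumors over 200 Gaussian background genes,
exponential survival at 0.015 events/month with a ×2.5 hazard in
double-altered tumors, exponential dropout at 0.01/month capped at 120
months of follow-up. Activation is sampled conditionally on mutation
status, with the two conditional probabilities solved by bisection from the
(marginal, odds ratio) pair — the solve is monotone, so the root is unique.
Variant classes among mutants are missense-dominated (60% missense, 25%
truncating, 7% splice, 5% inframe, 3% deletion). One seed expands into
fixed-order child streams (gene parameters, labels, expression noise,
survival) via `SeedSequence.spawn`, so each component is independently
reproducible and the whole generator is bit-deterministic per seed.

What the generator deliberately does **not** emulate: gene–gene correlation
beyond the planted signature shift, count-distribution artifacts
(library-size, heteroskedastic mean–variance coupling beyond the NB count
generator used for DEG simulation), copy-number structure, batch effects,
or non-proportional hazards. Passing recovery tests on this generator
therefore demonstrates correctness of the analytical chain under its stated
model, not robustness to every pathology of real cohort data.

The DEG count generator draws NB counts (variance μ + αμ², Poisson at
α = 0) with log-normal baseline means (median ≈ 100 counts) and multiplies
the case-group mean of planted genes by 2^log2FC. Its emitted statistic
table carries the fold change *estimated from the simulated counts* and a
Welch-test p on log2(count+1) — the planted truth is a separate output, so
analyst-facing tables never leak labels.

The dose-response generator maps the 4PL curve to OD with vehicle = 0.8
absorbance units and adds Gaussian noise specified on the percent-viability
scale.

## Problem sizes and numerical choices

The test suite and the acceptance script use: 200 random ≤10×10 matrices
for the scoring oracle; 400 seeded cohorts for type-I calibration of the
log-rank test (binomial 99% CI around α = 0.05); 100 seeded cohorts for
end-to-end recovery; 2000-gene DEG simulations; 100 noisy plates for IC50
recovery. These sizes give Monte-Carlo error comfortably below the
tolerances being checked while keeping a full run in tens of seconds.
Tolerances: exact oracles at 1e-12 (scoring, enrichment enumeration),
hand-computed survival statistics at 1e-9, noise-free 4PL recovery at 1e-6
relative. Ties at the activation threshold go to "low"; ties between event
and censoring times count the censored subject as at risk.

## Known limitations

- The expression reader accepts any numeric matrix and leaves units to the
  caller; it does not verify that values are log-scale or normalized.
- The log-rank implementation reports no hazard ratio or confidence
  interval, and there is no Cox regression.
- Ortholog mapping without a lookup table is heuristic (uppercase +
  exceptions) and intended for well-behaved symbol sets.
- Relative IC50 extrapolates if the tested concentration range does not
  bracket the inflection; the convergence/degeneracy flags should be
  checked before trusting the estimate.
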