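"""Per-sample gene-signature scoring and activation calling.

The score of a sample is the unweighted mean of its per-gene standardized
(z-score) expression over the members of a gene set.  Tumors are called
"activated" ("high") when their score strictly exceeds a threshold anchored
in the non-tumor reference group:

    tau = mean(ST scores) + k * SD(ST scores)        (sample SD, ddof 1)

with k = 1.5 by default, ST being the surrounding-liver-tissue samples.  The
standardization reference population defaults to all samples (tumor + ST) and
is configurable to either subset; standardization is a per-gene affine map,
so within-gene sample ranking is unaffected by the choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort_io import ClinicalTable, ExpressionMatrix, GeneSet
from .errors import ValidationError

__all__ = [
    "ZMatrix",
    "SignatureScores",
    "ActivationThreshold",
    "ActivationCall",
    "standardize",
    "signature_score",
    "activation_threshold",
    "classify_met",
]


@dataclass
class ZMatrix:
    """Per-gene standardized expression.

    ``values`` has the same labels as the source matrix minus zero-variance
    genes, which are listed in ``dropped_genes``.  ``gene_mean``/``gene_sd``
    are the reference-population statistics used, so the transform is exactly
    reproducible.
    """

    values: pd.DataFrame
    reference: str  # "all", "ST", "HCC" or "custom"
    reference_samples: tuple[str, ...]
    gene_mean: pd.Series
    gene_sd: pd.Series
    dropped_genes: tuple[str, ...] = ()

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class SignatureScores:
    """Per-sample signature score: mean z-value over present member genes."""

    scores: pd.Series  # index = sample ids, order as in the z-matrix
    set_name: str
    n_genes_used: int
    missing_genes: tuple[str, ...] = ()


@dataclass
class ActivationThreshold:
    """ST-referenced activation threshold with the statistics that produced it."""

    tau: float
    k: float
    st_mean: float
    st_sd: float
    n_st: int


@dataclass
class ActivationCall:
    """Per-tumor-sample high/low activation label.

    ``labels`` covers HCC samples only; a sample is "high" iff its score is
    strictly greater than ``threshold.tau`` (ties classify as "low").
    """

    labels: pd.Series  # index = HCC sample ids, values in {"high", "low"}
    threshold: ActivationThreshold

    @property
    def high_samples(self) -> list[str]:
        return list(self.labels.index[self.labels == "high"])


def standardize(
    expr: ExpressionMatrix,
    reference_samples: list[str] | None = None,
    clinical: ClinicalTable | None = None,
    reference: str = "all",
    ddof: int = 1,
) -> ZMatrix:
    """Z-transform each gene using reference-population mean and sample SD.

    Parameters
    ----------
    expr
        The expression matrix (any consistent numeric units; log-scale or
        normalized values are expected upstream).
    reference_samples
        Explicit reference population; overrides ``reference``.
    clinical, reference
        Convenience selector: ``"all"`` (default), ``"st"`` or ``"hcc"``;
        the latter two need ``clinical`` to resolve sample types.
    ddof
        Delta degrees of freedom for the SD (1 = sample SD, the default).

    Zero-variance genes are dropped and reported in ``dropped_genes``.
    """
    if reference_samples is None:
        if reference.lower() == "all":
            reference_samples = expr.samples
            ref_label = "all"
        else:
            if clinical is None:
                raise ValidationError(
                    "reference='st'/'hcc' requires a clinical table"
                )
            wanted = reference.upper()
            if wanted not in ("ST", "HCC"):
                raise ValidationError(f"unknown reference population {reference!r}")
            in_matrix = set(expr.samples)
            reference_samples = [
                s for s in clinical.samples_of_type(wanted) if s in in_matrix
            ]
            ref_label = wanted
    else:
        ref_label = "custom"
    missing = set(reference_samples) - set(expr.samples)
    if missing:
        raise ValidationError(f"reference samples absent from matrix: {sorted(missing)}")
    if len(reference_samples) < 2:
        raise ValidationError(
            f"reference population has {len(reference_samples)} sample(s); "
            "at least 2 required for a sample SD"
        )
    ref = expr.values[list(reference_samples)]
    mu = ref.mean(axis=1)
    sd = ref.std(axis=1, ddof=ddof)
    keep = sd > 0
    dropped = tuple(sd.index[~keep])
    z = expr.values.loc[keep].sub(mu[keep], axis=0).div(sd[keep], axis=0)
    return ZMatrix(
        values=z,
        reference=ref_label,
        reference_samples=tuple(reference_samples),
        gene_mean=mu[keep],
        gene_sd=sd[keep],
        dropped_genes=dropped,
    )


def signature_score(
    z: ZMatrix,
    gene_set: GeneSet,
    min_genes: int | None = None,
) -> SignatureScores:
    """Unweighted mean of member-gene z-values per sample.

    ``min_genes`` is the minimum number of members that must be present in the
    z-matrix; ``None`` (default) requires every member, so a missing signature
    gene is a hard error naming the absent symbols.
    """
    present = [g for g in gene_set.genes if g in z.values.index]
    missing = tuple(g for g in gene_set.genes if g not in z.values.index)
    required = len(gene_set) if min_genes is None else min_genes
    if len(present) < required:
        raise ValidationError(
            f"gene set {gene_set.name!r}: only {len(present)}/{len(gene_set)} "
            f"members present (required {required}); missing: {list(missing)}"
        )
    scores = z.values.loc[present].mean(axis=0)
    scores.name = "score"
    return SignatureScores(
        scores=scores,
        set_name=gene_set.name,
        n_genes_used=len(present),
        missing_genes=missing,
    )


def activation_threshold(
    scores: SignatureScores,
    clinical: ClinicalTable,
    k: float = 1.5,
    ddof: int = 1,
) -> ActivationThreshold:
    """tau = mean(ST scores) + k * SD(ST scores), sample SD by default."""
    st = [s for s in clinical.samples_of_type("ST") if s in scores.scores.index]
    if len(st) < 2:
        raise ValidationError(
            f"{len(st)} ST sample(s) with scores; at least 2 required"
        )
    st_scores = scores.scores[st]
    mean = float(st_scores.mean())
    sd = float(st_scores.std(ddof=ddof))
    return ActivationThreshold(
        tau=mean + k * sd, k=k, st_mean=mean, st_sd=sd, n_st=len(st)
    )


def classify_met(
    scores: SignatureScores,
    clinical: ClinicalTable,
    threshold: ActivationThreshold | float,
) -> ActivationCall:
    """Label each HCC sample "high" iff score > tau (strict); ST excluded."""
    if isinstance(threshold, (int, float)):
        threshold = ActivationThreshold(
            tau=float(threshold), k=float("nan"), st_mean=float("nan"),
            st_sd=float("nan"), n_st=0,
        )
    if not np.isfinite(threshold.tau):
        raise ValidationError("activation threshold is not finite")
    hcc = [s for s in clinical.samples_of_type("HCC") if s in scores.scores.index]
    if not hcc:
        raise ValidationError("no HCC samples with scores to classify")
    s = scores.scores[hcc]
    labels = pd.Series(
        np.where(s > threshold.tau, "high", "low"), index=s.index, name="met_class"
    )
    return ActivationCall(labels=labels, threshold=threshold)
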