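"""Readers, writers and validated in-memory containers for every table the
pipeline touches.

All parsers are strict: a malformed cell or an invariant violation raises
:class:`~met53.errors.FormatError` / :class:`~met53.errors.ValidationError`
rather than silently dropping or imputing rows.  Recoverable irregularities
(duplicate gene-set members, unrecognised variant-class strings) are repaired
and reported through :mod:`warnings`.

Formats
-------
* expression: TSV, gene symbols in the first column, sample ids in the header
* gene sets: GMT (name, description, members; tab-separated)
* clinical and mutation tables: headered CSV or TSV
* DEG statistic tables: TSV with columns ``gene``, ``fold_change``,
  ``p_value`` and optionally ``p_adj``
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

__all__ = [
    "ExpressionMatrix",
    "ClinicalTable",
    "MutationTable",
    "GeneSet",
    "DEGTable",
    "VARIANT_CLASSES",
    "SAMPLE_TYPES",
    "MAF_CLASS_ALIASES",
    "read_expression",
    "write_expression",
    "read_gmt",
    "write_gmt",
    "read_clinical",
    "write_clinical",
    "read_mutations",
    "write_mutations",
    "read_deg_table",
    "write_deg_table",
]

#: Canonical variant-class vocabulary.  "deletion_null" is first-class so the
#: loss-of-function ("null") subset is directly selectable downstream.
VARIANT_CLASSES = ("missense", "truncating", "splice", "inframe", "deletion_null", "other")

SAMPLE_TYPES = ("HCC", "ST")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Gene x sample numeric matrix with unique labels and finite values."""

    values: pd.DataFrame  # index = gene symbols, columns = sample ids

    def __post_init__(self) -> None:
        idx, cols = self.values.index, self.values.columns
        dup_g = idx[idx.duplicated()].unique().tolist()
        if dup_g:
            raise ValidationError(f"duplicate gene symbols: {dup_g}")
        dup_s = cols[cols.duplicated()].unique().tolist()
        if dup_s:
            raise ValidationError(f"duplicate sample ids: {dup_s}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("expression matrix must be numeric")
        if not np.all(np.isfinite(arr)):
            g, s = np.argwhere(~np.isfinite(arr))[0]
            raise ValidationError(
                f"non-finite expression value at gene {idx[g]!r}, sample {cols[s]!r}"
            )

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class ClinicalTable:
    """Per-sample clinical annotation: tissue type and overall survival."""

    table: pd.DataFrame  # columns: sample_id, sample_type, os_time, os_event

    REQUIRED = ("sample_id", "sample_type", "os_time", "os_event")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise FormatError(f"clinical table missing required columns: {missing}")
        t = self.table
        dup = t["sample_id"][t["sample_id"].duplicated()].unique().tolist()
        if dup:
            raise ValidationError(f"duplicate sample ids in clinical table: {dup}")
        bad_type = sorted(set(t["sample_type"]) - set(SAMPLE_TYPES))
        if bad_type:
            raise ValidationError(
                f"unknown sample_type labels {bad_type}; expected one of {SAMPLE_TYPES}"
            )
        if not set(pd.unique(t["os_event"])) <= {0, 1}:
            raise ValidationError("os_event must be 0 (censored) or 1 (death)")
        if (t["os_time"] < 0).any():
            bad = t.loc[t["os_time"] < 0, "sample_id"].tolist()
            raise ValidationError(f"negative os_time for samples {bad}")

    def samples_of_type(self, sample_type: str) -> list[str]:
        t = self.table
        return t.loc[t["sample_type"] == sample_type, "sample_id"].tolist()


@dataclass
class MutationTable:
    """Long-format mutation calls: one record per (sample, gene, class)."""

    table: pd.DataFrame  # columns: sample_id, gene, variant_class

    REQUIRED = ("sample_id", "gene", "variant_class")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise FormatError(f"mutation table missing required columns: {missing}")
        bad = sorted(set(self.table["variant_class"]) - set(VARIANT_CLASSES))
        if bad:
            raise ValidationError(
                f"variant_class labels {bad} outside vocabulary {VARIANT_CLASSES}"
            )
        self.table = self.table.drop_duplicates(subset=list(self.REQUIRED)).reset_index(drop=True)

    def records_for_gene(self, gene: str) -> pd.DataFrame:
        return self.table[self.table["gene"] == gene]


@dataclass(frozen=True)
class GeneSet:
    """Named collection of unique gene symbols."""

    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError(f"gene set {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError(f"gene set {self.name!r} contains duplicates")

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.genes)


@dataclass
class DEGTable:
    """Per-gene differential-expression statistics on linear fold-change scale."""

    table: pd.DataFrame  # columns: gene, fold_change, p_value, optionally p_adj

    REQUIRED = ("gene", "fold_change", "p_value")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise FormatError(f"DEG table missing required columns: {missing}")
        t = self.table
        dup = t["gene"][t["gene"].duplicated()].unique().tolist()
        if dup:
            raise ValidationError(f"duplicate genes in DEG table: {dup}")
        if (t["fold_change"] <= 0).any():
            raise ValidationError("fold_change must be > 0 (linear ratio scale)")
        for col in ("p_value", "p_adj"):
            if col in t.columns and ((t[col] < 0) | (t[col] > 1)).any():
                raise ValidationError(f"{col} outside [0, 1]")

    @property
    def has_adjusted(self) -> bool:
        return "p_adj" in self.table.columns


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def read_expression(path: str | Path) -> ExpressionMatrix:
    """Parse a genes-in-rows TSV into a validated :class:`ExpressionMatrix`.

    Row and column order are preserved from the file.  Duplicate labels and
    unparseable cells (including empty/NA cells) raise, naming the offending
    coordinate; missing values are never imputed.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    samples = header[1:]
    dup = [s for s in set(samples) if samples.count(s) > 1]
    if dup:
        raise ValidationError(f"duplicate sample ids in {path.name}: {sorted(dup)}")
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    raw.columns = samples  # undo any pandas de-duplication mangling
    dupg = raw.index[raw.index.duplicated()].unique().tolist()
    if dupg:
        raise ValidationError(f"duplicate gene symbols in {path.name}: {dupg}")
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = np.argwhere(numeric.isna().to_numpy())
    if bad.size:
        g, s = bad[0]
        raise FormatError(
            f"non-numeric cell {raw.iat[g, s]!r} at gene {raw.index[g]!r}, "
            f"sample {samples[s]!r} in {path.name}"
        )
    return ExpressionMatrix(numeric)


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.values.to_csv(path, sep="\t", index_label="gene")


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> list[GeneSet]:
    """Parse a GMT file: one set per line, ``name<TAB>description<TAB>members``.

    The description field is discarded; duplicate members within a line are
    deduplicated with a warning.  A line with fewer than three fields is a
    format error.
    """
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"GMT line {lineno}: expected name, description and at least "
                    f"one member, got {len(fields)} fields"
                )
            name, members = fields[0], fields[2:]
            unique = list(dict.fromkeys(members))  # preserves order
            if len(unique) != len(members):
                warnings.warn(
                    f"gene set {name!r}: {len(members) - len(unique)} duplicate "
                    "member(s) removed",
                    stacklevel=2,
                )
            sets.append(GeneSet(name, tuple(unique)))
    return sets


def write_gmt(sets: Iterable[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, "na", *s.genes]) + "\n")


# ---------------------------------------------------------------------------
# clinical
# ---------------------------------------------------------------------------

def read_clinical(path: str | Path) -> ClinicalTable:
    """Read a headered CSV/TSV with sample_id, sample_type, os_time, os_event."""
    df = pd.read_csv(path, sep=None, engine="python")
    if "sample_id" in df.columns:
        df["sample_id"] = df["sample_id"].astype(str)
    return ClinicalTable(df)


def write_clinical(clinical: ClinicalTable, path: str | Path) -> None:
    clinical.table.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# mutations
# ---------------------------------------------------------------------------

#: Ready-made alias table for common MAF-style class strings (opt-in).
MAF_CLASS_ALIASES: Mapping[str, str] = {
    "Missense_Mutation": "missense",
    "Nonsense_Mutation": "truncating",
    "Frame_Shift_Del": "truncating",
    "Frame_Shift_Ins": "truncating",
    "Splice_Site": "splice",
    "In_Frame_Del": "inframe",
    "In_Frame_Ins": "inframe",
}


def read_mutations(
    path: str | Path,
    aliases: Mapping[str, str] | None = None,
) -> MutationTable:
    """Read mutation calls.

    Class strings outside the canonical vocabulary are looked up in
    ``aliases`` (e.g. :data:`MAF_CLASS_ALIASES` maps "Nonsense_Mutation" to
    "truncating"); without an alias table, or for strings absent from it,
    they are demoted to ``"other"`` with a warning.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in MutationTable.REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"mutation file missing required columns: {missing}")
    alias_map = dict(aliases) if aliases is not None else {}

    def canon(label: str) -> str:
        if label in VARIANT_CLASSES:
            return label
        if label in alias_map:
            return alias_map[label]
        warnings.warn(
            f"unknown variant class {label!r} mapped to 'other'", stacklevel=3
        )
        return "other"

    df = df.copy()
    df["variant_class"] = df["variant_class"].map(canon)
    df["sample_id"] = df["sample_id"].astype(str)
    return MutationTable(df[list(MutationTable.REQUIRED)])


def write_mutations(mut: MutationTable, path: str | Path) -> None:
    mut.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# DEG statistic tables
# ---------------------------------------------------------------------------

def read_deg_table(path: str | Path, fold_change_scale: str | None = None) -> DEGTable:
    """Read a per-gene statistic table (TSV: gene, fold_change, p_value[, p_adj]).

    ``fold_change_scale`` is ``"linear"`` (default) or ``"log2"``; a leading
    comment line ``#fc_scale=log2`` in the file declares the scale and takes
    precedence over the default but not over an explicit argument.  Internally
    fold changes are always linear ratios.
    """
    path = Path(path)
    declared = None
    with open(path) as fh:
        first = fh.readline().strip()
    if first.startswith("#"):
        if "fc_scale=" in first:
            declared = first.split("fc_scale=")[1].strip()
    scale = fold_change_scale or declared or "linear"
    if scale not in ("linear", "log2"):
        raise FormatError(f"unknown fold-change scale {scale!r}")
    df = pd.read_csv(path, sep="\t", comment="#")
    if scale == "log2" and "fold_change" in df.columns:
        df = df.copy()
        df["fold_change"] = 2.0 ** df["fold_change"]
    return DEGTable(df)


def write_deg_table(table: DEGTable, path: str | Path) -> None:
    table.table.to_csv(path, sep="\t", index=False)
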