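"""End-to-end orchestration with a declarative config and a run manifest.

``run_cooccurrence`` executes score -> threshold -> classify -> stratify ->
crosstab -> score comparison -> KM/log-rank and writes every stage output
plus a JSON manifest; ``run_overlap`` chains adjust -> filter -> map ->
overlap -> enrichment for two DEG statistic tables.  The manifest echoes the
fully-defaulted config (no hidden knobs at run time), records a SHA-256
checksum for every input and output, and carries all warnings, so a run is
auditable and deterministic stages are checkably reproducible.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .cohort_io import (
    read_clinical,
    read_deg_table,
    read_expression,
    read_gmt,
    read_mutations,
)
from .deg_overlap import FilterSpec, filter_degs, map_orthologs, ora_test, overlap
from .errors import ValidationError
from .signature_scoring import (
    activation_threshold,
    classify_met,
    signature_score,
    standardize,
)
from .stratification_survival import (
    DEFAULT_NULL_CLASSES,
    assign_tp53_status,
    compare_scores,
    crosstab,
    km_estimate,
    logrank_test,
    stratify,
)

__all__ = ["CooccurrenceConfig", "OverlapConfig", "run_cooccurrence", "run_overlap"]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class CooccurrenceConfig:
    expression: str
    clinical: str
    mutations: str
    gmt: str
    out_dir: str
    set_name: str = "KAPOSI_LIVER_CANCER_MET_UP"
    k: float = 1.5
    reference: str = "all"  # standardization reference: all | st | hcc
    null_definition: tuple[str, ...] = tuple(sorted(DEFAULT_NULL_CLASSES))
    contrast: str = "double-vs-rest"  # or "pairwise"
    compare_method: str = "student"
    min_genes: int | None = None

    def validate(self) -> None:
        for name in ("expression", "clinical", "mutations", "gmt"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise ValidationError(f"config path {name}={p!r} does not exist")


@dataclass
class OverlapConfig:
    table_a: str  # e.g. mouse DEG statistics
    table_b: str  # e.g. human DEG statistics
    out_dir: str
    fold_change: float = 1.5
    p_adj: float = 0.05
    direction: str = "up"
    mapping: str | None = None  # optional two-column TSV mouse<TAB>human
    gmt: str | None = None  # optional pathway categories for enrichment
    map_a: bool = True  # treat table_a symbols as mouse and map them

    def validate(self) -> None:
        for name in ("table_a", "table_b"):
            if not Path(getattr(self, name)).exists():
                raise ValidationError(f"config path {name} does not exist")
        for name in ("mapping", "gmt"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ValidationError(f"config path {name}={p!r} does not exist")


def _manifest_skeleton(config_echo: dict) -> dict:
    return {
        "package_version": __version__,
        "config": config_echo,
        "inputs": {},
        "outputs": {},
        "warnings": [],
        "timing_seconds": None,
    }


def run_cooccurrence(config: CooccurrenceConfig) -> dict:
    """Run the full co-occurrence analysis; returns the manifest dict."""
    t0 = time.perf_counter()
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _manifest_skeleton(asdict(config))
    for name in ("expression", "clinical", "mutations", "gmt"):
        manifest["inputs"][name] = _sha256(Path(getattr(config, name)))

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        expr = read_expression(config.expression)
        clinical = read_clinical(config.clinical)
        mutations = read_mutations(config.mutations)
        sets = {s.name: s for s in read_gmt(config.gmt)}
        if config.set_name not in sets:
            raise ValidationError(
                f"gene set {config.set_name!r} not in {config.gmt}"
            )
        gene_set = sets[config.set_name]

        z = standardize(expr, clinical=clinical, reference=config.reference)
        scores = signature_score(z, gene_set, min_genes=config.min_genes)
        thr = activation_threshold(scores, clinical, k=config.k)
        calls = classify_met(scores, clinical, thr)
        status = assign_tp53_status(
            mutations, list(calls.labels.index),
            null_definition=config.null_definition,
        )
        strata = stratify(status, calls)
        ct = crosstab(strata)

        # score comparison between mutant and wild-type tumors
        mut_samples = status.table.index[status.table["status"] == "mutant"]
        wt_samples = status.table.index[status.table["status"] == "wild_type"]
        stat, p_cmp = compare_scores(
            scores.scores[mut_samples], scores.scores[wt_samples],
            method=config.compare_method,
        )

        # survival: join strata with follow-up, drop samples lacking it
        clin = clinical.table.set_index("sample_id")
        joined = strata.table.join(clin[["os_time", "os_event"]], how="inner")
        n_dropped = len(strata.table) - len(joined)
        if config.contrast == "double-vs-rest":
            grp_of = joined["stratum"].map(
                lambda s: "mut_high" if s == "mut_high" else "rest"
            )
        else:
            grp_of = joined["stratum"]
        groups, labels = [], []
        for g, sub in joined.groupby(grp_of):
            groups.append((sub["os_time"].to_numpy(), sub["os_event"].to_numpy()))
            labels.append(str(g))
        lr = logrank_test(groups, labels=labels)

        # ---- outputs
        scores_df = pd.DataFrame(
            {"sample_id": scores.scores.index, "score": scores.scores.values}
        )
        scores_df["class"] = scores_df["sample_id"].map(calls.labels).fillna("ST")
        paths = {
            "scores": out / "scores.tsv",
            "strata": out / "strata.tsv",
            "crosstab": out / "crosstab.tsv",
            "logrank": out / "logrank.json",
            "threshold": out / "threshold.json",
            "compare": out / "compare.json",
        }
        scores_df.to_csv(paths["scores"], sep="\t", index=False)
        strata.table.to_csv(paths["strata"], sep="\t")
        ct.counts.to_csv(paths["crosstab"], sep="\t")
        for label, (t, e) in zip(labels, groups):
            km = km_estimate(t, e)
            pth = out / f"km_{label}.tsv"
            km.table.to_csv(pth, sep="\t", index=False)
            paths[f"km_{label}"] = pth
        with open(paths["threshold"], "w") as fh:
            json.dump(
                {
                    "tau": thr.tau, "k": thr.k, "st_mean": thr.st_mean,
                    "st_sd": thr.st_sd, "n_st": thr.n_st,
                    "dropped_genes": list(z.dropped_genes),
                    "missing_set_genes": list(scores.missing_genes),
                },
                fh, indent=2,
            )
        with open(paths["logrank"], "w") as fh:
            json.dump(
                {
                    "statistic": lr.statistic, "df": lr.df, "p_value": lr.p_value,
                    "groups": list(lr.group_labels),
                    "observed": lr.observed.tolist(),
                    "expected": lr.expected.tolist(),
                    "odds_ratio": ct.odds_ratio,
                    "n_dropped_no_followup": int(n_dropped),
                    "n_excluded_no_call": int(strata.n_excluded),
                },
                fh, indent=2,
            )
        with open(paths["compare"], "w") as fh:
            json.dump(
                {
                    "method": config.compare_method, "statistic": stat,
                    "p_value": p_cmp,
                    "n_mutant": int(len(mut_samples)),
                    "n_wild_type": int(len(wt_samples)),
                },
                fh, indent=2,
            )

    for name, pth in paths.items():
        manifest["outputs"][name] = _sha256(Path(pth))
    manifest["warnings"] = [str(w.message) for w in caught]
    manifest["timing_seconds"] = time.perf_counter() - t0
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def run_overlap(config: OverlapConfig) -> dict:
    """Run the cross-species DEG overlap chain; returns the manifest dict."""
    t0 = time.perf_counter()
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _manifest_skeleton(asdict(config))
    for name in ("table_a", "table_b", "mapping", "gmt"):
        p = getattr(config, name)
        if p is not None:
            manifest["inputs"][name] = _sha256(Path(p))

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        spec = FilterSpec(
            fold_change=config.fold_change, p_adj=config.p_adj,
            direction=config.direction,
        )
        table_a = read_deg_table(config.table_a)
        table_b = read_deg_table(config.table_b)
        genes_a = filter_degs(table_a, spec)
        genes_b = filter_degs(table_b, spec)

        unmapped: list[str] = []
        if config.map_a and genes_a:
            mapping = None
            if config.mapping is not None:
                mp = pd.read_csv(config.mapping, sep="\t", header=None)
                mapping = dict(zip(mp[0].astype(str), mp[1].astype(str)))
            genes_a, unmapped = map_orthologs(genes_a, mapping)

        ov = overlap(genes_a, genes_b)
        paths = {"venn": out / "venn.json"}
        with open(paths["venn"], "w") as fh:
            json.dump(
                {
                    "n_a": ov.n_a, "n_b": ov.n_b,
                    "n_intersection": ov.n_intersection, "n_union": ov.n_union,
                    "n_a_only": ov.n_a_only, "n_b_only": ov.n_b_only,
                    "n_unmapped": len(unmapped),
                },
                fh, indent=2,
            )
        pd.Series(sorted(ov.intersection), name="gene").to_csv(
            out / "overlap_genes.txt", index=False, header=False
        )
        paths["overlap_genes"] = out / "overlap_genes.txt"

        if config.gmt is not None:
            hits = set(ov.intersection)
            universe = set(table_b.table["gene"])
            if not hits:
                warnings.warn("empty overlap; enrichment skipped")
            else:
                categories = read_gmt(config.gmt)
                enr = ora_test(hits & universe, categories, universe)
                enr.to_csv(out / "enrichment.tsv", sep="\t", index=False)
                paths["enrichment"] = out / "enrichment.tsv"

    for name, pth in paths.items():
        manifest["outputs"][name] = _sha256(Path(pth))
    manifest["warnings"] = [str(w.message) for w in caught]
    manifest["timing_seconds"] = time.perf_counter() - t0
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
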