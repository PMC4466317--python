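"""End-to-end organism analysis: digitize genes, estimate H, test normality.

The pipeline reproduces the study design of the distributional analysis:
per-gene Hurst exponents (any subset of the nine estimator modes) over a
genome, Kolmogorov-Smirnov significance levels per gene group (full gene
set, essential, nonessential) and candidate family, a Q-Q table per group
for the primary estimator mode, and an organism summary that flags whether
the essential group looks *more* normal than the full gene set.

The full gene set is ALL genes in the table regardless of essentiality
label: annotated gene sets routinely contain genes labelled neither
essential nor nonessential, so the two labelled groups are subsets of the
full set, not a partition of it.

Genes are never silently dropped: every exclusion (too short, ambiguous
bases, estimation failure) is logged and counted, and
analyzed + excluded == input rows holds for every run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .codec import (
    GeneRecord,
    GenomeSequence,
    MIN_GENE_LENGTH,
    digitize,
    extract_gene_sequence,
    read_fasta,
    read_gene_table,
)
from .exceptions import (
    AmbiguousBaseError,
    DegenerateSampleError,
    DomainError,
    EmptyAnalysisError,
    InputError,
    RepliconMismatchError,
)
from .hurst import METHODS, EstimatorConfig, estimate_all
from .normality import (
    FAMILIES,
    NormalityReport,
    group_normality,
    ks_test_family,
    qq_normal,
)

logger = logging.getLogger(__name__)

#: |delta p| below which nonessential-vs-full is called "unchanged"
UNCHANGED_BAND = 0.01
#: delta p above which the change is a full "increase" (else "slight_increase")
INCREASE_BAND = 0.10

#: minimum group size for a K-S report
MIN_GROUP_SIZE = 8


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one organism run."""

    fasta_path: str
    gene_table_path: str
    output_dir: str | None = None
    methods: tuple[str, ...] = METHODS
    primary_method: str = "spec_smoothed"
    families: tuple[str, ...] = FAMILIES
    estimator_configs: Mapping[str, EstimatorConfig] = field(default_factory=dict)
    min_gene_length: int = MIN_GENE_LENGTH
    ambiguity_policy: str = "skip-gene"  # or "strict"
    poisson_scale: float = 100.0
    unchanged_band: float = UNCHANGED_BAND
    increase_band: float = INCREASE_BAND
    seed: int = 0
    organism: str = "organism"

    def __post_init__(self):
        if not self.methods:
            raise InputError("methods must be non-empty")
        for m in self.methods:
            if m not in METHODS:
                raise InputError(f"unknown method {m!r}")
        if self.primary_method not in self.methods:
            raise InputError(
                f"primary_method {self.primary_method!r} not in methods {self.methods}"
            )
        if not self.families:
            raise InputError("families must be non-empty")
        if self.ambiguity_policy not in ("skip-gene", "strict"):
            raise InputError("ambiguity_policy must be 'skip-gene' or 'strict'")


@dataclass(frozen=True)
class OrganismSummary:
    """Qualitative per-organism outcome for the primary estimator mode."""

    organism: str
    primary_method: str
    n_genes_input: int
    n_genes_analyzed: int
    n_genes_excluded: int
    excluded_reasons: Mapping[str, int]
    group_counts: Mapping[str, int]
    significance: Mapping[str, Mapping[str, float]]  # group -> family -> p
    essential_more_normal_than_full: bool | None
    nonessential_vs_full: str | None  # unchanged/slight_increase/increase/decrease


@dataclass(frozen=True)
class OrganismResults:
    """Everything one run computed, before/independent of file output."""

    summary: OrganismSummary
    per_gene: pd.DataFrame          # gene_id, essentiality, method, H, n_points, r_squared
    reports: tuple[NormalityReport, ...]
    qq_tables: Mapping[str, pd.DataFrame]
    exclusions: pd.DataFrame        # gene_id, reason


def classify_change(delta_p: float, unchanged_band: float = UNCHANGED_BAND,
                    increase_band: float = INCREASE_BAND) -> str:
    """Qualitative label for p(nonessential) - p(full_gene_set)."""
    if abs(delta_p) <= unchanged_band:
        return "unchanged"
    if delta_p < 0:
        return "decrease"
    return "slight_increase" if delta_p <= increase_band else "increase"


def analyze_organism(
    genomes: Sequence[GenomeSequence],
    genes: Sequence[GeneRecord],
    config: RunConfig,
) -> OrganismResults:
    """In-memory core of :func:`run_organism`.

    Multi-replicon organisms are handled by resolving each gene against its
    own replicon and pooling all genes into one organism-level set.
    """
    by_replicon = {g.replicon_id: g for g in genomes}
    if len(by_replicon) != len(genomes):
        raise InputError("duplicate replicon ids in genome input")
    if not genes:
        raise EmptyAnalysisError("gene table is empty")

    rows: list[dict] = []
    exclusions: list[dict] = []
    analyzed_genes: list[tuple[GeneRecord, dict]] = []
    for gene in genes:
        genome = by_replicon.get(gene.replicon_id)
        if genome is None:
            raise RepliconMismatchError(
                f"gene {gene.gene_id} references unknown replicon "
                f"{gene.replicon_id!r} (available: {sorted(by_replicon)})"
            )
        seq = extract_gene_sequence(genome, gene)
        if len(seq) < config.min_gene_length:
            logger.warning(
                "excluding gene %s: length %d < %d",
                gene.gene_id, len(seq), config.min_gene_length,
            )
            exclusions.append({"gene_id": gene.gene_id, "reason": "too_short"})
            continue
        try:
            dig = digitize(seq, source_id=gene.gene_id)
        except AmbiguousBaseError as exc:
            if config.ambiguity_policy == "strict":
                raise
            logger.warning("excluding gene %s: %s", gene.gene_id, exc)
            exclusions.append({"gene_id": gene.gene_id, "reason": "ambiguous_base"})
            continue
        try:
            estimates, failures = estimate_all(
                dig, configs=config.estimator_configs, methods=config.methods
            )
        except Exception as exc:
            logger.warning("excluding gene %s: estimation failed (%s)", gene.gene_id, exc)
            exclusions.append({"gene_id": gene.gene_id, "reason": "estimation_failed"})
            continue
        for method, msg in failures.items():
            logger.warning("gene %s, method %s failed: %s", gene.gene_id, method, msg)
        for method, res in estimates.items():
            rows.append(
                {
                    "gene_id": gene.gene_id,
                    "essentiality": gene.essentiality,
                    "method": method,
                    "H": res.H,
                    "n_points": res.n_points,
                    "r_squared": np.nan if res.rsquared is None else res.rsquared,
                }
            )
        analyzed_genes.append((gene, estimates))

    if not analyzed_genes:
        raise EmptyAnalysisError("no genes survived the filters")
    per_gene = pd.DataFrame(
        rows, columns=["gene_id", "essentiality", "method", "H", "n_points", "r_squared"]
    )

    reports: list[NormalityReport] = []
    significance: dict[str, dict[str, float]] = {}
    qq_tables: dict[str, pd.DataFrame] = {}
    group_counts: dict[str, int] = {}

    for method in config.methods:
        sub = per_gene[per_gene.method == method]
        groups: dict[str, np.ndarray] = {"full_gene_set": sub.H.to_numpy()}
        for label in ("essential", "nonessential"):
            vals = sub[sub.essentiality == label].H.to_numpy()
            if method == config.primary_method:
                group_counts[label] = int(vals.size)
            if vals.size == 0:
                logger.warning("group %r empty for method %s; omitted", label, method)
                continue
            if vals.size < MIN_GROUP_SIZE:
                logger.warning(
                    "group %r has only %d genes for method %s; omitted",
                    label, vals.size, method,
                )
                continue
            groups[label] = vals
        method_reports = []
        for group, vals in groups.items():
            results = []
            for family in config.families:
                try:
                    results.append(
                        ks_test_family(vals, family, poisson_scale=config.poisson_scale)
                    )
                except (DomainError, DegenerateSampleError) as exc:
                    # e.g. a negative estimate makes poisson/exponential
                    # inapplicable for the group: drop the family, keep the run
                    logger.warning(
                        "group %r, method %s: family %r not applicable (%s)",
                        group, method, family, exc,
                    )
            if results:
                method_reports.append(
                    NormalityReport(
                        group=group, method=method, results=tuple(results),
                        sample_mean=float(np.mean(vals)),
                        sample_sd=float(np.std(vals, ddof=1)),
                        n=int(vals.size),
                    )
                )
        reports.extend(method_reports)
        if method == config.primary_method:
            group_counts["full_gene_set"] = int(groups["full_gene_set"].size)
            for rep in method_reports:
                significance[rep.group] = {r.family: r.p for r in rep.results}
            for group, vals in groups.items():
                qq = qq_normal(vals)
                qq_tables[group] = pd.DataFrame(
                    {
                        "rank": np.arange(1, vals.size + 1),
                        "ordered_value": qq.ordered_sample,
                        "plotting_position": qq.plotting_positions,
                        "theoretical_quantile": qq.theoretical_quantiles,
                    }
                )

    ess_flag: bool | None = None
    non_class: str | None = None
    if "normal" in config.families:
        p_full = significance.get("full_gene_set", {}).get("normal")
        p_ess = significance.get("essential", {}).get("normal")
        p_non = significance.get("nonessential", {}).get("normal")
        if p_full is not None and p_ess is not None:
            ess_flag = bool(p_ess > p_full)
        if p_full is not None and p_non is not None:
            non_class = classify_change(
                p_non - p_full, config.unchanged_band, config.increase_band
            )

    excl_df = pd.DataFrame(exclusions, columns=["gene_id", "reason"])
    reason_counts = excl_df.reason.value_counts().to_dict() if len(excl_df) else {}
    summary = OrganismSummary(
        organism=config.organism,
        primary_method=config.primary_method,
        n_genes_input=len(genes),
        n_genes_analyzed=len(analyzed_genes),
        n_genes_excluded=len(exclusions),
        excluded_reasons=reason_counts,
        group_counts=group_counts,
        significance=significance,
        essential_more_normal_than_full=ess_flag,
        nonessential_vs_full=non_class,
    )
    return OrganismResults(
        summary=summary,
        per_gene=per_gene,
        reports=tuple(reports),
        qq_tables=qq_tables,
        exclusions=excl_df,
    )


def _write_outputs(results: OrganismResults, config: RunConfig) -> None:
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    results.per_gene.to_csv(
        outdir / "hurst_per_gene.tsv", sep="\t", index=False, float_format="%.6f"
    )
    report_rows = [
        {
            "group": rep.group,
            "method": rep.method,
            "family": r.family,
            "n": r.n,
            "D": r.D,
            "p": r.p,
            "accepted": r.accepted,
        }
        for rep in results.reports
        for r in rep.results
    ]
    pd.DataFrame(report_rows).to_csv(
        outdir / "normality_report.tsv", sep="\t", index=False, float_format="%.6f"
    )
    for group, qq in results.qq_tables.items():
        qq.to_csv(
            outdir / f"qq_{group}.tsv", sep="\t", index=False, float_format="%.6f"
        )
    if len(results.exclusions):
        results.exclusions.to_csv(outdir / "excluded_genes.tsv", sep="\t", index=False)
    s = results.summary
    lines = [
        f"organism: {s.organism}",
        f"primary_method: {s.primary_method}",
        f"genes_input: {s.n_genes_input}",
        f"genes_analyzed: {s.n_genes_analyzed}",
        f"genes_excluded: {s.n_genes_excluded}",
        f"excluded_reasons: {dict(sorted(s.excluded_reasons.items()))}",
        f"group_counts: {dict(sorted(s.group_counts.items()))}",
    ]
    for group in ("full_gene_set", "essential", "nonessential"):
        for family, p in s.significance.get(group, {}).items():
            lines.append(f"p[{group}][{family}]: {p:.6f}")
    lines.append(f"essential_more_normal_than_full: {s.essential_more_normal_than_full}")
    lines.append(f"nonessential_vs_full: {s.nonessential_vs_full}")
    (outdir / "summary.txt").write_text("\n".join(lines) + "\n")
    prov = [
        f"genehurst version: {__version__}",
        f"seed: {config.seed}",
        "config:",
    ]
    cfg = asdict(config)
    cfg["estimator_configs"] = {
        m: asdict(c) for m, c in config.estimator_configs.items()
    }
    for key in sorted(cfg):
        prov.append(f"  {key}: {cfg[key]}")
    (outdir / "provenance.txt").write_text("\n".join(prov) + "\n")


def run_organism(config: RunConfig) -> OrganismResults:
    """File-based end-to-end run: read inputs, analyze, write result files."""
    genomes = read_fasta(config.fasta_path)
    genes = read_gene_table(config.gene_table_path)
    results = analyze_organism(genomes, genes, config)
    if config.output_dir is not None:
        _write_outputs(results, config)
    return results


def compare_methods(
    per_gene_h: pd.DataFrame,
    essential_gene_ids: Sequence[str] | None = None,
    min_coverage: float = 0.5,
) -> pd.DataFrame:
    """Rank estimator modes by essential-group normal-family significance.

    ``per_gene_h`` must have columns gene_id, method, H and either an
    ``essentiality`` column or an explicit ``essential_gene_ids`` list.
    Methods present for fewer than ``min_coverage`` of the genes are
    dropped with a warning.  Returns a DataFrame ranked by descending p
    (ties broken by method name).
    """
    df = per_gene_h.copy()
    if essential_gene_ids is not None:
        df["essentiality"] = np.where(
            df.gene_id.isin(set(essential_gene_ids)), "essential", "nonessential"
        )
    if "essentiality" not in df.columns:
        raise InputError("need an essentiality column or essential_gene_ids")
    methods = sorted(df.method.unique())
    if len(methods) < 2:
        raise InputError("need at least 2 methods to rank")
    n_genes = df.gene_id.nunique()
    rows = []
    for method in methods:
        sub = df[df.method == method]
        if sub.gene_id.nunique() < min_coverage * n_genes:
            logger.warning("method %s covers < %.0f%% of genes; dropped",
                           method, 100 * min_coverage)
            continue
        ess = sub[sub.essentiality == "essential"].H.to_numpy()
        if ess.size < MIN_GROUP_SIZE:
            logger.warning("method %s: essential group too small; dropped", method)
            continue
        reports, _ = group_normality(
            {"essential": ess}, families=("normal",), method=method, compare=False
        )
        rows.append({"method": method, "p_essential_normal": reports[0].result_for("normal").p})
    ranking = pd.DataFrame(rows).sort_values(
        ["p_essential_normal", "method"], ascending=[False, True]
    ).reset_index(drop=True)
    ranking.insert(0, "rank", np.arange(1, len(ranking) + 1))
    return ranking
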