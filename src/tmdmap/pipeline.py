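"""End-to-end orchestration: mapping, grouping, scoring and comparison.

Glue between the format readers, the peptide-to-helix mapper, GRAVY
scoring and the comparison statistics.  The command-line interface and the
reproduction script are thin layers over these functions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .hydropathy import gravy
from .method_stats import (
    DEFAULT_BIN_LABELS,
    BinTTest,
    ChiSquareResult,
    EnrichmentRow,
    MethodSummary,
    ReproducibilityResult,
    TMDBinHistogram,
    binomial_enrichment,
    chi_square_gof,
    histogram_from_counts,
    per_bin_ttest,
    replicate_reproducibility,
    summarize_method,
    tmd_histogram,
)
from .proteome_io import DetectedPeptide, ProteinRecord, TMDInterval
from .tmd_mapping import (
    MappingResult,
    ProteinGroup,
    ProteomeIndex,
    count_peptide_tmd_pairs,
    count_unique_tmds,
    group_proteins,
    map_peptides,
)


def tmd_counts_by_accession(
    proteome: Sequence[ProteinRecord], tmds: Sequence[TMDInterval]
) -> dict[str, int]:
    counts = {p.accession: 0 for p in proteome}
    for iv in tmds:
        if iv.protein_accession in counts:
            counts[iv.protein_accession] += 1
    return counts


@dataclass
class MethodAnalysis:
    """Everything computed for one method: the pooled (all-replicate)
    mapping, the per-replicate group sets and histogram fractions, and the
    aggregate summary."""

    method: str
    mapping: MappingResult
    groups: list[ProteinGroup]
    unique_tmd_count: int
    peptide_tmd_pairs: int
    replicate_group_sets: list[frozenset[str]]
    replicate_fractions: dict[str, list[float]]
    summary: MethodSummary


def analyze_method(
    method: str,
    tables: Mapping[str, Sequence[DetectedPeptide]],
    proteome: Sequence[ProteinRecord],
    tmds: Sequence[TMDInterval],
    *,
    gravy_by_accession: Mapping[str, float],
    tmd_count_by_accession: Mapping[str, int],
    index: ProteomeIndex | None = None,
    labels: Sequence[str] = DEFAULT_BIN_LABELS,
    min_partial_overlap: int = 2,
    il_equivalent: bool = False,
    unique_only: bool = False,
) -> MethodAnalysis:
    """Analyse one method given its per-replicate detected-peptide tables.

    Headline quantities (histogram, unique helices, GRAVY fraction) use
    the peptides pooled over replicates; reproducibility and the per-bin
    replicate fractions come from mapping each replicate separately.
    """
    if index is None:
        index = ProteomeIndex(proteome, il_equivalent=il_equivalent)
    opts = dict(
        min_partial_overlap=min_partial_overlap,
        il_equivalent=il_equivalent,
        unique_only=unique_only,
        index=index,
    )
    pooled = [p for reps in tables.values() for p in reps]
    mapping = map_peptides(pooled, proteome, tmds, **opts)
    groups = group_proteins(mapping.assignments) if mapping.assignments else []
    unique = count_unique_tmds(mapping.hits)
    pairs = count_peptide_tmd_pairs(mapping.hits)

    rep_sets: list[frozenset[str]] = []
    rep_fracs: dict[str, list[float]] = {label: [] for label in labels}
    for rep in sorted(tables):
        rep_map = map_peptides(tables[rep], proteome, tmds, **opts)
        rep_groups = (
            group_proteins(rep_map.assignments) if rep_map.assignments else []
        )
        rep_sets.append(frozenset(g.group_id for g in rep_groups))
        hist = tmd_histogram(rep_groups, tmd_count_by_accession, labels)
        for label, count in zip(hist.labels, hist.counts):
            rep_fracs[label].append(
                count / hist.total if hist.total else 0.0
            )

    summary = summarize_method(
        method,
        groups,
        tmd_count_by_accession,
        unique,
        gravy_by_accession,
        rep_sets,
        labels,
    )
    return MethodAnalysis(
        method, mapping, groups, unique, pairs, rep_sets, rep_fracs, summary
    )


def replicate_bin_fractions(
    tables: Mapping[str, Sequence[DetectedPeptide]],
    proteome: Sequence[ProteinRecord],
    tmds: Sequence[TMDInterval],
    *,
    tmd_count_by_accession: Mapping[str, int],
    index: ProteomeIndex | None = None,
    labels: Sequence[str] = DEFAULT_BIN_LABELS,
) -> dict[str, list[float]]:
    """Per-bin TMP-group fractions, one value per replicate.

    A lean path (no pooled mapping, no GRAVY) for replicate-level
    statistics such as the t-test null calibration.
    """
    if index is None:
        index = ProteomeIndex(proteome)
    fractions: dict[str, list[float]] = {label: [] for label in labels}
    for rep in sorted(tables):
        rep_map = map_peptides(tables[rep], proteome, tmds, index=index)
        rep_groups = (
            group_proteins(rep_map.assignments) if rep_map.assignments else []
        )
        hist = tmd_histogram(rep_groups, tmd_count_by_accession, labels)
        for label, count in zip(hist.labels, hist.counts):
            fractions[label].append(count / hist.total if hist.total else 0.0)
    return fractions


def null_ttest_false_positive_rate(
    n_sims: int,
    base_seed: int,
    config: "SimulationConfig | None" = None,
    alpha: float = 0.05,
) -> tuple[float, int]:
    """Empirical false-positive rate of the per-bin t-test under the null.

    Both pseudo-methods share one detection model (identical chemistry and
    probabilities), so every bin-level rejection is a false positive.
    Returns ``(rate, n_tests)`` over all non-degenerate bins of ``n_sims``
    simulated experiments seeded ``base_seed .. base_seed + n_sims - 1``.

    The null design uses a sparse detection probability (0.04) rather than
    the default study conditions: at the default 0.30 nearly every protein
    is identified in every replicate, the replicate fractions carry no
    sampling variance, and the calibration experiment would be degenerate.
    Sparse detection makes each replicate a genuine random subsample.
    """
    from dataclasses import replace

    from .synthetic_data import MethodModel, SimulationConfig, run_simulation

    if config is None:
        config = SimulationConfig(n_proteins=120)
    equal_methods = (
        MethodModel("null-A", "UR-TLC", 0.04, 0.04),
        MethodModel("null-B", "UR-TLC", 0.04, 0.04),
    )
    n_false = 0
    n_tests = 0
    for k in range(n_sims):
        cfg = replace(config, methods=equal_methods, seed=base_seed + k)
        proteome, truth, tables = run_simulation(cfg)
        index = ProteomeIndex(proteome)
        tmd_counts = tmd_counts_by_accession(proteome, truth)
        fracs = {
            name: replicate_bin_fractions(
                tables[name], proteome, truth,
                tmd_count_by_accession=tmd_counts, index=index,
            )
            for name in ("null-A", "null-B")
        }
        for t in per_bin_ttest(fracs["null-A"], fracs["null-B"]):
            if t.degenerate:
                continue
            n_tests += 1
            if t.pvalue < alpha:
                n_false += 1
    return (n_false / n_tests if n_tests else float("nan"), n_tests)


@dataclass
class ComparisonResult:
    """Cross-method comparison bundle."""

    analyses: dict[str, MethodAnalysis]
    proteome_histogram: TMDBinHistogram
    proteome_tmp_fraction: float
    chi_square: dict[str, ChiSquareResult]
    ttests: list[BinTTest]
    enrichment: list[EnrichmentRow]


def compare_methods(
    tables_by_method: Mapping[str, Mapping[str, Sequence[DetectedPeptide]]],
    proteome: Sequence[ProteinRecord],
    tmds: Sequence[TMDInterval],
    *,
    labels: Sequence[str] = DEFAULT_BIN_LABELS,
    min_partial_overlap: int = 2,
    il_equivalent: bool = False,
    unique_only: bool = False,
    categories_by_accession: Mapping[str, str] | None = None,
) -> ComparisonResult:
    """Run the full comparison across two or more methods.

    Each method's TMD-count histogram is tested (chi-square goodness of
    fit) against the proteome-wide distribution; the per-bin t-test and
    the optional category enrichment contrast the first two methods in
    sorted order.
    """
    if len(tables_by_method) < 2:
        raise ValueError("at least two method bundles required")
    index = ProteomeIndex(proteome, il_equivalent=il_equivalent)
    gravy_by_acc = {p.accession: gravy(p.sequence) for p in proteome}
    tmd_counts = tmd_counts_by_accession(proteome, tmds)

    analyses = {
        method: analyze_method(
            method,
            tables_by_method[method],
            proteome,
            tmds,
            gravy_by_accession=gravy_by_acc,
            tmd_count_by_accession=tmd_counts,
            index=index,
            labels=labels,
            min_partial_overlap=min_partial_overlap,
            il_equivalent=il_equivalent,
            unique_only=unique_only,
        )
        for method in sorted(tables_by_method)
    }

    proteome_hist = histogram_from_counts(tmd_counts.values(), labels)
    n_tmp = proteome_hist.total
    proteome_tmp_fraction = n_tmp / len(proteome) if proteome else float("nan")

    chi = {}
    for method, analysis in analyses.items():
        if analysis.summary.histogram.total > 0:
            chi[method] = chi_square_gof(
                analysis.summary.histogram, proteome_hist
            )

    names = sorted(analyses)
    a, b = analyses[names[0]], analyses[names[1]]
    ttests = per_bin_ttest(a.replicate_fractions, b.replicate_fractions)

    enrichment: list[EnrichmentRow] = []
    if categories_by_accession:
        counts = {}
        totals = {}
        for name in names[:2]:
            groups = analyses[name].groups
            cat_counts: dict[str, int] = {}
            for g in groups:
                cat = categories_by_accession.get(g.group_id)
                if cat:
                    cat_counts[cat] = cat_counts.get(cat, 0) + 1
            counts[name] = cat_counts
            totals[name] = len(groups)
        if totals[names[0]] and totals[names[1]]:
            enrichment = binomial_enrichment(
                counts[names[0]], totals[names[0]],
                counts[names[1]], totals[names[1]],
            )

    return ComparisonResult(
        analyses,
        proteome_hist,
        proteome_tmp_fraction,
        chi,
        ttests,
        enrichment,
    )
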