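"""Comparison analytics for the two solubilization/cleavage methods.

Implements the statistics used to contrast the urea (UR-TLC) and formic
acid / CNBr (FA-CTLC) workflows: the TMD-count histogram of identified
transmembrane-protein groups, a Pearson chi-square goodness-of-fit of that
histogram against the proteome-wide TMD distribution, replicate
reproducibility (intersection over union of the per-replicate group sets,
with the pairwise Jaccard values and Venn region counts), per-bin
two-sample t-tests across replicates, and a per-category exact binomial
enrichment screen with Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .tmd_mapping import ProteinGroup

log = logging.getLogger(__name__)

#: Default histogram bins: TMD counts 1..10 plus an open ">10" bin.
DEFAULT_BIN_LABELS: tuple[str, ...] = tuple(str(i) for i in range(1, 11)) + (">10",)


@dataclass(frozen=True)
class TMDBinHistogram:
    """Histogram of protein-group counts over TMD-count bins.

    Covers transmembrane groups only (>= 1 TMD); groups without any TMD
    are reported separately in ``n_zero_tmd``.  ``fractions`` are of the
    transmembrane total and sum to 1 when that total is positive.
    """

    labels: tuple[str, ...]
    counts: tuple[int, ...]
    n_zero_tmd: int = 0

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.counts):
            raise ValueError("labels and counts must align")
        if any(c < 0 for c in self.counts):
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(sum(self.counts))

    @property
    def fractions(self) -> tuple[float, ...]:
        total = self.total
        if total == 0:
            return tuple(float("nan") for _ in self.counts)
        return tuple(c / total for c in self.counts)


def bin_label_for(count: int, labels: Sequence[str] = DEFAULT_BIN_LABELS) -> str | None:
    """Bin label for a TMD count, or None for count 0."""
    if count <= 0:
        return None
    for label in labels:
        if label.startswith(">"):
            if count > int(label[1:]):
                return label
        elif count == int(label):
            return label
    return labels[-1]


def group_tmd_count(
    group: ProteinGroup,
    tmd_count_by_accession: Mapping[str, int],
    how: str = "max",
) -> int:
    """TMD count of a protein group: the max (default, conservative toward
    transmembrane calls) or mean over member proteins."""
    counts = [tmd_count_by_accession.get(a, 0) for a in group.member_accessions]
    if how == "max":
        return max(counts)
    if how == "mean":
        return int(round(float(np.mean(counts))))
    raise ValueError(f"unknown aggregation {how!r}")


def tmd_histogram(
    groups: Iterable[ProteinGroup],
    tmd_count_by_accession: Mapping[str, int],
    labels: Sequence[str] = DEFAULT_BIN_LABELS,
    how: str = "max",
) -> TMDBinHistogram:
    """Histogram the TMD counts of protein groups over the given bins."""
    counts = dict.fromkeys(labels, 0)
    n_zero = 0
    for g in groups:
        n = group_tmd_count(g, tmd_count_by_accession, how)
        label = bin_label_for(n, labels)
        if label is None:
            n_zero += 1
        else:
            counts[label] += 1
    hist = TMDBinHistogram(tuple(labels), tuple(counts[l] for l in labels), n_zero)
    if hist.total == 0:
        log.warning("no transmembrane groups: histogram fractions undefined")
    return hist


def histogram_from_counts(
    tmd_counts: Iterable[int], labels: Sequence[str] = DEFAULT_BIN_LABELS
) -> TMDBinHistogram:
    """Histogram raw per-protein TMD counts (e.g. the whole proteome)."""
    counts = dict.fromkeys(labels, 0)
    n_zero = 0
    for n in tmd_counts:
        label = bin_label_for(n, labels)
        if label is None:
            n_zero += 1
        else:
            counts[label] += 1
    return TMDBinHistogram(tuple(labels), tuple(counts[l] for l in labels), n_zero)


# ---------------------------------------------------------------------------
# Chi-square goodness of fit
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    pvalue: float
    dof: int
    merged_labels: tuple[tuple[str, ...], ...]
    merge_log: tuple[str, ...]


def chi_square_gof(
    observed: TMDBinHistogram,
    expected: TMDBinHistogram,
    min_expected: float = 5.0,
) -> ChiSquareResult:
    """Pearson goodness-of-fit of observed counts against the expected
    histogram's proportions.

    Bins whose expected count (expected fraction x observed total) falls
    below ``min_expected`` are merged right-to-left into their left
    neighbour, with a log of the merges.  Degrees of freedom are the
    number of compared bins minus 1.
    """
    if observed.labels != expected.labels:
        raise ValueError("observed and expected histograms must share bins")
    n = observed.total
    if n == 0:
        raise ValueError("all-zero observed histogram")
    if expected.total == 0:
        raise ValueError("all-zero expected histogram")

    merged: list[tuple[list[str], float, float]] = []  # labels, obs, exp
    for label, obs_c, exp_f in zip(
        observed.labels, observed.counts, expected.fractions
    ):
        merged.append(([label], float(obs_c), exp_f * n))
    merge_log: list[str] = []
    i = len(merged) - 1
    while i >= 0 and len(merged) > 1:
        labels_i, obs_i, exp_i = merged[i]
        if exp_i < min_expected:
            j = i - 1 if i > 0 else i + 1
            labels_j, obs_j, exp_j = merged[j]
            merge_log.append(
                f"merged bin(s) {'+'.join(labels_i)} "
                f"(expected {exp_i:.2f} < {min_expected:g}) into "
                f"{'+'.join(labels_j)}"
            )
            keep = min(i, j)
            merged[keep] = (
                (labels_j + labels_i) if j < i else (labels_i + labels_j),
                obs_i + obs_j,
                exp_i + exp_j,
            )
            del merged[max(i, j)]
            i = min(i, len(merged) - 1)
        else:
            i -= 1

    obs = np.array([m[1] for m in merged])
    exp = np.array([m[2] for m in merged])
    if np.any(exp <= 0):
        raise ValueError("expected proportion is zero in a compared bin")
    # rescale guards against drift when zero-expectation bins were dropped
    exp = exp * obs.sum() / exp.sum()
    statistic, pvalue = stats.chisquare(obs, exp)
    return ChiSquareResult(
        float(statistic),
        float(pvalue),
        len(merged) - 1,
        tuple(tuple(m[0]) for m in merged),
        tuple(merge_log),
    )


# ---------------------------------------------------------------------------
# Replicate reproducibility
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReproducibilityResult:
    percentage: float  # |intersection of all| / |union of all| * 100
    n_common: int
    n_union: int
    pairwise_jaccard: tuple[tuple[int, int, float], ...]
    venn_counts: tuple[tuple[tuple[int, ...], int], ...]


def replicate_reproducibility(
    replicate_sets: Sequence[set[str] | frozenset[str]],
) -> ReproducibilityResult:
    """Reproducibility across replicate identification sets.

    The headline percentage is |intersection of all sets| / |union of all
    sets| x 100.  Pairwise Jaccard indices and the Venn region counts
    (elements present in exactly each subset of replicates) are also
    returned so alternative definitions can be recomputed.
    """
    if len(replicate_sets) < 2:
        raise ValueError("at least two replicate sets required")
    sets = [frozenset(s) for s in replicate_sets]
    union = frozenset().union(*sets)
    if not union:
        raise ValueError("empty union of replicate sets")
    common = sets[0]
    for s in sets[1:]:
        common &= s
    pairwise = []
    for i, j in itertools.combinations(range(len(sets)), 2):
        inter = len(sets[i] & sets[j])
        uni = len(sets[i] | sets[j])
        pairwise.append((i, j, inter / uni if uni else float("nan")))
    venn: dict[tuple[int, ...], int] = {}
    for element in union:
        membership = tuple(i for i, s in enumerate(sets) if element in s)
        venn[membership] = venn.get(membership, 0) + 1
    return ReproducibilityResult(
        percentage=100.0 * len(common) / len(union),
        n_common=len(common),
        n_union=len(union),
        pairwise_jaccard=tuple(pairwise),
        venn_counts=tuple(sorted(venn.items())),
    )


# ---------------------------------------------------------------------------
# Per-bin t-tests
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BinTTest:
    label: str
    pvalue: float
    stars: str
    degenerate: bool
    mean_a: float
    mean_b: float


def _stars(p: float) -> str:
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return ""


def per_bin_ttest(
    fractions_a: Mapping[str, Sequence[float]],
    fractions_b: Mapping[str, Sequence[float]],
    equal_var: bool = True,
) -> list[BinTTest]:
    """Two-sided two-sample t-test per histogram bin on per-replicate
    fractions (classical equal-variance Student by default; Welch when
    ``equal_var`` is false).

    Bins with zero variance in both groups are degenerate: p = 1 for equal
    means, p = 0 (flagged) for unequal means.
    """
    if set(fractions_a) != set(fractions_b):
        raise ValueError("both methods must report the same bins")
    results = []
    for label in fractions_a:
        a = np.asarray(fractions_a[label], dtype=float)
        b = np.asarray(fractions_b[label], dtype=float)
        if len(a) < 2 or len(b) < 2:
            raise ValueError(f"bin {label!r}: >= 2 replicates required")
        if np.var(a) == 0.0 and np.var(b) == 0.0:
            if np.isclose(a.mean(), b.mean()):
                results.append(BinTTest(label, 1.0, "", True, a.mean(), b.mean()))
            else:
                log.warning(
                    "bin %s: zero variance with unequal means (degenerate)",
                    label,
                )
                results.append(BinTTest(label, 0.0, "**", True, a.mean(), b.mean()))
            continue
        _, p = stats.ttest_ind(a, b, equal_var=equal_var)
        p = float(p)
        results.append(BinTTest(label, p, _stars(p), False, a.mean(), b.mean()))
    return results


# ---------------------------------------------------------------------------
# Binomial enrichment
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EnrichmentRow:
    category: str
    count_a: int
    count_b: int
    proportion_a: float
    proportion_b: float
    direction: str  # 'A' if the category is relatively enriched in A
    pvalue: float
    qvalue: float


def binomial_enrichment(
    category_counts_a: Mapping[str, int],
    total_a: int,
    category_counts_b: Mapping[str, int],
    total_b: int,
) -> list[EnrichmentRow]:
    """Per-category exact two-sided binomial test of the method-A count
    against the pooled null proportion (count_A + count_B) / (nA + nB),
    with Benjamini-Hochberg q-values across categories.

    Categories absent from both methods are skipped.
    """
    if total_a <= 0 or total_b <= 0:
        raise ValueError("totals must be positive")
    categories = sorted(set(category_counts_a) | set(category_counts_b))
    rows: list[tuple[str, int, int, float]] = []
    for cat in categories:
        ca = int(category_counts_a.get(cat, 0))
        cb = int(category_counts_b.get(cat, 0))
        if ca == 0 and cb == 0:
            continue
        if ca > total_a or cb > total_b:
            raise ValueError(f"category {cat!r}: count exceeds total")
        p0 = (ca + cb) / (total_a + total_b)
        pvalue = stats.binomtest(ca, total_a, p0, alternative="two-sided").pvalue
        rows.append((cat, ca, cb, float(pvalue)))
    if not rows:
        return []
    qvalues = multipletests([r[3] for r in rows], method="fdr_bh")[1]
    out = []
    for (cat, ca, cb, p), q in zip(rows, qvalues):
        pa, pb = ca / total_a, cb / total_b
        out.append(
            EnrichmentRow(
                cat, ca, cb, pa, pb,
                "A" if pa >= pb else "B",
                p, float(q),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Per-method summary
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MethodSummary:
    """Aggregate description of one method's identifications."""

    method: str
    n_protein_groups: int
    n_tmp_groups: int
    tmp_fraction: float
    histogram: TMDBinHistogram
    unique_tmd_count: int
    gravy_positive_fraction: float
    reproducibility_pct: float


def summarize_method(
    method: str,
    groups: Sequence[ProteinGroup],
    tmd_count_by_accession: Mapping[str, int],
    unique_tmd_count: int,
    gravy_by_accession: Mapping[str, float],
    replicate_group_sets: Sequence[set[str] | frozenset[str]],
    labels: Sequence[str] = DEFAULT_BIN_LABELS,
) -> MethodSummary:
    """Assemble the per-method summary from mapping and scoring outputs.

    The group GRAVY value is that of the group representative (the
    smallest member accession).
    """
    hist = tmd_histogram(groups, tmd_count_by_accession, labels)
    n_groups = len(groups)
    gravy_pos = sum(
        1 for g in groups if gravy_by_accession.get(g.group_id, 0.0) > 0.0
    )
    repro = replicate_reproducibility(replicate_group_sets).percentage
    return MethodSummary(
        method=method,
        n_protein_groups=n_groups,
        n_tmp_groups=hist.total,
        tmp_fraction=hist.total / n_groups if n_groups else float("nan"),
        histogram=hist,
        unique_tmd_count=unique_tmd_count,
        gravy_positive_fraction=gravy_pos / n_groups if n_groups else float("nan"),
        reproducibility_pct=repro,
    )
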