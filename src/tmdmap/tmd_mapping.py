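"""Peptide-to-transmembrane-domain mapping.

The core classifier takes a located peptide span and a predicted
membrane-helix span (both 1-based inclusive) and decides whether the
peptide "hits" the helix:

* ``CONTAINS`` — the peptide covers the whole helix;
* ``WITHIN``   — the peptide lies entirely inside the helix (span equality
  resolves to ``CONTAINS``);
* ``N_PARTIAL`` / ``C_PARTIAL`` — the peptide crosses exactly one helix
  boundary with an overlap of at least ``min_partial_overlap`` residues
  (default 2; a one-residue graze is not a hit).

Mapping locates every (including overlapping) occurrence of each detected
peptide in the proteome, evaluates every occurrence x helix pair, and also
merges the matched residue ranges per protein into a coverage map.
Proteins sharing an identical set of matched peptides are collapsed into
protein groups.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

from .proteome_io import DetectedPeptide, ProteinRecord, TMDInterval

log = logging.getLogger(__name__)


class HitCategory(str, Enum):
    CONTAINS = "CONTAINS"
    WITHIN = "WITHIN"
    N_PARTIAL = "N_PARTIAL"
    C_PARTIAL = "C_PARTIAL"


@dataclass(frozen=True)
class PeptideMatch:
    """One placement of a detected peptide within a protein
    (1-based inclusive coordinates)."""

    peptide_sequence: str
    protein_accession: str
    start: int
    end: int

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass(frozen=True)
class TMDHit:
    """One peptide-occurrence x membrane-helix classification."""

    match: PeptideMatch
    tmd: TMDInterval
    overlap_aa: int
    category: HitCategory


@dataclass(frozen=True)
class ProteinGroup:
    """Proteins sharing an identical set of identified peptides, reported
    as one identification.  ``group_id`` is the lexicographically smallest
    member accession."""

    group_id: str
    member_accessions: tuple[str, ...]
    peptide_set: frozenset[str]


@dataclass
class MappingResult:
    hits: list[TMDHit]
    coverage: dict[str, list[tuple[int, int]]]
    assignments: dict[str, set[str]]  # accession -> matched peptide sequences
    orphan_peptides: list[str]
    promiscuous_peptides: list[str]


def classify_hit(
    match_span: tuple[int, int],
    tmd_span: tuple[int, int],
    min_partial_overlap: int = 2,
) -> tuple[HitCategory, int] | None:
    """Classify one peptide span against one helix span.

    Returns ``(category, overlap_aa)`` or ``None`` for no hit.  Precedence
    is CONTAINS > WITHIN > partial; span equality is CONTAINS.
    """
    ps, pe = match_span
    ts, te = tmd_span
    if ps > pe or ts > te:
        raise ValueError(f"invalid span: peptide {match_span}, TMD {tmd_span}")
    overlap = min(pe, te) - max(ps, ts) + 1
    if overlap <= 0:
        return None
    if ps <= ts and pe >= te:
        return (HitCategory.CONTAINS, overlap)
    if ps >= ts and pe <= te:
        return (HitCategory.WITHIN, overlap)
    if overlap < min_partial_overlap:
        return None
    # exactly one boundary crossed
    if ps < ts:  # enters across the helix N-terminal boundary
        return (HitCategory.N_PARTIAL, overlap)
    return (HitCategory.C_PARTIAL, overlap)


_IL_TABLE = str.maketrans("L", "I")


def locate_peptide(
    peptide_sequence: str,
    protein: ProteinRecord | str,
    il_equivalent: bool = False,
) -> list[int]:
    """All (including overlapping) 1-based occurrence positions of the
    peptide in the protein sequence, ascending.  With ``il_equivalent``,
    isoleucine and leucine are interchangeable on both sides."""
    if not peptide_sequence:
        raise ValueError("peptide must be non-empty")
    text = protein.sequence if isinstance(protein, ProteinRecord) else protein
    query = peptide_sequence.upper()
    if il_equivalent:
        text = text.translate(_IL_TABLE)
        query = query.translate(_IL_TABLE)
    positions = []
    i = text.find(query)
    while i >= 0:
        positions.append(i + 1)
        i = text.find(query, i + 1)
    return positions


class ProteomeIndex:
    """Concatenated-text substring index over a proteome.

    Sequences are joined with a separator outside the amino-acid alphabet
    so a single C-level ``str.find`` scan locates a peptide across all
    proteins at once.
    """

    SEP = "#"

    def __init__(
        self, proteins: Sequence[ProteinRecord], il_equivalent: bool = False
    ) -> None:
        self.proteins = sorted(proteins, key=lambda p: p.accession)
        self.il_equivalent = il_equivalent
        chunks, offsets = [], []
        pos = 0
        for p in self.proteins:
            offsets.append(pos)
            seq = p.sequence
            if il_equivalent:
                seq = seq.translate(_IL_TABLE)
            chunks.append(seq)
            pos += len(seq) + 1
        self._text = self.SEP.join(chunks)
        self._offsets = offsets

    def find(self, peptide_sequence: str) -> list[tuple[str, int]]:
        """All occurrences as (accession, 1-based start), sorted by
        accession then position."""
        query = peptide_sequence.upper()
        if self.il_equivalent:
            query = query.translate(_IL_TABLE)
        out = []
        i = self._text.find(query)
        while i >= 0:
            k = bisect_right(self._offsets, i) - 1
            out.append((self.proteins[k].accession, i - self._offsets[k] + 1))
            i = self._text.find(query, i + 1)
        return out


def _merge_ranges(ranges: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for s, e in sorted(ranges):
        if merged and s <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def map_peptides(
    peptides: Iterable[DetectedPeptide | str],
    proteome: Sequence[ProteinRecord],
    tmds: Iterable[TMDInterval],
    *,
    min_partial_overlap: int = 2,
    il_equivalent: bool = False,
    unique_only: bool = False,
    max_proteins: int = 100,
    index: ProteomeIndex | None = None,
) -> MappingResult:
    """Evaluate every peptide occurrence against every membrane helix of
    the occurrence's protein.

    Peptides matching more than one protein contribute hits to every match
    (maximal mapping) unless ``unique_only`` restricts the analysis to
    single-protein peptides.  Peptides matching more than ``max_proteins``
    proteins are flagged promiscuous but still reported.  The result also
    carries per-protein merged residue coverage and the
    accession -> peptide-set assignments used for protein grouping.
    The output is independent of peptide input order.
    """
    sequences = sorted(
        {p.sequence if isinstance(p, DetectedPeptide) else p for p in peptides}
    )
    if index is None or index.il_equivalent != il_equivalent:
        index = ProteomeIndex(proteome, il_equivalent=il_equivalent)
    tmds_by_protein: dict[str, list[TMDInterval]] = {}
    for iv in tmds:
        tmds_by_protein.setdefault(iv.protein_accession, []).append(iv)
    for ivs in tmds_by_protein.values():
        ivs.sort()

    hits: list[TMDHit] = []
    raw_coverage: dict[str, list[tuple[int, int]]] = {}
    assignments: dict[str, set[str]] = {}
    orphans: list[str] = []
    promiscuous: list[str] = []

    for seq in sequences:
        occurrences = index.find(seq)
        if not occurrences:
            orphans.append(seq)
            log.info("orphan peptide (no proteome occurrence): %s", seq)
            continue
        n_proteins = len({acc for acc, _ in occurrences})
        if n_proteins > max_proteins:
            promiscuous.append(seq)
            log.warning(
                "promiscuous peptide %s matches %d proteins", seq, n_proteins
            )
        if unique_only and n_proteins > 1:
            continue
        for acc, start in occurrences:
            end = start + len(seq) - 1
            assignments.setdefault(acc, set()).add(seq)
            raw_coverage.setdefault(acc, []).append((start, end))
            match = PeptideMatch(seq, acc, start, end)
            for iv in tmds_by_protein.get(acc, ()):
                outcome = classify_hit(
                    (start, end), iv.span, min_partial_overlap
                )
                if outcome is not None:
                    category, overlap = outcome
                    hits.append(TMDHit(match, iv, overlap, category))

    coverage = {acc: _merge_ranges(rs) for acc, rs in raw_coverage.items()}
    return MappingResult(hits, coverage, assignments, orphans, promiscuous)


def count_unique_tmds(hits: Iterable[TMDHit]) -> int:
    """Number of distinct (protein, helix ordinal) pairs with >= 1 hit —
    a helix hit by several peptides counts once."""
    return len({(h.tmd.protein_accession, h.tmd.ordinal) for h in hits})


def count_peptide_tmd_pairs(hits: Iterable[TMDHit]) -> int:
    """Number of distinct (peptide sequence, protein, helix ordinal)
    pairs — the alternative, peptide-level counter."""
    return len(
        {
            (h.match.peptide_sequence, h.tmd.protein_accession, h.tmd.ordinal)
            for h in hits
        }
    )


def group_proteins(assignments: Mapping[str, set[str] | frozenset[str]]) -> list[ProteinGroup]:
    """Merge proteins with identical matched-peptide sets into groups.

    Returns groups sorted by group id; the operation is a partition of the
    identified proteins and is idempotent.
    """
    by_set: dict[frozenset[str], list[str]] = {}
    for acc, peps in assignments.items():
        if not peps:
            raise ValueError(f"protein {acc!r} has no identified peptides")
        by_set.setdefault(frozenset(peps), []).append(acc)
    groups = [
        ProteinGroup(min(members), tuple(sorted(members)), pepset)
        for pepset, members in by_set.items()
    ]
    groups.sort(key=lambda g: g.group_id)
    return groups
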