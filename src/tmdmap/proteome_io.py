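"""Readers and writers for the formats the pipeline touches.

Covers FASTA proteomes, membrane-helix prediction tables in the two TMHMM
output dialects (per-segment "long" lines and one-line-per-protein "short"
summaries), and delimited detected-peptide tables as exported from a search
engine.  All coordinates are 1-based inclusive, matching TMHMM output.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

#: The 20 canonical amino-acid letters.
CANONICAL_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class ProteinRecord:
    """One database protein: accession, free-text description, sequence."""

    accession: str
    description: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True, order=True)
class TMDInterval:
    """One predicted membrane-spanning segment (1-based inclusive coords).

    ``ordinal`` indexes the helix within its protein in N-to-C order,
    starting at 1.
    """

    protein_accession: str
    start: int
    end: int
    ordinal: int = 1

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"invalid TMD interval {self.start}-{self.end} "
                f"for {self.protein_accession}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass(frozen=True)
class DetectedPeptide:
    """One peptide identification from a search-engine export.

    ``sequence`` is the plain database-space sequence (decorations and
    modification annotations stripped); ``modifications`` retains the
    stripped annotations as ``(residue_position, label)`` pairs.
    """

    sequence: str
    replicate: str
    method: str
    claimed_accessions: tuple[str, ...] = ()
    functional_category: str | None = None
    modifications: tuple[tuple[int, str], ...] = ()


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path, allow_x: bool = False) -> list[ProteinRecord]:
    """Read a FASTA proteome into validated :class:`ProteinRecord` objects.

    The accession is the first whitespace-delimited token of the header;
    sequences are uppercased with line breaks removed and trailing ``*``
    stop characters stripped.  Duplicate accessions, empty sequences and
    characters outside the 20-letter alphabet (plus ``X`` when ``allow_x``)
    raise :class:`ValueError`.
    """
    alphabet = CANONICAL_AA | {"X"} if allow_x else CANONICAL_AA
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        accession = rec.id
        if accession in seen:
            raise ValueError(f"duplicate accession in FASTA: {accession!r}")
        seen.add(accession)
        sequence = str(rec.seq).upper().rstrip("*")
        if not sequence:
            raise ValueError(f"empty sequence for accession {accession!r}")
        for pos, ch in enumerate(sequence, start=1):
            if ch not in alphabet:
                raise ValueError(
                    f"non-alphabet character {ch!r} at position {pos} "
                    f"of {accession!r}"
                )
        description = rec.description[len(rec.id):].strip()
        records.append(ProteinRecord(accession, description, sequence))
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records as FASTA (60-column wrap, deterministic input order)."""
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.accession, description=r.description)
        for r in records
    ]
    with open(path, "w", encoding="utf-8") as fh:
        SeqIO.write(seq_records, fh, "fasta")


# ---------------------------------------------------------------------------
# TMHMM prediction output (long and short dialects)
# ---------------------------------------------------------------------------

_SHORT_TOPOLOGY_RE = re.compile(r"(\d+)-(\d+)")
_LONG_REGIONS = {"TMhelix", "inside", "outside"}


def _finalize_intervals(
    raw: Mapping[str, list[tuple[int, int]]]
) -> list[TMDInterval]:
    """Sort each protein's segments N-to-C, assign ordinals, check overlap."""
    out: list[TMDInterval] = []
    for accession in sorted(raw):
        segments = sorted(raw[accession])
        prev_end = 0
        for ordinal, (start, end) in enumerate(segments, start=1):
            if start <= prev_end:
                raise ValueError(
                    f"overlapping membrane-helix intervals for {accession!r}: "
                    f"{start}-{end} overlaps a segment ending at {prev_end}"
                )
            prev_end = end
            out.append(TMDInterval(accession, start, end, ordinal))
    return out


def _parse_tmhmm_long(lines: Iterable[tuple[int, str]]) -> list[TMDInterval]:
    raw: dict[str, list[tuple[int, int]]] = {}
    for lineno, line in lines:
        fields = line.split()
        if len(fields) < 5 or fields[2] not in _LONG_REGIONS:
            raise ValueError(f"malformed long-dialect line {lineno}: {line!r}")
        if fields[2] != "TMhelix":
            continue  # inside/outside topology lines carry no helix
        try:
            start, end = int(fields[3]), int(fields[4])
        except ValueError as exc:
            raise ValueError(
                f"malformed coordinate on line {lineno}: {line!r}"
            ) from exc
        raw.setdefault(fields[0], []).append((start, end))
    return _finalize_intervals(raw)


def _parse_tmhmm_short(lines: Iterable[tuple[int, str]]) -> list[TMDInterval]:
    raw: dict[str, list[tuple[int, int]]] = {}
    for lineno, line in lines:
        fields = line.split()
        accession = fields[0]
        predhel: int | None = None
        topology: str | None = None
        for f in fields[1:]:
            if f.startswith("PredHel="):
                try:
                    predhel = int(f.split("=", 1)[1])
                except ValueError as exc:
                    raise ValueError(
                        f"malformed PredHel on line {lineno}: {line!r}"
                    ) from exc
            elif f.startswith("Topology="):
                topology = f.split("=", 1)[1]
        if topology is None:
            raise ValueError(
                f"short-dialect line {lineno} lacks Topology=: {line!r}"
            )
        segments = [
            (int(a), int(b)) for a, b in _SHORT_TOPOLOGY_RE.findall(topology)
        ]
        if predhel is not None and predhel != len(segments):
            raise ValueError(
                f"PredHel={predhel} disagrees with {len(segments)} parsed "
                f"Topology segments for protein {accession!r}"
            )
        raw.setdefault(accession, []).extend(segments)
    return _finalize_intervals(raw)


def parse_tmhmm(path: str | Path, dialect: str = "auto") -> list[TMDInterval]:
    """Parse TMHMM-style predictions into :class:`TMDInterval` objects.

    ``dialect`` is ``"long"`` (one line per predicted region, TMhelix lines
    carry the helices), ``"short"`` (one line per protein with ``PredHel=``
    and ``Topology=`` fields) or ``"auto"`` (inspect the first non-comment
    line).  Where ``PredHel`` is present it must agree with the number of
    parsed topology segments.
    """
    with open(path, encoding="utf-8") as fh:
        lines = [
            (i, line.strip())
            for i, line in enumerate(fh, start=1)
            if line.strip() and not line.lstrip().startswith("#")
        ]
    if not lines:
        return []
    if dialect == "auto":
        dialect = "short" if "Topology=" in lines[0][1] else "long"
    if dialect == "long":
        return _parse_tmhmm_long(lines)
    if dialect == "short":
        return _parse_tmhmm_short(lines)
    raise ValueError(f"unknown TMHMM dialect {dialect!r}")


def write_tmhmm_long(
    intervals: Iterable[TMDInterval],
    path: str | Path,
    tool: str = "TMHMM2.0",
) -> None:
    """Write intervals in the long TMHMM dialect (TMhelix lines only)."""
    rows = sorted(intervals)
    with open(path, "w", encoding="utf-8") as fh:
        for iv in rows:
            fh.write(
                f"{iv.protein_accession}\t{tool}\tTMhelix\t{iv.start}\t{iv.end}\n"
            )


def validate_intervals(
    intervals: Iterable[TMDInterval], proteome: Iterable[ProteinRecord]
) -> None:
    """Check every interval against the proteome's coordinate invariants."""
    lengths = {p.accession: len(p) for p in proteome}
    for iv in intervals:
        if iv.protein_accession not in lengths:
            raise ValueError(
                f"interval for unknown protein {iv.protein_accession!r}"
            )
        if iv.end > lengths[iv.protein_accession]:
            raise ValueError(
                f"interval {iv.start}-{iv.end} exceeds length "
                f"{lengths[iv.protein_accession]} of {iv.protein_accession!r}"
            )


# ---------------------------------------------------------------------------
# Detected-peptide tables
# ---------------------------------------------------------------------------

_DECORATION_RE = re.compile(r"^(?:[A-Za-z*-])\.(.+)\.(?:[A-Za-z*-])$")


def strip_peptide_cell(cell: str) -> tuple[str, tuple[tuple[int, str], ...]]:
    """Normalise one peptide cell to a plain uppercase sequence.

    Flanking-residue decorations of the form ``X.PEPTIDE.Y`` are removed,
    and modification annotations in parentheses or square brackets are
    stripped while being recorded as ``(residue_position, label)`` pairs,
    where the position is that of the preceding residue in the plain
    sequence (1-based).
    """
    text = cell.strip()
    m = _DECORATION_RE.match(text)
    if m:
        text = m.group(1)
    plain: list[str] = []
    mods: list[tuple[int, str]] = []
    i = 0
    while i < len(text):
        ch = text[i]
        if ch in "([":
            closer = ")" if ch == "(" else "]"
            j = text.find(closer, i + 1)
            if j < 0:
                raise ValueError(f"unbalanced {ch!r} in peptide cell {cell!r}")
            mods.append((len(plain), text[i + 1:j]))
            i = j + 1
        else:
            plain.append(ch.upper())
            i += 1
    return "".join(plain), tuple(mods)


def _sniff_delimiter(path: str | Path) -> str:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_peptide_table(
    path: str | Path,
    column_map: Mapping[str, str],
    min_peptide_length: int = 6,
) -> list[DetectedPeptide]:
    """Read a delimited detected-peptide table.

    ``column_map`` maps the logical fields ``peptide`` (required),
    ``replicate``, ``method``, ``proteins`` and ``category`` to column
    names of the file.  The delimiter (tab or comma) is sniffed from the
    header line.  Rows with an empty peptide cell, a missing mapped label,
    or a peptide shorter than ``min_peptide_length`` are rejected with a
    logged warning.
    """
    if "peptide" not in column_map:
        raise ValueError("column_map must map the 'peptide' field")
    sep = _sniff_delimiter(path)
    frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    for logical, column in column_map.items():
        if column not in frame.columns:
            raise ValueError(
                f"mapped column {column!r} (for {logical!r}) missing from "
                f"{path}; available: {list(frame.columns)}"
            )
    peptides: list[DetectedPeptide] = []
    for idx, row in frame.iterrows():
        cell = row[column_map["peptide"]].strip()
        if not cell:
            log.warning("row %d of %s: empty peptide cell, rejected", idx, path)
            continue
        sequence, mods = strip_peptide_cell(cell)
        if len(sequence) < min_peptide_length:
            log.warning(
                "row %d of %s: peptide %r shorter than %d, rejected",
                idx, path, sequence, min_peptide_length,
            )
            continue

        def _get(logical: str) -> str:
            col = column_map.get(logical)
            return row[col].strip() if col else ""

        replicate, method = _get("replicate"), _get("method")
        if ("replicate" in column_map and not replicate) or (
            "method" in column_map and not method
        ):
            log.warning(
                "row %d of %s: missing replicate/method label, rejected",
                idx, path,
            )
            continue
        accessions = tuple(
            a.strip() for a in re.split(r"[;,]", _get("proteins")) if a.strip()
        )
        peptides.append(
            DetectedPeptide(
                sequence=sequence,
                replicate=replicate or "rep1",
                method=method or "unknown",
                claimed_accessions=accessions,
                functional_category=_get("category") or None,
                modifications=mods,
            )
        )
    return peptides


def write_peptide_table(
    peptides: Sequence[DetectedPeptide], path: str | Path
) -> None:
    """Write peptides as TSV in the schema :func:`read_peptide_table` reads."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["peptide", "replicate", "method", "proteins", "category"])
        for p in peptides:
            writer.writerow(
                [
                    p.sequence,
                    p.replicate,
                    p.method,
                    ";".join(p.claimed_accessions),
                    p.functional_category or "",
                ]
            )


def write_tsv(
    rows: Iterable[Sequence], header: Sequence[str], path: str | Path,
    comment: str | None = None,
) -> None:
    """Generic deterministic TSV writer with a header row."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(header)
        writer.writerows(rows)
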