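"""In-silico chemical and enzymatic protein cleavage.

Implements the two digestion chemistries compared in the pipeline:

* urea / trypsin Lys-C (UR-TLC) — cleavage C-terminal of lysine and
  arginine;
* formic acid / CNBr then trypsin Lys-C (FA-CTLC) — cyanogen bromide first
  cleaves C-terminal of methionine (converting the terminal Met to
  homoserine or its lactone), then trypsin Lys-C cleaves after K and R.

Fragments carry protein-space 1-based inclusive coordinates so the
zero-missed-cleavage fragment set tiles the protein exactly.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping, Sequence

from .proteome_io import ProteinRecord


@dataclass(frozen=True)
class CleavageRule:
    """A cleavage specificity: cut C-terminal of any residue in
    ``cleave_after`` unless the next residue is in ``exceptions``.

    ``terminal_conversion`` optionally rewrites the residue left at a
    fragment's C-terminus by the cleavage chemistry (CNBr converts the
    terminal methionine to homoserine, marked ``Hse``).
    """

    name: str
    cleave_after: frozenset[str]
    exceptions: frozenset[str] = frozenset()
    terminal_conversion: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if not self.cleave_after:
            raise ValueError("cleave_after must be non-empty")

    def conversion_for(self, residue: str) -> str | None:
        for src, label in self.terminal_conversion:
            if residue == src:
                return label
        return None


#: Trypsin/Lys-C: C-terminal of arginine and lysine, no proline exception.
TRYPSIN_LYSC = CleavageRule("trypsin_lysC", frozenset("KR"))

#: Trypsin/Lys-C with the classical block before proline (KP/RP uncut).
TRYPSIN_LYSC_NO_P = CleavageRule(
    "trypsin_lysC_noP", frozenset("KR"), exceptions=frozenset("P")
)

#: Cyanogen bromide: C-terminal of methionine, Met -> homoserine (Hse).
CNBR = CleavageRule("cnbr", frozenset("M"), terminal_conversion=(("M", "Hse"),))

#: Single-pass union specificity (C-terminal of M, K and R), as a search
#: engine configures the CNBr + trypsin Lys-C chain.
CNBR_TRYPSIN_LYSC = CleavageRule(
    "cnbr+trypsin_lysC", frozenset("KRM"), terminal_conversion=(("M", "Hse"),)
)

RULES_BY_NAME: Mapping[str, CleavageRule] = {
    r.name: r for r in (TRYPSIN_LYSC, TRYPSIN_LYSC_NO_P, CNBR, CNBR_TRYPSIN_LYSC)
}

#: Ordered rule chains per method chemistry.
CHEMISTRIES: Mapping[str, tuple[CleavageRule, ...]] = {
    "UR-TLC": (TRYPSIN_LYSC,),
    "FA-CTLC": (CNBR, TRYPSIN_LYSC),
}


@dataclass(frozen=True)
class Fragment:
    """One digestion product with protein-space coordinates
    (1-based inclusive); ``c_term_conversion`` holds the homoserine marker
    when the chemistry rewrote the C-terminal residue."""

    protein_accession: str
    start: int
    end: int
    sequence: str
    missed_cleavages: int
    c_term_conversion: str | None = None

    def __len__(self) -> int:
        return len(self.sequence)


def cleavage_sites(sequence: str, rule: CleavageRule) -> list[int]:
    """0-based cut positions: site ``i`` cuts between residues ``i-1`` and
    ``i`` (so 0 < i < len)."""
    return [
        i
        for i in range(1, len(sequence))
        if sequence[i - 1] in rule.cleave_after
        and sequence[i] not in rule.exceptions
    ]


def _fragments_from_boundaries(
    accession: str,
    sequence: str,
    boundaries: Sequence[int],
    max_missed: int,
    rule: CleavageRule,
    offset: int = 0,
) -> list[Fragment]:
    out: list[Fragment] = []
    for a in range(len(boundaries) - 1):
        for b in range(a + 1, min(a + max_missed + 2, len(boundaries))):
            lo, hi = boundaries[a], boundaries[b]
            frag_seq = sequence[lo:hi]
            conversion = rule.conversion_for(frag_seq[-1])
            out.append(
                Fragment(
                    protein_accession=accession,
                    start=offset + lo + 1,
                    end=offset + hi,
                    sequence=frag_seq,
                    missed_cleavages=b - a - 1,
                    c_term_conversion=conversion,
                )
            )
    return out


def cleave(
    protein: ProteinRecord, rule: CleavageRule, max_missed: int = 0
) -> list[Fragment]:
    """Digest one protein, returning all fragments with at most
    ``max_missed`` internal cleavage sites, sorted by (start, end)."""
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    seq = protein.sequence
    if not seq:
        raise ValueError(f"empty sequence for {protein.accession!r}")
    boundaries = [0, *cleavage_sites(seq, rule), len(seq)]
    frags = _fragments_from_boundaries(
        protein.accession, seq, boundaries, max_missed, rule
    )
    frags.sort(key=lambda f: (f.start, f.end))
    return frags


def sequential_digest(
    protein: ProteinRecord,
    rules: Sequence[CleavageRule],
    max_missed_per_stage: Sequence[int] | None = None,
) -> list[Fragment]:
    """Apply an ordered chain of cleavage rules, stage k digesting every
    fragment emitted by stage k-1.

    Coordinates stay in protein space.  The reported missed-cleavage count
    of each final fragment is the number of internal sites of the combined
    (union) specificity, so zero-missed fragments tile the protein exactly
    as in a single-pass digest with the union rule.
    """
    if not rules:
        raise ValueError("rules must be non-empty")
    if max_missed_per_stage is None:
        max_missed_per_stage = [0] * len(rules)
    if len(max_missed_per_stage) != len(rules):
        raise ValueError("one max_missed value per stage required")

    seq = protein.sequence
    current = [
        Fragment(protein.accession, 1, len(seq), seq, 0)
        if seq
        else None
    ]
    if current[0] is None:
        raise ValueError(f"empty sequence for {protein.accession!r}")

    for rule, max_missed in zip(rules, max_missed_per_stage):
        nxt: dict[tuple[int, int], Fragment] = {}
        for frag in current:
            boundaries = [0, *cleavage_sites(frag.sequence, rule), len(frag.sequence)]
            for sub in _fragments_from_boundaries(
                protein.accession,
                frag.sequence,
                boundaries,
                max_missed,
                rule,
                offset=frag.start - 1,
            ):
                # a C-terminal conversion from an earlier stage survives if
                # the fragment end is unchanged
                if sub.c_term_conversion is None and sub.end == frag.end:
                    sub = Fragment(
                        sub.protein_accession, sub.start, sub.end,
                        sub.sequence, sub.missed_cleavages, frag.c_term_conversion,
                    )
                nxt.setdefault((sub.start, sub.end), sub)
        current = list(nxt.values())

    # recount missed cleavages against the union of all stage specificities
    union_sites = set()
    for rule in rules:
        union_sites.update(cleavage_sites(seq, rule))
    final = [
        Fragment(
            f.protein_accession,
            f.start,
            f.end,
            f.sequence,
            sum(1 for s in union_sites if f.start - 1 < s < f.end),
            f.c_term_conversion,
        )
        for f in current
    ]
    final.sort(key=lambda f: (f.start, f.end))
    return final


def digest_method(
    protein: ProteinRecord, method: str, max_missed: int = 0
) -> list[Fragment]:
    """Digest with a named method chemistry (``UR-TLC`` or ``FA-CTLC``)."""
    try:
        rules = CHEMISTRIES[method]
    except KeyError:
        raise ValueError(
            f"unknown method {method!r}; expected one of {sorted(CHEMISTRIES)}"
        ) from None
    return sequential_digest(protein, rules, [max_missed] * len(rules))


_HSE_MARKER_RE = re.compile(r"\((Hse|Hsl)\)")


def normalize_homoserine(peptide_sequence: str) -> str:
    """Strip homoserine / homoserine-lactone markers from a peptide so it
    matches the database-space protein substring.

    Markers must annotate methionine positions; a marker on any other
    residue raises :class:`ValueError`.
    """
    out: list[str] = []
    i = 0
    for m in _HSE_MARKER_RE.finditer(peptide_sequence):
        chunk = peptide_sequence[i:m.start()]
        if not chunk or chunk[-1] != "M":
            raise ValueError(
                f"{m.group(1)} marker on a non-methionine residue in "
                f"{peptide_sequence!r}"
            )
        out.append(chunk)
        i = m.end()
    out.append(peptide_sequence[i:])
    return "".join(out)
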