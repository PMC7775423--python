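"""Independent brute-force reference implementations used as test oracles.

These deliberately re-derive every answer from first principles (explicit
residue-index sets, exhaustive substring enumeration) and share no code
with the library paths they check.
"""

from __future__ import annotations


def classify_by_residue_sets(
    match_span: tuple[int, int],
    tmd_span: tuple[int, int],
    min_partial_overlap: int = 2,
) -> tuple[str, int] | None:
    """Re-derive the hit category from explicit residue-index sets."""
    peptide = set(range(match_span[0], match_span[1] + 1))
    tmd = set(range(tmd_span[0], tmd_span[1] + 1))
    overlap = peptide & tmd
    if not overlap:
        return None
    if tmd <= peptide:
        return ("CONTAINS", len(overlap))
    if peptide <= tmd:
        return ("WITHIN", len(overlap))
    if len(overlap) < min_partial_overlap:
        return None
    if min(peptide) < min(tmd):
        return ("N_PARTIAL", len(overlap))
    return ("C_PARTIAL", len(overlap))


def bruteforce_sites(sequence: str, cleave_after: set[str],
                     exceptions: set[str] = frozenset()) -> list[int]:
    return [
        i
        for i in range(1, len(sequence))
        if sequence[i - 1] in cleave_after and sequence[i] not in exceptions
    ]


def bruteforce_fragments(
    sequence: str,
    cleave_after: set[str],
    max_missed: int,
    exceptions: set[str] = frozenset(),
) -> set[tuple[int, int, str, int]]:
    """All site-bounded substrings with <= max_missed internal sites, as
    (start, end, sequence, missed) with 1-based inclusive coordinates."""
    bounds = [0, *bruteforce_sites(sequence, cleave_after, exceptions),
              len(sequence)]
    out = set()
    for a in range(len(bounds) - 1):
        for b in range(a + 1, len(bounds)):
            missed = b - a - 1
            if missed > max_missed:
                break
            lo, hi = bounds[a], bounds[b]
            out.add((lo + 1, hi, sequence[lo:hi], missed))
    return out
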