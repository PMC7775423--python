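"""GRAVY hydropathy scoring and a sliding-window membrane-helix surrogate.

GRAVY (grand average of hydropathy) is the mean Kyte-Doolittle hydropathy
value over a sequence; scores above 0 indicate a hydrophobic, likely
membrane, protein.  The window predictor here is a deliberately simple
hydropathy-profile caller labelled ``surrogate-window`` in all outputs: it
lets the full pipeline run self-contained, and is not a topology predictor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .proteome_io import ProteinRecord, TMDInterval

#: Tool label stamped on surrogate predictions so they are never mistaken
#: for genuine TMHMM output.
SURROGATE_TOOL = "surrogate-window"

_KD_VALUES: Mapping[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}


@dataclass(frozen=True)
class HydropathyScale:
    """A residue-to-hydropathy map over exactly the 20 canonical residues."""

    name: str
    values: Mapping[str, float]

    def __post_init__(self) -> None:
        if set(self.values) != set(_KD_VALUES):
            raise ValueError("scale must cover exactly the 20 canonical residues")
        if not all(np.isfinite(v) for v in self.values.values()):
            raise ValueError("scale values must be finite")


KYTE_DOOLITTLE = HydropathyScale("Kyte-Doolittle", dict(_KD_VALUES))


def gravy(
    sequence: str,
    scale: HydropathyScale = KYTE_DOOLITTLE,
    skip_unknown: bool = False,
) -> float:
    """Grand average of hydropathy: the mean per-residue scale value.

    Unknown residues raise :class:`ValueError` unless ``skip_unknown``,
    which excludes them from both the sum and the length.
    """
    if not sequence:
        raise ValueError("sequence must be non-empty")
    values = []
    for pos, ch in enumerate(sequence.upper(), start=1):
        try:
            values.append(scale.values[ch])
        except KeyError:
            if skip_unknown:
                continue
            raise ValueError(
                f"residue {ch!r} at position {pos} not in scale {scale.name!r}"
            ) from None
    if not values:
        raise ValueError("no scored residues in sequence")
    return float(np.mean(values))


def classify_hydrophobic(score: float) -> bool:
    """True iff the GRAVY score is strictly above 0 (a score of exactly 0
    is classified not hydrophobic)."""
    if not np.isfinite(score):
        raise ValueError("score must be finite")
    return score > 0.0


def window_profile(
    sequence: str,
    window: int = 19,
    scale: HydropathyScale = KYTE_DOOLITTLE,
) -> np.ndarray:
    """Centred moving average of per-residue hydropathy.

    Returns one value per full window; entry ``i`` is the mean over the
    window centred on residue ``i + window // 2 + 1`` (1-based).  The
    window must be odd and no longer than the sequence.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window > len(sequence):
        raise ValueError("window exceeds sequence length")
    per_residue = np.array([_lookup(scale, ch) for ch in sequence.upper()])
    kernel = np.full(window, 1.0 / window)
    return np.convolve(per_residue, kernel, mode="valid")


def _lookup(scale: HydropathyScale, ch: str) -> float:
    try:
        return scale.values[ch]
    except KeyError:
        raise ValueError(f"residue {ch!r} not in scale {scale.name!r}") from None


def predict_tmd_surrogate(
    protein: ProteinRecord,
    threshold: float = 1.6,
    min_len: int = 18,
    window: int = 19,
    scale: HydropathyScale = KYTE_DOOLITTLE,
) -> list[TMDInterval]:
    """Call putative membrane helices from the hydropathy profile.

    Each maximal run of window centres with mean hydropathy strictly
    above ``threshold`` is reported as the union of its contributing
    windows (the run expanded by half a window on each side, clipped to
    the sequence); overlapping calls are merged and intervals shorter
    than ``min_len`` residues dropped.  Output is interval-compatible
    with the TMHMM parsers so downstream stages are agnostic to origin.
    Sequences shorter than the window yield no predictions.
    """
    n = len(protein.sequence)
    if n < window:
        return []
    profile = window_profile(protein.sequence, window=window, scale=scale)
    half = window // 2
    # strict inequality by contract; rounding keeps a profile sitting
    # exactly at the threshold from leaking past it via summation noise
    above = np.round(profile, 9) > threshold
    spans: list[tuple[int, int]] = []
    run_start: int | None = None
    for i, flag in enumerate([*above, False]):
        if flag and run_start is None:
            run_start = i
        elif not flag and run_start is not None:
            # centres run_start .. i-1 (0-based) -> residues, expanded
            start = max(1, run_start + 1)
            end = min(n, (i - 1) + window)
            if spans and start <= spans[-1][1]:
                spans[-1] = (spans[-1][0], end)  # merge overlapping calls
            else:
                spans.append((start, end))
            run_start = None
    intervals = [
        TMDInterval(protein.accession, s, e, ordinal)
        for ordinal, (s, e) in enumerate(
            [sp for sp in spans if sp[1] - sp[0] + 1 >= min_len], start=1
        )
    ]
    return intervals


def gravy_table(
    proteins: Iterable[ProteinRecord],
    scale: HydropathyScale = KYTE_DOOLITTLE,
    skip_unknown: bool = False,
) -> list[tuple[str, int, float, bool]]:
    """Per-protein rows (accession, length, gravy, hydrophobic flag),
    sorted by accession."""
    rows = []
    for p in sorted(proteins, key=lambda r: r.accession):
        score = gravy(p.sequence, scale=scale, skip_unknown=skip_unknown)
        rows.append((p.accession, len(p), score, classify_hydrophobic(score)))
    return rows
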