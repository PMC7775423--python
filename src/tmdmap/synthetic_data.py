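"""Seeded generator of proteomes with planted membrane helices and of
method-specific detected-peptide tables.

The generator emulates the study conditions of a plant microsomal-membrane
bottom-up experiment: roughly 23% of database proteins are transmembrane
(about half of those with a single helix, the rest with a geometric-like
tail up to 30 helices), helices are 18-25 hydrophobic residues, and loops
are hydrophilic with exponential lengths (mean 60).  Detection is a
peptide-wise independent Bernoulli whose probability depends only on
whether the candidate fragment overlaps a true helix by at least two
residues — the simplest model separating the two chemistries' access to
membrane-embedded sequence: the urea workflow (UR-TLC) rarely recovers
helix-overlapping peptides (p = 0.02) while the CNBr workflow (FA-CTLC)
recovers them readily (p = 0.20); loop peptides are detected at p = 0.30
by both.

All randomness flows from one integer seed through documented
``numpy.random.SeedSequence`` keys, so adding replicates or methods never
perturbs previously generated data.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .digestion import CHEMISTRIES, sequential_digest
from .proteome_io import (
    DetectedPeptide,
    ProteinRecord,
    TMDInterval,
    write_fasta,
    write_peptide_table,
    write_tmhmm_long,
)

#: Residue composition of hydrophilic loops (and of whole non-membrane
#: proteins).  Rich in D/E/K/R/S/G so trypsin sites are frequent and GRAVY
#: is clearly negative; a little Met keeps CNBr active outside helices.
LOOP_COMPOSITION: Mapping[str, float] = {
    "D": 0.09, "E": 0.10, "K": 0.09, "R": 0.07, "S": 0.10, "G": 0.10,
    "N": 0.06, "Q": 0.06, "T": 0.07, "P": 0.06, "A": 0.08, "H": 0.03,
    "L": 0.04, "V": 0.03, "M": 0.02,
}

#: Residue composition of membrane helices.  Rich in I/L/V/F/A so the
#: Kyte-Doolittle window profile rises well above 1.6; Met at 6% gives
#: CNBr intra-helix cut sites, K/R are absent as in real helices.
TMD_COMPOSITION: Mapping[str, float] = {
    "I": 0.18, "L": 0.22, "V": 0.16, "F": 0.12, "A": 0.12, "G": 0.05,
    "T": 0.04, "S": 0.03, "M": 0.06, "W": 0.01, "Y": 0.01,
}


@dataclass(frozen=True)
class MethodModel:
    """Detection model of one solubilization/cleavage method."""

    name: str
    chemistry: str  # key into digestion.CHEMISTRIES
    p_detect_loop_peptide: float
    p_detect_tmd_peptide: float

    def __post_init__(self) -> None:
        if self.chemistry not in CHEMISTRIES:
            raise ValueError(f"unknown chemistry {self.chemistry!r}")
        for p in (self.p_detect_loop_peptide, self.p_detect_tmd_peptide):
            if not 0.0 <= p <= 1.0:
                raise ValueError("detection probabilities must be in [0, 1]")


DEFAULT_METHODS: tuple[MethodModel, ...] = (
    MethodModel("UR-TLC", "UR-TLC", 0.30, 0.02),
    MethodModel("FA-CTLC", "FA-CTLC", 0.30, 0.20),
)


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition parameters for the synthetic experiment."""

    n_proteins: int = 150
    tmp_fraction: float = 0.23
    tmd_count_max: int = 30
    tmd_count_decay: float = 0.5  # P(k) proportional to decay**k over 1..max
    tmd_length_range: tuple[int, int] = (18, 25)
    loop_length_mean: float = 60.0
    loop_length_min: int = 8
    soluble_length_mean: float = 300.0
    soluble_length_min: int = 60
    methods: tuple[MethodModel, ...] = DEFAULT_METHODS
    min_peptide_length: int = 6
    max_peptide_length: int = 45
    max_missed: int = 1
    replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.tmp_fraction <= 1.0:
            raise ValueError("tmp_fraction must be in [0, 1]")
        lo, hi = self.tmd_length_range
        if not (0 < lo <= hi):
            raise ValueError("tmd_length_range must be non-degenerate")
        if self.min_peptide_length > self.max_peptide_length:
            raise ValueError("peptide length bounds inverted")
        if self.n_proteins < 1 or self.replicates < 1:
            raise ValueError("n_proteins and replicates must be >= 1")

    @property
    def tmd_count_distribution(self) -> np.ndarray:
        """P(TMD count = k) for k = 1..tmd_count_max; with the default
        decay of 0.5 roughly half the mass sits at a single helix."""
        k = np.arange(1, self.tmd_count_max + 1)
        w = self.tmd_count_decay ** k
        return w / w.sum()


def _draw_sequence(rng: np.random.Generator, length: int,
                   composition: Mapping[str, float]) -> str:
    letters = list(composition)
    probs = np.array([composition[a] for a in letters])
    probs = probs / probs.sum()
    return "".join(rng.choice(letters, size=length, p=probs))


def _method_key(name: str) -> int:
    """Stable small integer identifying a method in seed derivation."""
    return zlib.crc32(name.encode("utf-8")) & 0x7FFFFFFF


def _rng(seed: int, *key: int) -> np.random.Generator:
    """Documented seed-splitting rule: one master seed plus a tuple key."""
    return np.random.default_rng(np.random.SeedSequence((int(seed), *key)))


#: SeedSequence stream key of the proteome stream.
_PROTEOME_STREAM = 1


def generate_proteome(
    config: SimulationConfig,
) -> tuple[list[ProteinRecord], list[TMDInterval]]:
    """Generate the synthetic proteome and its ground-truth helix set.

    Transmembrane proteins alternate hydrophilic loops with hydrophobic
    helices (loop - helix - loop - ... - helix - loop); soluble proteins
    are a single loop-composition sequence.  Deterministic for a fixed
    config and seed.
    """
    rng = _rng(config.seed, _PROTEOME_STREAM)
    lo, hi = config.tmd_length_range
    records: list[ProteinRecord] = []
    intervals: list[TMDInterval] = []
    width = len(str(config.n_proteins))
    for i in range(config.n_proteins):
        accession = f"SYN{i + 1:0{width}d}"
        if rng.random() < config.tmp_fraction:
            k = int(rng.choice(
                np.arange(1, config.tmd_count_max + 1),
                p=config.tmd_count_distribution,
            ))
            parts: list[str] = []
            pos = 0
            for t in range(k):
                loop_len = config.loop_length_min + int(
                    rng.exponential(config.loop_length_mean)
                )
                parts.append(_draw_sequence(rng, loop_len, LOOP_COMPOSITION))
                pos += loop_len
                tmd_len = int(rng.integers(lo, hi + 1))
                parts.append(_draw_sequence(rng, tmd_len, TMD_COMPOSITION))
                intervals.append(
                    TMDInterval(accession, pos + 1, pos + tmd_len, t + 1)
                )
                pos += tmd_len
            tail_len = config.loop_length_min + int(
                rng.exponential(config.loop_length_mean)
            )
            parts.append(_draw_sequence(rng, tail_len, LOOP_COMPOSITION))
            sequence = "".join(parts)
            records.append(ProteinRecord(accession, "synthetic TMP", sequence))
        else:
            length = config.soluble_length_min + int(
                rng.exponential(config.soluble_length_mean)
            )
            records.append(
                ProteinRecord(
                    accession,
                    "synthetic soluble",
                    _draw_sequence(rng, length, LOOP_COMPOSITION),
                )
            )
    return records, intervals


def _overlap_ge(
    start: int, end: int, tmds: Sequence[TMDInterval], min_overlap: int = 2
) -> bool:
    for iv in tmds:
        if min(end, iv.end) - max(start, iv.start) + 1 >= min_overlap:
            return True
    return False


def simulate_detection(
    proteome: Sequence[ProteinRecord],
    truth: Sequence[TMDInterval],
    method: MethodModel,
    config: SimulationConfig,
) -> dict[str, list[DetectedPeptide]]:
    """Simulate the detected-peptide tables of one method.

    Every protein is digested with the method's chemistry (missed
    cleavages up to ``config.max_missed`` per stage); candidate fragments
    within the peptide length bounds are detected independently per
    replicate with ``p_detect_tmd_peptide`` when they overlap a true
    helix by >= 2 residues and ``p_detect_loop_peptide`` otherwise.
    Replicate streams are keyed by (seed, method, replicate), so earlier
    replicates are invariant to adding more.
    """
    rules = CHEMISTRIES[method.chemistry]
    tmds_by_protein: dict[str, list[TMDInterval]] = {}
    for iv in truth:
        tmds_by_protein.setdefault(iv.protein_accession, []).append(iv)

    candidates: list[tuple[str, str, bool]] = []  # accession, sequence, is_tmd
    for protein in proteome:
        frags = sequential_digest(
            protein, rules, [config.max_missed] * len(rules)
        )
        ptmds = tmds_by_protein.get(protein.accession, ())
        for f in frags:
            if not (
                config.min_peptide_length <= len(f) <= config.max_peptide_length
            ):
                continue
            candidates.append(
                (
                    protein.accession,
                    f.sequence,
                    _overlap_ge(f.start, f.end, ptmds),
                )
            )

    p = np.array(
        [
            method.p_detect_tmd_peptide if is_tmd else method.p_detect_loop_peptide
            for _, _, is_tmd in candidates
        ]
    )
    tables: dict[str, list[DetectedPeptide]] = {}
    mkey = _method_key(method.name)
    for rep in range(1, config.replicates + 1):
        rng = _rng(config.seed, mkey, rep)
        drawn = rng.random(len(candidates)) < p if candidates else np.array([])
        label = f"rep{rep}"
        tables[label] = [
            DetectedPeptide(
                sequence=seq,
                replicate=label,
                method=method.name,
                claimed_accessions=(acc,),
            )
            for (acc, seq, _), hit in zip(candidates, drawn)
            if hit
        ]
    return tables


def run_simulation(
    config: SimulationConfig,
) -> tuple[
    list[ProteinRecord],
    list[TMDInterval],
    dict[str, dict[str, list[DetectedPeptide]]],
]:
    """Generate the proteome and all per-method, per-replicate tables."""
    proteome, truth = generate_proteome(config)
    tables = {
        m.name: simulate_detection(proteome, truth, m, config)
        for m in config.methods
    }
    return proteome, truth, tables


def write_simulation(
    outdir: str | Path, config: SimulationConfig
) -> tuple[Path, Path, list[Path]]:
    """Run the simulation and write proteome.fasta, tmhmm_truth.txt (long
    dialect) and peptides_<method>_rep<k>.tsv under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    proteome, truth, tables = run_simulation(config)
    fasta = outdir / "proteome.fasta"
    write_fasta(proteome, fasta)
    tmhmm = outdir / "tmhmm_truth.txt"
    write_tmhmm_long(truth, tmhmm)
    peptide_paths = []
    for method_name, reps in tables.items():
        safe = method_name.replace("/", "-")
        for rep_label, peptides in reps.items():
            path = outdir / f"peptides_{safe}_{rep_label}.tsv"
            write_peptide_table(peptides, path)
            peptide_paths.append(path)
    return fasta, tmhmm, peptide_paths
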