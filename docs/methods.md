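# Methods

## Peptide-to-TMD hit classification

A detected peptide placed at residues `[p1, p2]` of a protein is compared
with each predicted transmembrane domain (TMD) `[t1, t2]` of that protein
(all coordinates 1-based inclusive). The peptide is a **hit** when

* `CONTAINS` — `p1 <= t1` and `p2 >= t2` (the peptide covers the whole
  TMD; span equality resolves here),
* `WITHIN` — `t1 <= p1` and `p2 <= t2` (the peptide lies inside the TMD),
* `N_PARTIAL` / `C_PARTIAL` — the peptide crosses exactly one TMD
  boundary and `overlap = min(p2, t2) - max(p1, t1) + 1 >= 2`.

Precedence is `CONTAINS > WITHIN > partial`, so every hit receives
exactly one category. The two-residue minimum applies only to
boundary-crossing peptides; a `WITHIN` peptide of any accepted length
(>= 6 residues by default) is a hit. A peptide spanning both boundaries
is `CONTAINS` even though it also extends outside the TMD. "Unique TMDs
identified" counts distinct (protein, TMD-ordinal) pairs with >= 1 hit —
a TMD hit by three peptides is one identified TMD; the peptide-level
counter (distinct peptide x TMD pairs) is reported alongside because both
readings of a TMD-identification count are defensible.

Peptide location is exact substring search returning all, including
overlapping, occurrences; isoleucine/leucine equivalence is available but
off by default (search-engine identifications drawn from the same
database match exactly). Peptides matching several proteins contribute
hits to every match (maximal mapping; `--unique-only` restricts to
single-protein peptides), and group-level reporting absorbs the
redundancy: proteins with identical matched-peptide sets form one protein
group whose identifier is the lexicographically smallest member
accession.

Coordinates are kept 1-based inclusive (the convention of TMHMM output)
in all domain types and in the overlap arithmetic; conversion to 0-based
half-open happens only in the BED-like coverage writer, whose header says
so. A single convention end-to-end was preferred over converting at the
parser boundary, trading one `+1` in the overlap formula for the absence
of a dual representation.

## In-silico digestion

A cleavage rule cuts C-terminal of a residue set unless the next residue
is in an exception set. Built-in rules: trypsin/Lys-C (after K and R, no
proline exception by default — the classical KP/RP block is available as
an option), CNBr (after M, marking the fragment's terminal Met as
homoserine, `Hse`), and their single-pass union (after K, R and M) as a
search engine would configure the chain. Sequential digestion applies
rules in order, each stage cleaving every fragment of the previous one,
with coordinates kept in protein space; with zero missed cleavages the
result provably equals the union-rule single pass, and missed-cleavage
counts are reported against the union site set. Homoserine /
homoserine-lactone markers on search-engine peptides are stripped
(`normalize_homoserine`) so sequences match the database; a marker on a
non-Met residue is an error. Protein N-terminal Met removal and
semi-specific cleavage are not modelled. The default missed-cleavage
allowance for detectability modelling is 1 per stage (configurable);
digestion tests exercise 0-3.

## GRAVY and the surrogate helix caller

GRAVY is the mean Kyte-Doolittle hydropathy over the sequence; a score
strictly above 0 classifies a protein hydrophobic (a score of exactly 0
is not hydrophobic — the boundary is strict and tested). Group-level
GRAVY is that of the group representative (smallest accession); a
per-protein table is always available. Unknown residues are an error
unless explicitly skipped (excluded from both sum and length).

The surrogate helix caller is a centred moving average (window 19,
odd-only) thresholded at 1.6 (strict; the profile is rounded to 9
decimals first so a window sitting exactly at the threshold cannot leak
past it through floating-point summation noise). Each maximal
above-threshold run of window centres is reported as the union of its
contributing windows, overlapping calls merged, intervals shorter than 18
residues dropped. Its output is format-identical to parsed TMHMM
predictions and is stamped `surrogate-window` everywhere so it can never
be mistaken for TMHMM; it exists so the pipeline runs self-contained, not
to reproduce TMHMM's hidden Markov model.

## Comparison statistics

* **TMD-count histogram**: transmembrane protein groups binned by TMD
  count (bins 1..10 and ">10" by default). A group's TMD count is the
  maximum over members (conservative toward transmembrane claims; mean
  selectable). Zero-TMD groups are reported separately, never binned.
* **Chi-square goodness of fit** of a method's histogram against the
  proteome-wide TMD distribution: Pearson statistic on observed counts
  vs expected proportions, dof = bins - 1, bins with expected count < 5
  merged right-to-left into their left neighbour with a logged merge
  trail.
* **Reproducibility** across replicate group sets:
  `|intersection of all| / |union of all| x 100`. Because published
  reproducibility percentages rarely state their formula, the pairwise
  Jaccard table and the full Venn region counts are emitted so any
  alternative definition can be recomputed.
* **Per-bin t-test**: two-sided two-sample test on per-replicate bin
  fractions, classical equal-variance Student by default (Welch
  selectable), significance stars at 0.05 / 0.01. Zero variance in both
  groups is degenerate: p = 1 for equal means, p = 0 flagged otherwise.
* **Binomial enrichment**: per functional category, exact two-sided
  binomial test of the method-A count against the pooled null proportion
  `(countA + countB) / (nA + nB)`; Benjamini-Hochberg q-values across
  categories, raw p-values kept alongside. Categories are consumed as an
  input column, never predicted.

## Synthetic data generator

The generator emulates a plant microsomal-membrane experiment at desk
scale. Defaults: 150 proteins per proteome (chosen so a 100-seed sweep
completes in minutes on one core); each protein is transmembrane with
probability 0.23; TMD counts follow `P(k) proportional to 0.5^k` over
1..30 (about half of all TMPs have a single helix); helix lengths are
uniform 18-25 residues; loops are exponential with mean 60 (minimum 8);
soluble proteins are exponential with mean 300 (minimum 60) residues.
Residue compositions are fixed documented tables: loops rich in
D/E/K/R/S/G (frequent tryptic sites, clearly negative GRAVY, 2% Met),
helices rich in I/L/V/F/A (window hydropathy well above 1.6, no K/R, 6%
Met so CNBr has intra-helix sites).

Detection is peptide-wise independent Bernoulli on the candidate
fragments of each method's chemistry within length bounds 6-45: a
candidate overlapping a true helix by >= 2 residues is detected with
`p_tmd` (UR-TLC 0.02, FA-CTLC 0.20), any other with `p_loop` (0.30 for
both). This is deliberately the simplest model separating the two
chemistries' access to membrane-embedded sequence — no abundance,
ionization, retention or FDR modelling — so passing tests demonstrate the
mapping and statistics machinery, not mass-spectrometric realism. Real
data differ in (at least) correlated peptide detectability, shared
peptides across homologues, noisy TMD predictions and non-uniform
protein abundance.

Randomness: one master seed enters `numpy.random.SeedSequence` tuples —
`(seed, 1)` for the proteome stream and `(seed, crc32(method), replicate)`
per detection table — so adding methods or replicates never perturbs
previously generated data, and identical configs are byte-reproducible.

## Null calibration of the per-bin t-test

The t-test's false-positive rate is estimated on simulations where both
pseudo-methods share one detection model, so every rejection is false.
This null study uses sparse detection (p = 0.04, 120 proteins) rather
than the default 0.30: at 0.30 essentially every protein is identified in
every replicate, the per-replicate fractions carry no sampling variance,
and the experiment degenerates (nothing to calibrate). With sparse
detection each replicate is a genuine random subsample; over 200
simulations the rate over all non-degenerate bins sits within two
standard errors of the nominal 0.05.

## Numerical and edge-case choices

* FASTA: accession = first header token; sequences uppercased, trailing
  `*` stripped; duplicate accessions, empty sequences and non-alphabet
  characters are errors (X admitted on request). Peptides whose claimed
  accession is absent are kept and flagged orphan; they may still match
  other proteins by sequence.
* TMHMM parsing: long and short dialects auto-detected from the first
  non-comment line; `PredHel` must agree with the parsed `Topology`
  segment count; malformed coordinates are reported with their line
  number; per-protein intervals must be non-overlapping and are assigned
  ordinals in N-to-C order.
* Peptide tables: delimiter (tab/comma) sniffed from the header line
  only; `X.PEPTIDE.Y` flanking decorations stripped; bracketed or
  parenthesised modification annotations removed but retained as
  (position, label) pairs; rows with empty peptide cells or missing
  mapped labels are rejected with a logged warning.
* Writers emit deterministic row order and a version + parameter header
  comment, never timestamps, so identical runs are byte-identical.
* Promiscuous peptides (matching > 100 proteins by default) are flagged
  and logged but still reported.

## Limitations

Identification is sequence-level only: no spectra, no FDR, no
quantification. The detection model's probabilities are stylized; the
simulator supports directional claims (which chemistry reaches more
helix sequence) but not magnitude claims about any real experiment.
Functional-category enrichment depends entirely on a user-supplied
annotation column. The surrogate helix caller assigns no topology
(inside/outside) and should not be used where genuine TMHMM output is
available.
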