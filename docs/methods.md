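# Methods

This note documents the model implemented by `synpss`, the conventions
adopted where the published description of this family of methods leaves
choices open, the synthetic data the tests run on, and the limits of what
those tests demonstrate.

## Words, synonymous words, similarity levels

A word is an n-gram over the 20 standard amino-acid letters. Windows
containing any other letter (X, B, Z, U, O) are skipped on both the
template and the subject side: BLOSUM62 positivity is undefined for X/U/O
and ambiguous for B/Z, and the similarity level below is built on it.

Given a local alignment between a known-structure protein *p* and a
similar protein *sp*, every window of n alignment columns with no gap in
either row yields a synonymous word: the subject-side n-gram, annotated
with the structure of the query-side window (structure inheritance) and
with the similarity level of the two n-grams — the count of aligned
positions whose BLOSUM62 score is strictly positive ("interchangeable"
residues). An original word of *p* is its own synonym at level n.
The BLOSUM62 table is embedded verbatim (NCBI distribution, half-bit
scores) so levels cannot drift with an external dependency; a unit test
cross-checks every entry against Biopython's copy.

## Dictionary construction and aggregation

The dictionary maps each word to per-source records
`(source id, structure, similarity level, frequency, source positions)`.
Identical `(word, source, structure)` occurrences are clustered: the
frequency is the occurrence count (an original word of the source counts
1 plus any identical harvested copies), the level is the maximum observed,
positions are unioned. Distinct structure strings for the same
`(word, source)` are kept as separate records and vote independently —
one stored level per source with maximum-evidence aggregation keeps the
strongest signal without suppressing genuine structural ambiguity.
This rule makes aggregation associative: building from a pooled template
set equals merging per-template dictionaries (tested).

Source exclusion (e.g. hiding every template sharing ≥ 25% identity with
the target, the customary redundancy protocol) is a read-only view; the
underlying dictionary is never modified.

## Matching and voting

Exact matching looks the target word up directly. Inexact matching allows
at most one mismatched (don't-care, never gapped) position, implemented
by n position-masked projections of every dictionary word; the index is
contractually equivalent to a brute-force Hamming-distance ≤ 1 scan
(tested against a vectorised scan on 10⁴-word dictionaries). The
don't-care position incurs no score penalty and still receives the
record's structure vote.

Each matched record votes
`min(freq_t, freq_i) × (1 + min(Sim_t, Sim_i))` onto the n covered
residues per occurrence of the word on the target; a word occurring at
several target positions votes fully at each. Per residue, the state with
the highest total wins; ties resolve coil > helix > strand, and a residue
with no votes at all is called coil with confidence 0 (coil is the
majority/default state).

### Confidence normalization (a documented convention)

The confidence level at residue x is
`floor(10 × winning votes(x) / N(x))` clamped into [0, 9], where N(x)
sums, over every (word item, matched record) contribution covering x, the
maximum score that contribution could attain, `freq_t × (1 + Sim_t)`.
This particular denominator is this package's convention: it realises a
"vote share of the attainable maximum" ratio, guarantees the [0, 9] range
without rescaling, and is invariant under multiplying all frequencies by
a constant (tested). Other normalizations consistent with the same verbal
description exist; calibration (below) makes downstream use independent
of the choice.

## Evaluation

Q3 is the percentage of residues with matching state; Q3Ho/Q3Eo/Q3Co are
recalls over residues whose *observed* state is H/E/C (their
truth-frequency-weighted mean reproduces Q3, tested). Set-level Q3 is
reported per-protein-averaged by default, with pooled per-residue
averaging available. SOV follows the 1999 revision (Zemla, Venclovas,
Fidelis & Rost): for each state, overlapping observed/predicted segment
pairs contribute `(minov + δ)/maxov × len(s_obs)` with
`δ = min(maxov − minov, minov, ⌊len(s_obs)/2⌋, ⌊len(s_pred)/2⌋)`, observed
segments with no partner contribute only to the normalizer, and the
combined measure pools numerators and normalizers over the three states.
The test oracle is an independent transcription of the same published
formula, coded separately (no pre-installed package provides SOV).

## Confidence calibration and the meta-combiner

An accuracy table maps each confidence level 0–9 of a predictor to the
mean per-residue Q3 it achieved on a calibration set, plus the residue
count. The combiner compares, per residue, the two predictors'
calibrated accuracies and emits the state of the better-calibrated one;
exact ties go to method A (a fixed, documented choice — the alternative
orderings are equally defensible and the case is measure-zero in
practice). When both predictors agree, the state is emitted regardless
of levels. A level with no calibration data raises rather than guessing.

## Shared-word alignment

For two proteins with word sets X and Y, every word present in both
contributes, for each occurrence pair (i on x, j on y), one count to the
n diagonal residue pairs (x_{i+k}, y_{j+k}). The resulting L₁×L₂ count
matrix is used as the substitution surface of a global Needleman–Wunsch
alignment with a linear gap penalty (default 0 — the counts themselves
are sparse enough that gaps emerge where diagonal runs are interrupted;
the penalty is configurable). Traceback ties prefer match over a gap in
y over a gap in x, making the alignment deterministic; optimality is
spot-checked against exhaustive enumeration on small matrices.

## DSSP reduction and formats

Eight-state DSSP codes reduce as H, G, I → H; E, B → E; everything else
(T, S, blank, '-') → C — the common convention, adopted explicitly
because usage varies across the literature; users mapping B → C or
G → C will see slightly different per-state numbers. Coordinates are
0-based half-open internally and 1-based inclusive in every file and
report. Alignments are accepted as BLAST XML, BLAST tabular with
qseq/sseq columns, or a minimal `simple-tsv` dialect emitted by the
synthetic generator, with HSPs above the e-value threshold (default
0.001) dropped; search parameters (j = 3, b = 500, e = 0.001) are
recorded as provenance only and never enforced. The dictionary file is a
`#`-header block plus one TSV row per record and round-trips losslessly.

## Synthetic data: what it emulates and what it does not

The generator produces template pools with segment-structured three-state
assignments (per-state minimum and geometric mean segment lengths — an
i.i.d. per-residue structure would make SOV meaningless), residues drawn
with mild state-conditional propensities, and homologs derived by
substitutions preferring positive-BLOSUM62 partners (Boltzmann weights in
the half-bit score) with geometric-length indels. Identity is exact by
construction in the gapless case (`round(identity × L)` conserved
positions). The family-pool variant organises templates into families
derived from common founders (default 10 families × 3 members at 55%
within-family identity, 10 gapless hits per member at 50–90% identity),
which is what gives held-out prediction its realistic difficulty: a
held-out member can only be predicted through relatives' synonymous
words.

Not emulated: e-value statistics, iterated profile search, compositional
bias, domain architecture, or real family phylogenies. Passing tests
therefore demonstrate the machinery's correctness and the qualitative
behaviour of the method (self-consistency, close-homolog recovery, the
word-length/matching trade-off, confidence→accuracy monotonicity), not
benchmark-level accuracy on real chains, which depends on dictionary
scale and real homolog retrieval.

## Problem sizes and numerical choices

The study and property suites run at desk scale chosen as the package's
own defaults: the word-length study uses a 30-template family pool with
10 hits per protein and 12 held-out targets over word lengths
{3, 4, 5, 6, 8, 10}; held-out recovery uses 20 templates with one
≥ 60%-identity target each; matching equivalence uses 10⁴-word
dictionaries. All randomness flows through a single seeded NumPy
generator per entry point, so every experiment is reproducible from its
seed. Vote totals are accumulated in float arrays but all scores are
integers, so argmax ties are exact, never epsilon-dependent.

## Known limitations

- Prediction quality collapses to the coil baseline when the dictionary
  contains no relatives of the target (by design: the method is
  homology-driven).
- The confidence denominator convention above is one of several
  reasonable readings; absolute confidence values are therefore only
  meaningful after calibration.
- Per-(word, source) aggregation keeps the maximum similarity level;
  pools where the same word recurs at many levels for one source lose
  the level distribution.
- The shared-word aligner is global; aligning a domain against a
  multi-domain chain would need local or semi-global variants.
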