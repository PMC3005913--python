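# synpss

Dictionary-based three-state protein secondary structure prediction from
**synonymous words**, with a confidence-calibrated two-predictor consensus
and a shared-word pairwise sequence aligner.

## The problem and the idea

Assigning each residue of a protein chain one of three secondary-structure
states — helix (H), strand (E) or coil (C) — from sequence alone is a
classic structural-bioinformatics task, scored by per-residue accuracy
(Q3) and the segment overlap measure (SOV). Most modern predictors learn
from position-specific profiles. `synpss` instead takes a
dictionary/nearest-neighbour view rooted in local sequence similarity:

- A **word** is an n-gram of a protein sequence (default n = 8).
- Given a protein *p* of known structure and a significant local alignment
  between *p* and a similar protein *sp*, every gap-free n-gram of *sp*
  aligned with an n-gram *w* of *p* is a **synonymous word** of *w*. It
  inherits the structure of *w* and carries a **similarity level**: the
  number of aligned positions whose BLOSUM62 score is positive
  (e.g. level(DFDM, EWQL) = 3).
- All words and synonymous words of a template pool are clustered into a
  protein-dependent dictionary mapping each word to per-source records
  `(structure, similarity level Sim_i, frequency freq_i)`.
- To predict a target *t*, its own word set (words + synonyms, with
  `freq_t`, `Sim_t`) is matched against the dictionary — exactly, or
  *inexactly* with at most one don't-care position — and each matched
  record votes its structure onto the covered residues with score

  ```
  s_i = min(freq_t, freq_i) × (1 + min(Sim_t, Sim_i))
  ```

  Per residue the state with the highest vote total wins (ties
  C > H > E), and a confidence level in 0–9 is the winning vote share of
  the maximum attainable score, rounded down.

Because synonymous words come from each protein's own set of similar
sequences, unrelated proteins rarely share them even when they share
identical n-grams — and remote homologs often share many, which the
`align` module exploits: counting the synonymous words shared by each
residue pair of two proteins yields a substitution surface for a global
dynamic-programming alignment that can align structurally similar pairs
far below the twilight zone of direct sequence identity.

Two further components round out the toolkit: an evaluation module
(Q3, per-observed-state recalls, SOV'99) and a meta-combiner that merges
two predictors per residue by transforming their confidence levels into
calibrated mean-Q3 accuracies.

## Worked example

Build a dictionary from a synthetic family-structured pool, hold one
member out, and predict it from its relatives' synonymous words:

```python
from synpss import (FamilyPoolConfig, PredictorConfig, ProteinChain,
                    build_dictionary, evaluate, exclude_sources,
                    generate_family_pool, predict)

chains, alignments = generate_family_pool(FamilyPoolConfig(seed=7))
dictionary = build_dictionary(chains, alignments, n=6)

target = chains[4]                              # held-out family member
view = exclude_sources(dictionary, [target.id])  # its own structure hidden
bare = ProteinChain(target.id, target.sequence)
pred = predict(bare, alignments[target.id], view,
               PredictorConfig(word_length=6, matching="inexact"))

rep = evaluate(pred.ss3, target.ss3)
print(pred.ss3[:60])
print(f"Q3 = {rep.q3:.1f}%  SOV = {rep.sov:.1f}%")
```

prints

```
CCCCCEECCCCCCCCCCECCCCCCHHCCCCHHHHHHHCCCCCCHHHHCCCHHHHHHHHHH
Q3 = 75.0%  SOV = 66.8%
```

i.e. 75% of the 132 residues are assigned the correct state purely by
looking up word matches inherited from the target's (diverged) relatives;
the SOV of 66.8% reflects some fragmented strand segments. Per-residue
confidence (`pred.confidence`, 0–9) marks which regions to trust.

The same pipeline is available from the shell:

```sh
synpss simulate --seed 7 --out sim/
synpss build --pool sim/pool.fasta --ss sim/pool.ss3 --aln sim/alignments \
             --word-length 8 --out pool.syn
synpss predict --target t.fasta --aln t_aln.tsv --dict pool.syn \
               --mode inexact --out t.pred
synpss evaluate --pred t.pred --truth sim/pool.ss3
```

plus `synpss combine` (calibrated consensus) and `synpss synalign`
(shared-word alignment with an exportable count matrix).

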