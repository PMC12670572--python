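# prnascreen

Structure-based identification and analysis of phi29-like packaging RNAs
(pRNAs).

The DNA-packaging motor of the *Bacillus* virus phi29 and its relatives is
geared by a small non-coding RNA, the packaging RNA (pRNA). Across viruses
the pRNA primary sequence diverges almost beyond recognition, yet its
secondary structure is strongly conserved: a thermodynamically stable
three-way junction (3WJ) from which two hairpin arms emanate, carrying the
right-hand (RH) and left-hand (LH) loops. Neighbouring subunits link
"hand-in-hand" — one subunit's RH loop base-pairs with the next subunit's
LH loop — closing a hexameric ring on the motor. Because sequence identity
decays while the fold persists, homology searches driven by primary
sequence miss family members that structure-aware searches find.

`prnascreen` implements that structure-first search and its companion
analyses as a tested, reusable pipeline for anyone studying structured
non-coding RNA families:

* **Folding and junction detection** — deterministic base-pair maximization
  (Nussinov-style dynamic programming, optional no-lonely-pairs mode) with
  a per-pair stability tie-break (G:C −3, A:U −2, G:U −1), loop
  decomposition, and 3WJ detection. Externally predicted structures can be
  supplied as dot-bracket wherever a fold is an input.
* **Loop pairing rules** — the string search for the maximal contiguous
  antiparallel Watson–Crick block between an RH and an LH loop, the
  GG/CC ± 0–2 A/U pattern classification, and the activity rules from
  loop-mutant packaging assays: a block of length ≥ 3 with a G:C,G:C core
  is active, and a length-2 block is active only if both pairs are G:C.
* **Ring-closure combinatorics** — mixtures of loop variants become a
  directed pairing graph (edge u→v when u's RH pairs v's LH actively);
  feasible ring sizes are closed-walk lengths. The classic complementation
  experiments fall out: two individually inactive cross-complementary
  species form rings of even size (period 2), three species in a directed
  triangle give multiples of 3, and the smallest size compatible with both
  is six — the stoichiometric argument for the hexamer.
* **Genome screening** — sliding-window scans of both strands that keep
  windows folding into the pRNA architecture (a 3WJ whose own two arms
  carry an actively pairing loop pair), with coverage, fold-score, and
  bulge-size filters, plus a seeded dinucleotide-shuffle empirical null and
  a naive exact-substring comparator.
* **Conservation statistics** — per-feature existence and
  sequence-similarity rates over annotated alignment regions (Bulge1/2/3,
  3WJ, the conserved ATP-binding G).
* **Motor-protein checks** — exact Smith–Waterman–Gotoh local alignment
  (BLOSUM62, gap open 11 / extend 1) of CDS translations against reference
  connector (gp10) and ATPase (gp16) proteins, reporting query coverage
  and percent identity.
* **Phylogenetic distances** — p/JC69 distance matrices, neighbor-joining
  trees, and patristic-distance reports (substitutions/site) relative to a
  reference leaf; external Newick trees are accepted directly.
* **Synthetic data with ground truth** — a generator for
  structure-conserved, sequence-divergent pRNA families (compensatory
  loop covariation), planted genomes, annotated alignments, and
  loop-variant activity panels.

## Worked example

Generate a pRNA-like element, diverge it with compensatory covariation,
plant the family in a random genome, and screen by structure:

```python
from prnascreen import (
    ScreenConfig, diverge, hexamer_verdict, make_loop_panel,
    max_complementary_block, merge_candidates, naive_sequence_search,
    plant_in_genome, predict_activity, recall, sample_prna, scan_genome,
)

inst = sample_prna(seed=7, name="example")
print(inst.record.residues)
print(inst.structure.dotbracket)
```

```
UGGUGUUAACCGAAAAACUAUACUAAAAAGGAUAGUAUAGUAAAAGCUCCGGGUCCUCCUCACCCGGAGCAAAACGGUUAACACCA
((((((((((((....(((((((((.......)))))))))....(((((((((.......)))))))))....))))))))))))
```

The closing helix encloses a three-way junction; the two hairpins carry the
RH loop `AAAAGGA` and LH loop `CCUCCUC`, whose maximal complementary block
is `AGGA:UCCU` — 4 pairs, 2 of them G:C, an active GG/CC-core pattern:

```python
block = max_complementary_block("AAAAGGA", "CCUCCUC")
print(block.length, block.n_gc, predict_activity(block))
# 4 2 ActivityCall(active=True, rule_fired='block_ge3')
```

Screen a 2-kb genome with two 30%-diverged copies planted at unknown loci:

```python
fam = [diverge(inst, rate=0.3, compensatory=True, seed=k, name=f"m{k}") for k in range(2)]
planted = plant_in_genome(fam, 2000, seed=42)
cfg = ScreenConfig(window_len=90, step=4)   # window matched to the 86-nt template
cands = merge_candidates(scan_genome(planted.genome, 86, cfg))
print(planted.truth)
print([(c.start, c.end, c.strand) for c in cands])
print(recall(cands, planted.truth))
print(naive_sequence_search(planted.genome, inst.record))
```

```
((607, 693, '+', 'm0'), (1613, 1699, '+', 'm1'))
[(111, 198, '+'), (607, 693, '+'), (1612, 1700, '+')]
1.0
[]
```

Both planted copies are recovered exactly (recall 1.0, plus one background
locus that genuinely folds into the architecture), while exact-substring
search finds nothing — at 30% divergence the primary sequence no longer
matches, but the structure does. Ring-closure combinatorics for the
two-species complementation mixture:

```python
species, _ = make_loop_panel("cross_pair")
v = hexamer_verdict(species)
print(sorted(v.feasible_sizes), v.minimal_cycle, v.hexamer_active)
# [2, 4, 6, 8, 10, 12] 2 True
```

## Command line

```bash
prnascreen simulate genome --seed 4 --n 1 --genome-len 1500 --out sim/
prnascreen screen --genome sim/genome.fasta --template-len 86 --out candidates.tsv
prnascreen ring --panel panel.tsv --max-n 12
prnascreen conserve --aln aln.fasta --features features.tsv --out table1.tsv
prnascreen protein-check --cds cds.faa --refs gp10.faa,gp16.faa
prnascreen phylo --aln aln.fasta --model jc69 --ref phi29 --out table2.tsv
```

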