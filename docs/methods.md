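# Methods

## Scope and modelling stance

The pipeline reproduces, at desk scale, the logic of a structure-first
search for packaging-RNA (pRNA) family members and the combinatorial and
statistical analyses built on it. It deliberately does not reimplement the
heavyweight machinery that production searches use — covariance models with
database-calibrated E-values, nearest-neighbor thermodynamic folding,
heuristic database alignment, or maximum-likelihood tree inference. Each of
those is replaced by a deterministic, oracle-testable primitive that
preserves the role the component plays in the pipeline; the pipeline's
correctness criteria are defined on structures and graphs, not on physical
energies or significance values.

## Secondary structure model

`fold_max_pairing` maximizes the number of Watson–Crick (+ optional G:U)
pairs over pseudoknot-free structures with a minimum hairpin loop of
`min_hairpin` unpaired bases (default 3). Among maximizers it minimizes an
additive per-pair pseudo-energy (G:C −3, A:U −2, G:U −1; dimensionless,
more negative = more stable), and residual ties are resolved in the
traceback by pairing the 5′-most position with its smallest admissible
partner — the output is a deterministic function of the input.

Two structure spaces are supported. The default (`min_helix=1`) is the
full pseudoknot-free space. With `min_helix=2` every helix must contain at
least two stacked pairs ("no lonely pairs"), computed with a second
dynamic program over helix-anchored states. The screen and the generator's
re-validation use `min_helix=2`: isolated single pairs are structurally
meaningless under pair maximization and routinely spawn spurious 1-bp
helices inside junctions, flipping a three-way junction's measured degree.
Both modes are tested against exhaustive enumeration of the corresponding
structure space.

G:U wobble pairs are allowed in helices by default (standard RNA
behaviour) and excluded from the loop–loop complementarity search by
default, where the covariation logic is framed in strict Watson–Crick
terms; both are flags.

`parse_junctions` decomposes a structure into hairpin loops,
internal/bulge loops, multiloops, and exterior positions (a partition of
all unpaired positions, property-tested). A three-way junction is a
multiloop of degree exactly 3, counting the closing helix.
`threeway_arm_hairpins` additionally requires the junction's two
non-closing arms to be unbranched helices ending in hairpins — the pRNA
architecture — and `enclosing_helix_span` reports the structural element's
extent by walking outward from the junction through stacks and interior
loops.

## Loop pairing and activity rules

`max_complementary_block` is an exact search for the longest contiguous
antiparallel complementary block between two loops (ties: more G:C pairs,
then smallest offsets), checked against brute force over all substring
pairs. The activity rules encode the loop-mutant packaging assays: a block
of length ≥ 3 is called active only when it carries two adjacent G:C pairs
(the GG/CC core; all experimentally active natural blocks follow the
GG/CC ± 0–2 A/U pattern), and a length-2 block is active only when both
pairs are G:C (rationalized by the higher melting temperature of G:C). A
length ≥ 3 all-A/U block is untested experimentally; calling it inactive
is a documented assumption of this package.

## Ring-closure model

A mixture of loop variants defines a directed graph with an edge u→v when
u's RH loop forms an active block with v's LH loop. Because a mixture
supplies unlimited copies of each species, a ring of n subunits is a
closed directed walk of length n (one species may occupy alternating
positions); feasible sizes are computed by boolean adjacency powers and
checked against explicit walk enumeration. `max_n` defaults to 12, the
hexamer plus one harmonic. Whether real heterogeneous rings mix species
beyond planned alternation is not asserted; the walk model permits it.

## Genome screen

Windows slide over both strands (default window 120 nt — the pRNA domain-1
scale — and step 10, both configurable). A window becomes a candidate iff
its fold (no-lonely-pairs maximization) contains a three-way junction
whose own two arm hairpins, within length bounds 3–10, form an active
complementary block of length ≥ 3; no interior/bulge loop spans more than
30 nt; the fold score is at most −20; and the junction's enclosing-helix
span covers at least 80% of the template length. The E-value of a
calibrated homology search is not reproducible here; the score threshold
plus an optional empirical null (score percentile against 100 seeded
dinucleotide-preserving shuffles) preserve the filter's role. Coverage is
interpreted as matched span over template length — the denominator is not
stated in the original criteria and is recorded here as an interpretation.

Because pair maximization is a global criterion, a window much longer than
the element can be restructured by flanking sequence; screens should use a
window close to the expected element length (the synthetic benchmark uses
window 90 / step 4 for its 86-nt template). Overlapping candidates are
merged transitively at interval Jaccard ≥ 0.5, keeping the best-scoring
representative.

On 3-kb i.i.d. backgrounds the screen emits roughly 0–4 background
candidates per genome — windows that genuinely satisfy the structural
criteria; specificity against random sequence is not a design goal, recall
on structure-conserved elements is.

## Synthetic data

The generator emulates the study inputs with known ground truth. The
scaffold (defaults: closing helix 12 bp, arm helices 9 bp, loops 7 nt,
junction spacers 4 nt, ~86 nt total) abstracts pRNA domain 1 to one 3WJ
with two loop-bearing arms; the real molecule has additional helices and
the CCA bulge, which is represented only as an annotated unpaired tract.
The designed RH/LH block is one of GG/CC ± 0–2 A/U additions (default
AGGA:UCCU).

Letter discipline makes the designed fold the pairing optimum: the RH loop
is purine-only, the LH loop pyrimidine-only (neither can pair internally),
spacers are all A, and a few helix boundary bases are constrained to
classes that remove equal-score re-pairings into adjacent loops. Helices
are otherwise random over the full alphabet and exact reverse complements
of their partners. Every sampled instance is re-validated by folding
(the screen's own architecture criterion); about 15–20% of raw draws fail
and are resampled from the same seeded stream, so all emitted instances
validate.

Compensatory divergence models the observed loop covariation: every
substitution is a transition (A↔G, C↔U), and substitutions at paired
positions (helices and the designed block) apply the complementary
transition to the partner. Transitions preserve the purine/pyrimidine
letter discipline, so structure recovery survives high rates; draws that
nevertheless break recovery or block activity (e.g. a transition
dissolving the G:C core) are redrawn. Non-compensatory divergence
substitutes sites independently over the full alphabet with no
preservation — the mode that destroys hand-in-hand pairing.

What passing tests therefore show: the screen recovers elements whose
architecture is exactly conserved under heavy sequence divergence, the
regime the biological claim is about. They do not show robustness to
indels, to partially degraded architectures, to non-transition divergence
of real families, or to realistic genomic background composition (the
default background is i.i.d. with configurable GC; a dinucleotide
background is available for the null).

`make_alignment` exploits that family members share the scaffold, so
columns align by construction (no aligner is involved). Feature regions:
Bulge1 = RH loop, Bulge3 = LH loop, Bulge2 = a junction spacer (the
CCA-relevant-bulge stand-in), 3WJ = all junction spacer columns,
critical_G = the conserved G column fixed mid-arm on the LH arm's 3′
strand. Options force pairwise-distinct loop strings (redrawing members),
k-of-n feature occupancy (gapping rows), or k-of-n conservation of the
critical G.

## Conservation statistics

Existence rate = percent of rows whose feature columns are all non-gap.
Similarity rate = percent of rows (full row count as denominator) whose
region string equals the region's modal string among occupied rows, with
two conventions: 0% when all occupied region strings are pairwise
distinct, and 100% when at most one row is occupied. This single
definition reproduces both published regimes — 0% for the all-distinct
bulges and 92% (= 46/50) for the near-universal conserved G — whether the
four deviating rows diverge or are absent. Comparison is case-insensitive
with T ≡ U; modal ties break lexicographically.

## Protein similarity

Exact Smith–Waterman–Gotoh local alignment with BLOSUM62 and affine gaps
(a gap of length k costs 11 + k); the traceback takes the best cell with
the smallest indices and prefers diagonal, then up, then left. Percent
identity defaults to identical columns over all alignment columns (gaps in
the denominator); the reference-length denominator is available because
published descriptions of the metric are ambiguous between the two. The
co-occurrence check passes when every reference protein's best CDS hit
reaches 50% query coverage and 25% identity (configurable; no thresholds
are stated in the source analyses, these are conservative homology-call
values).

## Phylogenetic distances

Pairwise distances use pairwise deletion (mutually non-gap columns;
complete deletion is a flag) under the p or JC69 model,
d = −(3/4)·ln(1 − 4p/3), infinite (or an error in strict mode) at
saturation p ≥ 3/4. Trees come from standard neighbor joining (negative
branch lengths clamped to 0 and logged); on additive matrices the realized
patristic distances equal the input to 1e−9 (property-tested on random
trees). The patristic report lists path-length sums from a reference leaf
in substitutions/site; externally inferred trees in Newick format can be
reported directly, so a maximum-likelihood tree can be substituted without
touching the rest of the pipeline.

## Numerical and interface choices

Coordinates are 0-based half-open internally, 1-based only in
human-readable reports. RNA is canonicalized to uppercase AUCG with a
logged T→U conversion on read. All randomness flows from seeded NumPy
generators; identical seeds give byte-identical outputs. The folding
kernels are compiled with numba when available, with a pure-Python
fallback. Feature maps travel as a sidecar TSV (name, comma-separated
0-based columns) rather than a display-oriented annotation format.

## Known limitations

* Pair maximization is not a thermodynamic model: energies are
  pseudo-scores, there is no temperature/ionic dependence, no suboptimal
  ensembles, and no pseudoknots.
* The loop–loop search is contiguous-block only; bulged kissing
  interactions are out of scope.
* `eligible_loop_pairs` enumerates hairpin loops only; unpaired tracts at
  helix termini are not considered loop candidates.
* The screen's candidate unit is a folded window; elements longer than the
  window, split by indels, or with architectures beyond "one 3WJ + two
  arm hairpins" are not detected.
* Activity is binary; plaque-count magnitudes are consumed only as labels.
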