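# Methods

This note documents the models, algorithms and numerical choices behind
`snofamkit`, and what the simulation-based tests do and do not establish.

## Box annotation

Boxes are located by degenerate (IUPAC) pattern matching; two codes match
when their base sets intersect, and a window is a hit when its mismatch
count stays within the per-box budget. Defaults: C `RUGAUGA` (≤1
mismatch), D `CUGA` (≤1), internal C'/D' one extra mismatch each
(reflecting their higher variability), H `ANANNA` (exact on the three A
positions), ACA exact and anchored to the last 3 nt of the mature
sequence. All budgets and windows are `BoxParams` fields.

For box C/D candidates the C box must start within the first 10 nt and
the D box end within the last 10 nt. Internal D'/C' boxes are optional;
a candidate combination is scored

    score = box_bonus · n_optional − Σ mismatches − w · Σ |spacer − 12|

with `box_bonus = 2.0` and `w = 0.25`, where the spacers are C→D' and
C'→D and 12 nt is the typical spacing. The bonus term exists because a
pure penalty score would never include an optional box; with it, an exact
internal box at near-optimal spacing is always annotated while heavily
mismatched placements are not. Spacers are accepted in [2, 60] —
soft-scored, not hard-filtered, to keep divergent true positives. Ties
break toward fewer mismatches, then the 5'-most placement.

For box H/ACA candidates the ACA must terminate the sequence exactly and
the H box is searched in the hinge window [0.35·L, 0.65·L], preferring
fewest mismatches, then centrality.

## Structure checks

*Terminal stem (C/D)*: the longest contiguous antiparallel complementary
run (Watson-Crick + GU) between the ≤6 nt upstream of the C box and the
≤6 nt downstream of the D box; pass at ≥3 pairs. A K-turn-style G:A
apposition of the box-flanking residues is reported but not required
(config switch, off by default), since it is an assembly feature rather
than an annotation filter.

*Hairpin topology (H/ACA)*: the 5' segment (before H) and 3' segment
(between H and ACA) are folded independently by base-pair-maximising
dynamic programming (minimum hairpin loop 3, WC+GU, H and ACA positions
held unpaired). Two variants exist:

- `nussinov` — exact maximum pairing, with ties broken toward the most
  stacked structure. This is the oracle-checked primitive (equal to
  exhaustive structure enumeration on all small strings in the tests).
- `nussinov_helices` — the same objective restricted to structures built
  from helices of ≥ `min_helix` (default 3) stacked pairs; isolated pairs
  score nothing. The topology check uses this variant, because under pure
  pair maximisation a single point substitution that opens one stray
  complementary pair can outweigh and reshuffle a well-stacked fold,
  destroying pocket detection even though the designed architecture is
  intact. Restricting to helices is the discrete analogue of
  stacking-dominated energy folding.

A hairpin passes when a root-to-terminal-loop pair chain has ≥5 pairs and
contains an interior loop with ≥3 unpaired nt on each side (the
pseudouridylation pocket). Both hairpins must pass.

Classification attempts both annotations and ranks candidates by
(structure passed, box score), ties toward C/D; random 150-mers classify
with a passing structure in <1% of cases at the defaults.

## Homology search

Seeding is exact-word matching (default word 9, both strands) of any
query member against the genome; hit windows are padded by the query
length and merged. Extension is local Smith-Waterman with affine gaps
(match +2, mismatch −3, gap of length k costs 5 + 2k), computed with
Biopython's `PairwiseAligner`; an independent quadratic DP serves as the
test oracle. Candidates then pass: identity ≥0.55 over ≥60% of the query;
box annotation; structure check; trimming to mature bounds (terminal-stem
ends for C/D, first paired position to the ACA for H/ACA, with the 3' pad
cut back to the nearest terminal ACA first); re-annotation of the trimmed
sequence. Overlapping retained candidates within a family resolve to the
higher score; across families, each locus is assigned to the single
best-scoring family (best-hit assignment) — without this, closely related
families within a class would each claim every gene. Searches iterate
(default 2 rounds): each round re-searches with the query set grown by
the previous round's finds, so homologs reachable only through
intermediate species are picked up. The search path contains no
randomness.

Family alignments anchor boxes of like kind into common columns and align
the inter-anchor segments progressively (exact sum-of-pairs optimum for
up to three members, centre-star beyond that; guide order by identity to
the family's most representative member). `#=GC Boxes` uses C/D/d/c/H/A
letters, `#=GC SS_cons` maps the guide member's structure-check pairs to
columns. Stockholm files are written in a canonical single-block form so
round trips are byte-stable.

## Target prediction

C/D antisense elements are the ≤15 nt immediately 5' of the D and D'
boxes; H/ACA guides are the interior-loop halves of each hairpin. The
duplex model is ungapped antiparallel WC+GU complementarity — chosen over
structural alignment so that every prediction is reproducible by direct
window enumeration. Scan thresholds default to ≥10 pairs with ≤2
unpaired for C/D (≤1 unpaired across both pocket half-duplexes for
H/ACA), but a *called* site additionally requires a fully paired duplex
(`call_min_score = 1.0`): with wobble pairs allowed, a ≤2-unpaired
12-mer window matches random RNA about every 600 nt, which would flood
orphan detection with chance hits. The modified residue follows the +5
rule for C/D (config-exposed offset) and is the first hinge nucleotide
between the H/ACA half-duplexes, which must be a U. The canonical
13–17 nt pocket-to-box distance constraint is not enforced by default;
the generator places pockets within hairpins of fixed geometry, so the
constraint would be untestable here — it can be added as a filter by
callers working with real annotation.

Conservation tables classify each pair column across species as
`conserved_pair` (same pair everywhere), `compensatory` (paired
everywhere, ≥2 pair identities) or `lost` (unpaired in ≥1 row while the
majority pair), and render rows as `targetSegment&ASE` with a single `M`
marker column and the predicted position at the row end.

## Clusters

Single-linkage chaining of genes along a chromosome with inter-gene gap ≤
2000 nt (strand ignored by default — assemblies mapped by homology may be
flipped). A cluster's signature is the sorted family multiset
(copy-number-sensitive). Cross-species matching merges instances sharing
≥2 families, greedily by overlap; the conserved core is the multiset
intersection. Member families are dated by the LCA of the cluster-bearing
species that carry them.

## Gain/loss reconstruction

Per family, the origin is the LCA of all species with a positive count
(single-origin Dollo assumption). Ancestral copy numbers are computed by
Sankoff dynamic programming over states {0..max observed count} within
the origin subtree, with branch cost |parent − child|, the Dollo side
condition that a 0-copy ancestor never regains the family, and origin
state ≥1; states above the observed maximum cannot reduce a linear cost,
so the default ceiling is exact. Ties break toward the smallest ancestral
state, which prefers late duplication over early duplication plus loss.
The founding gain is recorded on the branch entering the origin and is
not costed. Node summaries count families present / gained / lost per
node and satisfy observed(child) = observed(parent) + gained − lost
everywhere; gains and losses are weighted symmetrically (a config pair
allows asymmetric weights). Species without a genome in the run should be
pruned from the tree before inference rather than coded as 0, since
absence of evidence is not loss.

## Synthetic data

The generator emulates the statistical structure the analysis assumes,
with full ground truth. Key design points:

- **Archetypes from the grammar.** C/D: 5 nt leader + C + 12 nt ASE + D'
  + 10 nt spacer + C' + 12 nt ASE + D + 5 nt tail, with leader and tail
  complementary (the terminal stem). H/ACA: two
  stem(5)-pocket(7)-stem(5)-loop(4) hairpins around an H-box hinge and a
  terminal ACA. H/ACA stems are G/C, loops and 3' pocket halves all-A,
  and the gene contains no U, so the G and C counts balance exactly and
  the designed fold is the unique base-pair maximum; guide diversity
  lives in the 5' pocket halves (A/C alphabet, no partner in the
  hairpins). Every archetype is verified at build time by running the
  actual annotation, classification and trimming code on a buffered copy.
- **Histories.** One copy at the origin; on each branch each copy is
  lost with probability `p_loss` (default 0.1), otherwise duplicates with
  probability `p_dup` (default 0.1). Extinct families are resampled so
  every emitted family is observable (count logged).
- **Evolution.** Site-wise substitutions at rate μ per branch; conserved
  elements (boxes, guide elements, stems — everything except spacers and
  hinge flanks) mutate at μ·ρ with ρ = 0.05, reflecting the near
  invariance of boxes and guides across real families. No indels by
  default (probability config-exposed).
- **Genomes.** One chromosome per species; 40% of families grouped four
  at a time into clusters with 100–500 nt spacing, everything else placed
  with ≥2.5 kb of background between units so unrelated genes never chain
  into a cluster. Planted genes are flanked by 3 nt neutral buffers
  (`AAA`, orientation-adjusted) that cannot extend the terminal stem or
  the hairpins — this keeps mature trimming, and hence coordinate
  recovery, exact at zero divergence. Background is i.i.d. with
  configurable GC.
- **Targets.** One rRNA-like molecule (default 1800 nt) carrying, per
  non-orphan family, the reverse complement of its guide at a recorded
  position (for H/ACA: 3'-half complement, U + spacer, 5'-half
  complement); 10% of families are designated orphans and get no site.
  The assembled target is verified: each planted site is its family's
  unique fully-paired hit and orphan guides have none, else the
  background is resampled.

Everything is driven by one `numpy` generator; identical configs give
byte-identical outputs.

**What the simulations do not capture:** real intergenic sequence
composition and repeats, indels in mature snoRNAs, intronic/host-gene
context, genome rearrangements, covariance-model-level remote homology,
and thermodynamic duplex stability. Passing recovery tests therefore
demonstrates internal consistency of the pipeline under the stated
evolutionary model, not field performance on real assemblies.

## Problem sizes used in the test suite

Oracle sweeps run at sizes where exhaustive enumeration is exact and
fast: all rooted bifurcating shapes with ≤6 leaves × all count vectors
over {0..3} for the parsimony oracle; all G/C strings to length 12 plus
400 random 4-letter strings to length 20 for folding; 1,000 random 200-nt
sequences × 6 patterns for motif matching; 500 random pairs for the
alignment oracle. End-to-end runs use 8 species × 20 families (seed 42)
at μ = 0 and μ = 0.10, and a 200-family birth/death cohort for origin
recovery. On the origin-recovery statistic: a family whose single
founding copy is lost on a basal branch leaves no trace, so even the
optimal estimator (the carrier LCA) misses it; the expected recovery at
`p_loss = 0.1` is ≈0.91 with realisations either side of 0.90 depending
on the seed.
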