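# snofamkit

Comparative genomics of plant small nucleolar RNA (snoRNA) families:
annotation of box C/D and box H/ACA snoRNAs, homology search across
genomes, rRNA/snRNA target prediction, genomic cluster analysis, and
Dollo-parsimony reconstruction of per-branch family gains and losses on a
species tree.

## The problem

snoRNAs guide chemical modification of ribosomal and spliceosomal RNAs.
Box C/D snoRNAs carry a C box (consensus `RUGAUGA`) near the 5' end and a
D box (`CUGA`) near the 3' end, often with more variable internal C'/D'
copies, and direct 2'-O-methylation: the modified target nucleotide is the
one paired with the fifth guide nucleotide upstream of the D (or D') box —
the "+5 rule". Box H/ACA snoRNAs fold into a hairpin-hinge-hairpin-tail
architecture with an H box (`ANANNA`) in the hinge and a terminal `ACA`;
the interior loop ("pseudouridylation pocket") of each hairpin clamps the
target around the isomerised uridine. In plants, snoRNA genes frequently
sit in polycistronic genomic clusters.

Given query families, genomes, target RNAs and a species tree, `snofamkit`

1. finds candidate loci by exact-word seeding + Smith-Waterman extension,
2. filters them by identity/coverage, box annotation (degenerate-pattern
   matching with per-box mismatch budgets and spacer scoring around the
   typical 12 nt) and class-specific structure checks (terminal stem for
   C/D; constrained base-pair-maximisation hairpin/pocket topology for
   H/ACA),
3. builds box-anchored family alignments in Stockholm format with a
   `#=GC Boxes` column annotation,
4. predicts modification sites by ungapped antiparallel WC+GU duplexes and
   renders cross-species conservation tables,
5. detects and matches genomic clusters, and
6. reconstructs each family's history with Dollo-constrained linear-cost
   Sankoff parsimony over copy numbers: the family originates once, at the
   last common ancestor of the species that carry it; ancestral copy
   numbers minimise the total |parent − child| branch cost; per-branch
   gains and losses and per-node summaries follow.

A fully ground-truthed synthetic-data generator
(`snofamkit.synthetic_data`) stands in for real genome cohorts: it builds
archetype genes from the box grammar itself, evolves them along a
simulated species tree under a birth/duplication/loss process with
conserved elements mutating more slowly than background, plants them
(optionally clustered) into random genomes, and embeds complementary
modification sites in a target RNA.

## Worked example

```python
from snofamkit.synthetic_data import SimConfig, simulate_dataset
from snofamkit.pipeline import build_queries_from_truth, run_pipeline

cfg = SimConfig(seed=7, n_species=5, n_cd_families=3, n_haca_families=2,
                genome_length=30_000, mu=0.02)
ds = simulate_dataset(cfg)
res = run_pipeline(build_queries_from_truth(ds), ds.genomes, ds.targets, ds.tree)
print(res.matrix)
```

prints the paralog count matrix (families × species, tree leaf order;
`conserved` marks families found in more than one species):

```
         sp3  sp4  sp5  sp1  sp2  conserved
cd001      1    2    1    0    1       True
cd002      1    1    1    0    1       True
cd003      1    1    1    1    1       True
haca004    1    1    1    1    1       True
haca005    2    1    1    1    2       True
```

The reconstructed history of family `cd001`
(`res.histories["cd001"]`) reads: origin `N1` (the root), total cost 2,
per-branch events `{'N1': (1, 0), 'sp4': (1, 0), 'sp1': (0, 1)}` — the
family was born at the root, duplicated on the branch to `sp4` and lost on
the branch to `sp1`, which matches the count row above. The cross-species
target table for `cd001` (via
`snofamkit.target_prediction.build_conservation_table`) renders in the
target`&`guide dialect with the methylated residue marked `M` and the
predicted position at the end of each row:

```
         M
sp2  AUAUGAGCCAAA&UUUGGCUCAUAU  71
sp3  AUAUGAGCCAAA&UUUGGCUCAUAU  71
sp4  AUAUGAGCCAAA&UUUGGCUCAUAU  71
sp5  AUAUGAGCCAAA&UUUGGCUCAUAU  71
     CCCCCCCCCCCC
     ############
```

(the `C` line classifies every pair column as conserved; the bar below is
per-column sequence conservation).

A command-line interface mirrors the library:
`snofamkit simulate`, `snofamkit annotate`, `snofamkit search`,
`snofamkit targets`, `snofamkit clusters`, `snofamkit evolve` — run any of
them with `--help`.

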