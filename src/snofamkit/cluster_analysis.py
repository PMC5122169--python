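"""Genomic snoRNA clusters: detection, cross-species matching, origins.

Plant snoRNAs are frequently encoded in polycistronic clusters — several
genes within a short chromosomal region transcribed as one unit. Clusters
are detected by single-linkage chaining of genomic coordinates (strand
ignored by default, since homology-mapped assemblies may be flipped),
identified across species by their family-composition signature, and each
member family is annotated with its gain/loss origin node on the species
tree.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import dendropy

from snofamkit.core_io import GenomicInterval, SnoGene, node_label


@dataclass
class ClusterInstance:
    species: str
    chrom: str
    member_ids: list[str]       # genomic order
    families: list[str]         # same order; "" -> UNKNOWN in the signature
    span: GenomicInterval
    max_internal_gap: int

    @property
    def signature(self) -> tuple[str, ...]:
        return cluster_signature(self)


def detect_clusters(
    genes: list[SnoGene], max_gap: int = 2000, same_strand: bool = False
) -> list[ClusterInstance]:
    """Single-linkage chaining: consecutive genes on a chromosome whose
    inter-gene gap is <= ``max_gap`` join one cluster; singletons drop."""
    out: list[ClusterInstance] = []
    keyfn = lambda g: (g.species, g.interval.chrom, g.interval.strand if same_strand else "")
    groups: dict[tuple, list[SnoGene]] = {}
    for g in genes:
        groups.setdefault(keyfn(g), []).append(g)
    for (species, chrom, _), members in sorted(groups.items()):
        members.sort(key=lambda g: (g.interval.start, g.interval.end))
        chain: list[SnoGene] = [members[0]]
        for g in members[1:]:
            gap = g.interval.start - chain[-1].interval.end
            if gap <= max_gap:
                chain.append(g)
            else:
                _emit(out, species, chrom, chain)
                chain = [g]
        _emit(out, species, chrom, chain)
    return out


def _emit(out: list[ClusterInstance], species: str, chrom: str, chain: list[SnoGene]) -> None:
    if len(chain) < 2:
        return
    gaps = [
        b.interval.start - a.interval.end for a, b in zip(chain, chain[1:])
    ]
    out.append(
        ClusterInstance(
            species=species,
            chrom=chrom,
            member_ids=[g.gene_id for g in chain],
            families=[g.family for g in chain],
            span=GenomicInterval(chrom, chain[0].interval.start, chain[-1].interval.end),
            max_internal_gap=max(gaps),
        )
    )


def cluster_signature(cluster: ClusterInstance) -> tuple[str, ...]:
    """Canonical composition signature: sorted family multiset, order- and
    strand-insensitive but copy-number-sensitive."""
    return tuple(sorted(f if f else "UNKNOWN" for f in cluster.families))


@dataclass
class ConservedCluster:
    """A cluster composition seen in >=2 species."""

    signature: tuple[str, ...]          # shared (core) family multiset
    instances: list[ClusterInstance]
    presence: dict[str, list[ClusterInstance]] = field(default_factory=dict)
    origins: dict[str, str] = field(default_factory=dict)  # family -> node label

    @property
    def species(self) -> list[str]:
        return sorted(self.presence)


def _shared(a: tuple[str, ...], b: tuple[str, ...]) -> int:
    return sum((Counter(a) & Counter(b)).values())


def match_clusters(
    instances: list[ClusterInstance], min_shared: int = 2
) -> list[ConservedCluster]:
    """Group cluster instances across species by shared family content.

    Greedy union: instance pairs are merged largest-overlap first (ties by
    lexicographic signatures) whenever they share >= ``min_shared``
    families; groups spanning >=2 species become ConservedClusters.
    """
    n = len(instances)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    pairs = []
    for i in range(n):
        for j in range(i + 1, n):
            ov = _shared(instances[i].signature, instances[j].signature)
            if ov >= min_shared:
                pairs.append((-ov, instances[i].signature, instances[j].signature, i, j))
    pairs.sort()
    for _, _, _, i, j in pairs:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj

    groups: dict[int, list[ClusterInstance]] = {}
    for i, inst in enumerate(instances):
        groups.setdefault(find(i), []).append(inst)

    out = []
    for members in groups.values():
        if len({m.species for m in members}) < 2:
            continue
        core = Counter(members[0].signature)
        for m in members[1:]:
            core &= Counter(m.signature)
        presence: dict[str, list[ClusterInstance]] = {}
        for m in members:
            presence.setdefault(m.species, []).append(m)
        out.append(
            ConservedCluster(
                signature=tuple(sorted(core.elements())),
                instances=sorted(members, key=lambda m: (m.species, m.chrom, m.span.start)),
                presence=presence,
            )
        )
    out.sort(key=lambda c: c.signature)
    return out


def cluster_member_origins(
    conserved: ConservedCluster,
    tree: dendropy.Tree,
    histories: dict[str, object],
) -> dict[str, str]:
    """Per-family origin: the LCA of the cluster species that carry the
    family, a restriction of the family's Dollo origin to this cluster."""
    origins = {}
    families = sorted(set(f for inst in conserved.instances for f in inst.families))
    for fam in families:
        if fam not in histories:
            raise ValueError(f"no gain/loss history for family {fam}")
        carriers = sorted(
            sp for sp, insts in conserved.presence.items()
            if any(fam in inst.families for inst in insts)
        )
        if len(carriers) == 1:
            leaf = tree.find_node_with_taxon_label(carriers[0])
            origins[fam] = node_label(leaf)
        else:
            mrca = tree.mrca(taxon_labels=carriers)
            origins[fam] = node_label(mrca)
    conserved.origins = origins
    return origins
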