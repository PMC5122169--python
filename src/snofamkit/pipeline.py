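"""End-to-end orchestration: simulate or load inputs, search, annotate,
predict targets, detect clusters and reconstruct gain/loss histories."""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import pandas as pd

from snofamkit.cluster_analysis import (
    ClusterInstance,
    ConservedCluster,
    cluster_member_origins,
    detect_clusters,
    match_clusters,
)
from snofamkit.core_io import SeqRecord, SnoGene
from snofamkit.homology_search import (
    FamilyQuery,
    SearchParams,
    SearchResult,
    build_family_query,
    iterate_search,
)
from snofamkit.phylo_evolution import (
    GainLossHistory,
    build_presence_matrix,
    sankoff_counts,
    summarize_families,
)
from snofamkit.synthetic_data import SimulatedDataset
from snofamkit.target_prediction import DuplexParams, TargetSite, mark_orphans, predict_targets


@dataclass
class PipelineResult:
    search: SearchResult
    genes: dict[str, list[SnoGene]]
    clusters: dict[str, list[ClusterInstance]]
    conserved_clusters: list[ConservedCluster]
    sites: dict[str, list[TargetSite]]
    orphans: list[str]
    matrix: pd.DataFrame
    histories: dict[str, GainLossHistory]
    summary: pd.DataFrame


def build_queries_from_truth(ds: SimulatedDataset) -> list[FamilyQuery]:
    """One query per family, seeded from the first species (tree leaf
    order) that carries the family — the 'reference annotation' species."""
    queries = []
    for fam, simfam in ds.families.items():
        ref = next(sp for sp in ds.species if ds.truth.histories[fam].leaf_counts.get(sp, 0) > 0)
        members = [
            SeqRecord(id=g.gene_id, seq=g.seq)
            for g in ds.truth.genes[ref]
            if g.family == fam
        ]
        queries.append(
            build_family_query(fam, simfam.archetype.sno_class, members)
        )
    return queries


def run_pipeline(
    queries: list[FamilyQuery],
    genomes: dict[str, list[SeqRecord]],
    targets: list[SeqRecord],
    tree: dendropy.Tree,
    search_params: SearchParams | None = None,
    duplex_params: DuplexParams | None = None,
    max_gap: int = 2000,
) -> PipelineResult:
    search_params = search_params or SearchParams()
    duplex_params = duplex_params or DuplexParams()

    result = iterate_search(queries, genomes, search_params)

    all_genes = [g for sp in sorted(result.genes) for g in result.genes[sp]]
    clusters = {
        sp: detect_clusters(result.genes[sp], max_gap) for sp in sorted(result.genes)
    }
    instances = [c for sp in sorted(clusters) for c in clusters[sp]]
    conserved = match_clusters(instances)

    sites = predict_targets(all_genes, targets, duplex_params)
    families = [q.family_id for q in queries]
    orphans = mark_orphans(families, sites)

    matrix = build_presence_matrix(result.counts, tree)
    histories = {}
    for fam in matrix.index:
        leaf_counts = {sp: int(matrix.loc[fam, sp]) for sp in matrix.columns if sp != "conserved"}
        histories[fam] = sankoff_counts(tree, leaf_counts, family=fam)
    summary = summarize_families(list(histories.values()), tree)

    for cc in conserved:
        try:
            cluster_member_origins(cc, tree, histories)
        except ValueError:
            pass

    return PipelineResult(
        search=result,
        genes=result.genes,
        clusters=clusters,
        conserved_clusters=conserved,
        sites=sites,
        orphans=orphans,
        matrix=matrix,
        histories=histories,
        summary=summary,
    )
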