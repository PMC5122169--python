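"""Ground-truthed synthetic inputs for the snoRNA pipeline.

The generator emulates the statistical structure of the real inputs — a
species tree, snoRNA families born at some ancestral node that duplicate
and get lost along branches, sequences whose boxes, antisense elements and
structural stems are under much stronger conservation than background,
genomes with (optionally clustered) planted copies, and target RNAs with
complementary modification sites — while recording complete ground truth.

Archetype genes are built from the box grammar itself (leader + C box +
ASE + D' box + ... + D box + stem tail for box C/D; stem-pocket-stem
hairpins around an H box and terminal ACA for box H/ACA), so no external
sequence data is needed. Planted genes are flanked in the genome by short
neutral buffers that cannot extend the terminal stem, which keeps mature
trimming — and therefore coordinate recovery — exact at zero divergence.

Everything is driven by one :class:`numpy.random.Generator`; identical
configs give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np

from snofamkit.box_annotation import BoxParams, BoxSet, annotate_cd_boxes, annotate_haca_boxes, classify_snoRNA
from snofamkit.core_io import (
    GenomicInterval,
    SeqRecord,
    SnoGene,
    node_label,
    parse_newick,
    revcomp_rna,
    write_fasta,
    write_gff3,
    write_newick,
)
from snofamkit.target_prediction import DuplexParams, extract_ase, duplex_scan

RNA = "ACGU"


@dataclass
class SimConfig:
    seed: int = 42
    n_species: int = 8
    tree_newick: str | None = None      # overrides the random tree if given
    n_cd_families: int = 12
    n_haca_families: int = 8
    p_dup: float = 0.1                  # per-copy per-branch duplication prob
    p_loss: float = 0.1                 # per-copy per-branch loss prob
    mu: float = 0.0                     # per-branch per-site substitution prob
    rho: float = 0.05                   # rate multiplier inside conserved elements
    indel_prob: float = 0.0             # per-branch indel prob in spacers
    origin_mode: str = "root"           # "root" | "random"
    genome_length: int = 60_000         # minimum background length per species
    gc: float = 0.5
    cluster_fraction: float = 0.4       # fraction of families placed in clusters
    cluster_size: int = 4
    cluster_spacing: tuple[int, int] = (100, 500)
    intergenic_spacing: tuple[int, int] = (2500, 4000)
    target_length: int = 1800
    orphan_fraction: float = 0.1
    max_retries: int = 50

    def __post_init__(self) -> None:
        for p in (self.p_dup, self.p_loss, self.mu, self.rho, self.gc,
                  self.cluster_fraction, self.orphan_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Species tree


def simulate_tree(n_species: int, rng: np.random.Generator) -> dendropy.Tree:
    """Random rooted bifurcating tree by uniform pairwise joins
    (coalescent-style): repeatedly merge two uniformly chosen lineages."""
    if n_species < 2:
        raise ValueError("need at least 2 species")
    lineages = [f"sp{i + 1}" for i in range(n_species)]
    while len(lineages) > 1:
        i, j = sorted(rng.choice(len(lineages), size=2, replace=False))
        merged = f"({lineages[i]},{lineages[j]})"
        lineages = [l for k, l in enumerate(lineages) if k not in (i, j)] + [merged]
    return parse_newick(lineages[0] + ";")


# ---------------------------------------------------------------------------
# Family histories


@dataclass
class FamilyHistory:
    family: str
    origin: str
    node_counts: dict[str, int]
    branch_events: dict[str, tuple[int, int]]   # node -> (gained, lost) on entering branch
    leaf_counts: dict[str, int]
    fates: dict[str, list[int]] = field(default_factory=dict)  # node -> offspring per parent copy

    @property
    def identifiable_origin_leaves(self) -> list[str]:
        return sorted(sp for sp, c in self.leaf_counts.items() if c > 0)


def simulate_family_history(
    tree: dendropy.Tree,
    origin: dendropy.Node,
    p_dup: float,
    p_loss: float,
    rng: np.random.Generator,
    family: str = "",
) -> FamilyHistory:
    """One copy at the origin; on each branch below it every copy is lost
    with prob ``p_loss``, else duplicates (one extra copy) with ``p_dup``."""
    node_counts: dict[str, int] = {}
    branch_events: dict[str, tuple[int, int]] = {}
    fates: dict[str, list[int]] = {}
    counts: dict[dendropy.Node, int] = {}
    subtree = set(origin.preorder_iter())
    for node in tree.preorder_node_iter():
        lbl = node_label(node)
        if node not in subtree:
            node_counts[lbl] = 0
            branch_events[lbl] = (0, 0)
            continue
        if node is origin:
            counts[node] = 1
            node_counts[lbl] = 1
            branch_events[lbl] = (1, 0)
            continue
        parent = counts[node.parent_node]
        fate: list[int] = []
        for _ in range(parent):
            if rng.random() < p_loss:
                fate.append(0)
            else:
                fate.append(2 if rng.random() < p_dup else 1)
        surv = sum(fate)
        fates[lbl] = fate
        counts[node] = surv
        node_counts[lbl] = surv
        d = surv - parent
        branch_events[lbl] = (max(d, 0), max(-d, 0))
    leaf_counts = {
        node_label(lf): node_counts[node_label(lf)] for lf in tree.leaf_node_iter()
    }
    return FamilyHistory(
        family, node_label(origin), node_counts, branch_events, leaf_counts, fates
    )


# ---------------------------------------------------------------------------
# Archetype genes from the box grammar

CD_LEADER, CD_TAIL = "GGCAC", "GUGCC"
CD_CBOX, CD_CPBOX, CD_DBOX = "AUGAUGA", "GUGAUGA", "CUGA"
HP_STEM5, HP_STEM3 = "GGGGG", "CCCCC"
HP_LOOP = "AAAA"


@dataclass
class Archetype:
    family: str
    sno_class: str
    seq: str
    protected: np.ndarray        # bool per site: conserved element
    boxes: BoxSet
    ases: list                   # AntisenseElements of the archetype


def _rand_seq(rng: np.random.Generator, n: int, alphabet: str = RNA) -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), size=n))


def make_cd_archetype(family: str, rng: np.random.Generator, max_retries: int = 50) -> Archetype:
    """leader + C + ASE(D') + D' + spacer + C' + ASE(D) + D + tail, with the
    terminal stem formed by the complementary leader/tail."""
    for _ in range(max_retries):
        ase_dp = _rand_seq(rng, 12)
        mid = _rand_seq(rng, 10)
        ase_d = _rand_seq(rng, 12)
        seq = (
            CD_LEADER + CD_CBOX + ase_dp + CD_DBOX + mid
            + CD_CPBOX + ase_d + CD_DBOX + CD_TAIL
        )
        want = (
            ("C", 5, 12),
            ("Dprime", 24, 28),
            ("Cprime", 38, 45),
            ("D", 57, 61),
        )
        arch = _validate_archetype(family, "CD", seq, want, rng)
        if arch is not None:
            return arch
    raise RuntimeError(f"could not build a clean CD archetype for {family}")


def make_haca_archetype(family: str, rng: np.random.Generator, max_retries: int = 50) -> Archetype:
    """hairpin(stem-pocket-stem-loop) + hinge H box + hairpin + ACA tail.

    Stems are G/C and the gene contains no U; the 3' pocket halves are
    all-A so that the gene's C count equals its G count, which makes the
    designed fold the unique base-pair maximum and keeps the pockets
    (the guide elements) unpaired. Guide diversity lives in the 5' pocket
    halves (A/C alphabet: no partner anywhere in the hairpins).
    """
    for _ in range(max_retries):
        p5a, p5b = _rand_seq(rng, 7, "AC"), "A" * 7
        p3a, p3b = _rand_seq(rng, 7, "AC"), "A" * 7
        hbox = "A" + _rand_seq(rng, 1, "ACG") + "A" + _rand_seq(rng, 2, "ACG") + "A"
        hp1 = HP_STEM5 + p5a + HP_STEM5 + HP_LOOP + HP_STEM3 + p5b + HP_STEM3
        hp2 = HP_STEM5 + p3a + HP_STEM5 + HP_LOOP + HP_STEM3 + p3b + HP_STEM3
        seq = hp1 + "AA" + hbox + "AA" + hp2 + "A" + "ACA"
        want = (("H", 40, 46), ("ACA", len(seq) - 3, len(seq)))
        arch = _validate_archetype(family, "HACA", seq, want, rng)
        if arch is not None:
            return arch
    raise RuntimeError(f"could not build a clean HACA archetype for {family}")


def _validate_archetype(family, sno_class, seq, want_boxes, rng) -> Archetype | None:
    bp = BoxParams()
    boxes = annotate_cd_boxes(seq, bp) if sno_class == "CD" else annotate_haca_boxes(seq, bp)
    if boxes is None:
        return None
    got = tuple((h.name, h.start, h.end) for h in boxes.hits)
    if got != want_boxes:
        return None
    cls = classify_snoRNA(seq, bp)
    if cls is None or cls[0] != sno_class or not all(ch.passed for ch in cls[2]):
        return None
    # the actual search pipeline must trim a buffered copy back to the gene
    from snofamkit.homology_search import Candidate, SearchParams, _filter_one

    padded = "AAA" + seq + "AAA"
    cand = Candidate(
        family=family, species="_chk",
        interval=GenomicInterval("chk", 0, len(padded)),
        seq=padded, score=1.0, identity=1.0, coverage=1.0, source_member="arch",
    )
    cand = _filter_one(cand, sno_class, SearchParams())
    if not cand.retained or cand.seq != seq:
        return None
    gene = SnoGene(
        gene_id=f"{family}_arch", species="", family=family, sno_class=sno_class,
        interval=GenomicInterval("arch", 0, len(seq)), seq=seq, boxes=boxes,
    )
    ases = extract_ase(gene)
    if sno_class == "CD" and not any(a.location == "upstream_D" and len(a.seq) == 12 for a in ases):
        return None
    if sno_class == "HACA" and len(ases) < 2:
        return None
    protected = np.ones(len(seq), dtype=bool)
    if sno_class == "CD":
        protected[28:38] = False            # the spacer between D' and C'
    else:
        protected[[38, 39, 46, 47, len(seq) - 4]] = False  # hinge flanks + pre-ACA nt
    return Archetype(family, sno_class, seq, protected, boxes, ases)


# ---------------------------------------------------------------------------
# Sequence evolution


def mutate_sequence(
    seq: str,
    protected: np.ndarray,
    mu: float,
    rho: float,
    rng: np.random.Generator,
) -> str:
    """One branch of site-wise substitution: rate ``mu`` at background
    sites, ``mu * rho`` inside conserved elements; no indels in boxes."""
    if mu == 0.0:
        return seq
    rates = np.where(protected, mu * rho, mu)
    hit = rng.random(len(seq)) < rates
    if not hit.any():
        return seq
    chars = list(seq)
    for i in np.nonzero(hit)[0]:
        alts = [b for b in RNA if b != chars[i]]
        chars[i] = alts[rng.integers(0, 3)]
    return "".join(chars)


@dataclass
class SimFamily:
    archetype: Archetype
    history: FamilyHistory
    leaf_seqs: dict[str, list[str]]      # species -> one sequence per copy
    orphan: bool = False


def evolve_gene_sequences(
    tree: dendropy.Tree,
    history: FamilyHistory,
    archetype: Archetype,
    mu: float,
    rho: float,
    rng: np.random.Generator,
) -> dict[str, list[str]]:
    """Evolve the archetype along the history: copies mutate per branch,
    duplicates inherit the mutated state."""
    origin = _find_node(tree, history.origin)
    seqs: dict[dendropy.Node, list[str]] = {origin: [archetype.seq]}
    for node in origin.preorder_iter():
        if node is origin:
            continue
        parent_seqs = seqs[node.parent_node]
        fate = history.fates[node_label(node)]
        out: list[str] = []
        for src, k in zip(parent_seqs, fate):
            if k == 0:
                continue
            mutated = mutate_sequence(src, archetype.protected, mu, rho, rng)
            out.extend([mutated] * k)
        seqs[node] = out
    leaf_seqs: dict[str, list[str]] = {}
    for lf in tree.leaf_node_iter():
        lbl = node_label(lf)
        leaf_seqs[lbl] = seqs.get(lf, [])
        if history.node_counts.get(lbl, 0) == 0:
            leaf_seqs[lbl] = []
    return leaf_seqs


def _find_node(tree: dendropy.Tree, label: str) -> dendropy.Node:
    for node in tree.preorder_node_iter():
        if node_label(node) == label:
            return node
    raise KeyError(label)


# ---------------------------------------------------------------------------
# Genomes


@dataclass
class GroundTruth:
    genes: dict[str, list[SnoGene]]                  # species -> truth genes
    histories: dict[str, FamilyHistory]
    clusters: dict[str, list[list[str]]]             # species -> member gene-id lists
    target_sites: dict[str, tuple[str, int, int, int, str]]  # family -> (target, start1, end1, mod1, type)
    orphans: list[str]
    classes: dict[str, str]                          # family -> CD | HACA


@dataclass
class SimulatedDataset:
    config: SimConfig
    tree: dendropy.Tree
    species: list[str]
    families: dict[str, SimFamily]
    genomes: dict[str, list[SeqRecord]]
    targets: list[SeqRecord]
    truth: GroundTruth
    resampled_extinct: int = 0


def _background(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join("ACGT"[i] for i in rng.choice(4, size=n, p=p))


def _dna(rna: str) -> str:
    return rna.replace("U", "T")


def plant_genomes(
    families: dict[str, SimFamily],
    species: list[str],
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[dict[str, list[SeqRecord]], dict[str, list[SnoGene]], dict[str, list[list[str]]]]:
    """Assemble one chromosome per species with planted (buffered) genes.

    The first ``cluster_fraction`` of families are grouped ``cluster_size``
    at a time; per species the first copy of each present group member goes
    into one run with inter-gene spacing ~ U[cluster_spacing]; everything
    else is placed as singletons separated by U[intergenic_spacing] of
    background so that unrelated genes never chain into a cluster.
    """
    fam_ids = list(families)
    n_clustered = int(round(config.cluster_fraction * len(fam_ids)))
    groups = [
        fam_ids[i: i + config.cluster_size]
        for i in range(0, n_clustered, config.cluster_size)
    ]
    clustered = {f for g in groups for f in g}

    genomes: dict[str, list[SeqRecord]] = {}
    genes: dict[str, list[SnoGene]] = {}
    clusters: dict[str, list[list[str]]] = {}
    for sp in species:
        units: list[list[tuple[str, str]]] = []  # list of runs of (family, seq)
        for grp in groups:
            run = [(f, families[f].leaf_seqs[sp][0]) for f in grp if families[f].leaf_seqs.get(sp)]
            if run:
                units.append(run)
        for f in fam_ids:
            copies = families[f].leaf_seqs.get(sp, [])
            start = 1 if f in clustered and copies else 0
            for seq in copies[start:]:
                units.append([(f, seq)])
        order = rng.permutation(len(units))
        units = [units[i] for i in order]

        chunks: list[str] = []
        pos = 0
        sp_genes: list[SnoGene] = []
        sp_clusters: list[list[str]] = []
        counter: dict[str, int] = {}
        for run in units:
            gap = int(rng.integers(*config.intergenic_spacing))
            chunks.append(_background(rng, gap, config.gc))
            pos += gap
            run_ids = []
            for k, (fam, seq) in enumerate(run):
                if k > 0:
                    sp_gap = int(rng.integers(*config.cluster_spacing))
                    chunks.append(_background(rng, sp_gap, config.gc))
                    pos += sp_gap
                strand = "+" if rng.random() < 0.5 else "-"
                insert = _dna(seq) if strand == "+" else _dna(revcomp_rna(seq))
                buf = "AAA" if strand == "+" else "TTT"
                chunks.append(buf + insert + buf)
                iv = GenomicInterval("chr1", pos + 3, pos + 3 + len(seq), strand)
                pos += len(insert) + 6
                counter[fam] = counter.get(fam, 0) + 1
                gid = f"{fam}_{sp}_t{counter[fam]}"
                sp_genes.append(
                    SnoGene(
                        gene_id=gid, species=sp, interval=iv,
                        sno_class=families[fam].archetype.sno_class,
                        family=fam, seq=seq,
                        boxes=_annotate_for(families[fam].archetype.sno_class, seq),
                    )
                )
                run_ids.append(gid)
            if len(run_ids) >= 2:
                sp_clusters.append(run_ids)
        if pos < config.genome_length:
            chunks.append(_background(rng, config.genome_length - pos, config.gc))
        genomes[sp] = [SeqRecord(id="chr1", seq="".join(chunks))]
        genes[sp] = sp_genes
        clusters[sp] = sp_clusters
    return genomes, genes, clusters


def _annotate_for(sno_class: str, seq: str) -> BoxSet | None:
    return annotate_cd_boxes(seq) if sno_class == "CD" else annotate_haca_boxes(seq)


def _guide_seq(arch: Archetype) -> str:
    if arch.sno_class == "CD":
        return next(a.seq for a in arch.ases if a.location == "upstream_D")
    return next(a.seq for a in arch.ases if a.location == "pocket_5p")


def _guide_distinct(arch: Archetype, existing, min_dist: int = 3) -> bool:
    """Guides of same-class families must differ at >= ``min_dist`` sites,
    so one family's guide can never be mistaken for another's target."""
    g = _guide_seq(arch)
    for other in existing:
        if other.archetype.sno_class != arch.sno_class:
            continue
        o = _guide_seq(other.archetype)
        if len(o) == len(g) and sum(a != b for a, b in zip(g, o)) < min_dist:
            return False
    return True


# ---------------------------------------------------------------------------
# Target RNAs


def make_target_rna(
    families: dict[str, SimFamily],
    config: SimConfig,
    rng: np.random.Generator,
    duplex_params: DuplexParams | None = None,
) -> tuple[list[SeqRecord], dict[str, tuple[str, int, int, int, str]], list[str]]:
    """One rRNA-like target with, per non-orphan family, the reverse
    complement of its archetype guide embedded at a recorded position; the
    true modified residue follows the +offset rule (CD) or sits in the
    pocket hinge (HACA). Verified by re-scanning: each planted site is the
    family's unique accepted site and orphans have none.
    """
    dp = duplex_params or DuplexParams()
    fam_ids = list(families)
    n_orphan = int(round(config.orphan_fraction * len(fam_ids)))
    orphan_idx = set(rng.choice(len(fam_ids), size=n_orphan, replace=False).tolist())
    orphans = sorted(fam_ids[i] for i in orphan_idx)
    for f in orphans:
        families[f].orphan = True

    for _ in range(config.max_retries):
        rng_try = np.random.default_rng(rng.integers(0, 2**31))
        pieces: list[str] = []
        pos = 0
        sites: dict[str, tuple[str, int, int, int, str]] = {}
        for i, f in enumerate(fam_ids):
            if i in orphan_idx:
                continue
            fam = families[f]
            ases = fam.archetype.ases
            if fam.archetype.sno_class == "CD":
                ase = next(a for a in ases if a.location == "upstream_D")
                planted = revcomp_rna(ase.seq)
                gap = int(rng_try.integers(30, 80))
                pieces.append(_rna_background(rng_try, gap, config.gc))
                pos += gap
                start1 = pos + 1
                pieces.append(planted)
                mod1 = start1 + dp.mod_offset - 1
                sites[f] = ("target1", start1, pos + len(planted), mod1, "Nm")
                pos += len(planted)
            else:
                ase = next(a for a in ases if a.location == "pocket_5p")
                h5, h3 = ase.seq, ase.seq2
                spacer = "U" + _rna_background(rng_try, dp.psi_spacer - 1, config.gc)
                planted = revcomp_rna(h3) + spacer + revcomp_rna(h5)
                gap = int(rng_try.integers(30, 80))
                pieces.append(_rna_background(rng_try, gap, config.gc))
                pos += gap
                start1 = pos + 1
                pieces.append(planted)
                mod1 = start1 + len(h3)
                sites[f] = ("target1", start1, pos + len(planted), mod1, "Psi")
                pos += len(planted)
        if pos < config.target_length:
            pieces.append(_rna_background(rng_try, config.target_length - pos, config.gc))
        target = SeqRecord(id="target1", seq="".join(pieces))

        if _verify_target(target, families, fam_ids, orphan_idx, sites, dp):
            return [target], sites, orphans
    raise RuntimeError("could not build an unambiguous target RNA")


def _rna_background(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join("ACGU"[i] for i in rng.choice(4, size=n, p=p))


def _verify_target(target, families, fam_ids, orphan_idx, sites, dp) -> bool:
    for i, f in enumerate(fam_ids):
        fam = families[f]
        if fam.archetype.sno_class == "CD":
            ase = next(a for a in fam.archetype.ases if a.location == "upstream_D")
        else:
            ase = next(a for a in fam.archetype.ases if a.location == "pocket_5p")
        hits = [h for h in duplex_scan(ase, target, dp) if h.score >= dp.call_min_score]
        if i in orphan_idx:
            if hits:
                return False
        else:
            want = sites[f]
            if len(hits) != 1 or hits[0].window != (want[1], want[2]):
                return False
    return True


# ---------------------------------------------------------------------------
# Top level


def simulate_dataset(config: SimConfig | None = None) -> SimulatedDataset:
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed)
    if config.tree_newick:
        tree = parse_newick(config.tree_newick)
    else:
        tree = simulate_tree(config.n_species, rng)
    species = [node_label(lf) for lf in tree.leaf_node_iter()]
    nodes = list(tree.preorder_node_iter())

    families: dict[str, SimFamily] = {}
    resampled = 0
    total = config.n_cd_families + config.n_haca_families
    for i in range(total):
        sno_class = "CD" if i < config.n_cd_families else "HACA"
        fam = f"{'cd' if sno_class == 'CD' else 'haca'}{i + 1:03d}"
        arch = (
            make_cd_archetype(fam, rng, config.max_retries)
            if sno_class == "CD"
            else make_haca_archetype(fam, rng, config.max_retries)
        )
        while not _guide_distinct(arch, families.values()):
            arch = (
                make_cd_archetype(fam, rng, config.max_retries)
                if sno_class == "CD"
                else make_haca_archetype(fam, rng, config.max_retries)
            )
        for _ in range(config.max_retries):
            if config.origin_mode == "random":
                origin = nodes[int(rng.integers(0, len(nodes)))]
            else:
                origin = tree.seed_node
            hist = simulate_family_history(tree, origin, config.p_dup, config.p_loss, rng, fam)
            if any(c > 0 for c in hist.leaf_counts.values()):
                break
            resampled += 1
        leaf_seqs = evolve_gene_sequences(tree, hist, arch, config.mu, config.rho, rng)
        families[fam] = SimFamily(archetype=arch, history=hist, leaf_seqs=leaf_seqs)

    genomes, genes, clusters = plant_genomes(families, species, config, rng)
    targets, target_sites, orphans = make_target_rna(families, config, rng)

    truth = GroundTruth(
        genes=genes,
        histories={f: fam.history for f, fam in families.items()},
        clusters=clusters,
        target_sites=target_sites,
        orphans=orphans,
        classes={f: fam.archetype.sno_class for f, fam in families.items()},
    )
    return SimulatedDataset(
        config=config,
        tree=tree,
        species=species,
        families=families,
        genomes=genomes,
        targets=targets,
        truth=truth,
        resampled_extinct=resampled,
    )


def write_dataset(ds: SimulatedDataset, outdir: str | Path) -> None:
    """Emit genomes/*.fasta, truth/*.gff3, truth/history.tsv, targets.fasta
    and species.nwk."""
    outdir = Path(outdir)
    (outdir / "genomes").mkdir(parents=True, exist_ok=True)
    (outdir / "truth").mkdir(parents=True, exist_ok=True)
    for sp, recs in ds.genomes.items():
        write_fasta(recs, outdir / "genomes" / f"{sp}.fasta")
        write_gff3(ds.truth.genes[sp], outdir / "truth" / f"{sp}.gff3")
    write_fasta(ds.targets, outdir / "targets.fasta")
    write_newick(ds.tree, outdir / "species.nwk")
    lines = ["family\tclass\torigin\tspecies\tcount"]
    for fam, hist in ds.truth.histories.items():
        for sp, c in sorted(hist.leaf_counts.items()):
            lines.append(f"{fam}\t{ds.truth.classes[fam]}\t{hist.origin}\t{sp}\t{c}")
    (outdir / "truth" / "history.tsv").write_text("\n".join(lines) + "\n")
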