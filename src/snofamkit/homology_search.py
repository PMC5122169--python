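"""Seeded homology search for snoRNA families across genomes.

The search replaces an external blast/infernal stage with a self-contained
pipeline: exact word (k-mer) seeding on both strands, Smith-Waterman
extension with affine gaps, then the discriminative filters — percent
identity and coverage, box annotation, and the class-specific structure
check — followed by trimming to mature bounds. Retained candidates can be
fed back as additional query members over several rounds, so that homologs
too diverged from the original query are still reached through intermediate
species. The final step builds a box-anchored family-wide alignment with a
``#=GC Boxes`` line and a consensus-structure line.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from Bio import Align

from snofamkit.box_annotation import (
    BoxParams,
    BoxSet,
    StructureCheck,
    annotate_cd_boxes,
    annotate_haca_boxes,
    check_hairpin_topology,
    check_terminal_stem,
)
from snofamkit.core_io import (
    IUPAC_RNA,
    FamilyAlignment,
    GenomicInterval,
    SeqRecord,
    SnoGene,
    revcomp_rna,
    to_rna,
)

# ---------------------------------------------------------------------------
# Configuration


@dataclass(frozen=True)
class AlignScoring:
    """Local-alignment scoring; a gap of length k costs open + k * extend."""

    match: int = 2
    mismatch: int = -3
    gap_open: int = -5
    gap_extend: int = -2


@dataclass
class SearchParams:
    word: int = 9            # seed word size ("relaxed" sensitivity)
    min_id: float = 0.55
    min_cov: float = 0.60    # aligned fraction of the query member
    rounds: int = 2
    cap_per_species: int = 50
    member_cap: int = 50
    extend_members: int = 8  # members tried per window at the extension stage
    pad: int = 3             # nt of window kept beyond the aligned span
    scoring: AlignScoring = field(default_factory=AlignScoring)
    box_params: BoxParams = field(default_factory=BoxParams)


# ---------------------------------------------------------------------------
# Family queries


@dataclass
class FamilyQuery:
    family_id: str
    sno_class: str
    members: list[SeqRecord]
    consensus: str = ""
    consensus_boxes: BoxSet | None = None


_CODE_OF = {frozenset(v): k for k, v in IUPAC_RNA.items()}


def _iupac_code(bases: set[str]) -> str:
    return _CODE_OF.get(frozenset(bases), "N")


def build_family_query(
    family_id: str,
    sno_class: str,
    members: list[SeqRecord],
    params: BoxParams | None = None,
) -> FamilyQuery:
    """Assemble a query: members, a majority/IUPAC consensus from the
    box-anchored family alignment, and the consensus box annotation."""
    params = params or BoxParams()
    annotated = []
    missing = []
    for m in members:
        bs = _annotate(m.seq, sno_class, params)
        if bs is None:
            missing.append(m.id)
        else:
            annotated.append((m.id, to_rna(m.seq), bs))
    if missing:
        raise ValueError(f"family {family_id}: members without mandatory boxes: {missing}")
    aln = align_family(family_id, sno_class, annotated, params)
    consensus = []
    rows = list(aln.rows.values())
    n = len(rows)
    for col in zip(*rows):
        gaps = sum(1 for ch in col if ch in "-.")
        if gaps * 2 >= n:
            continue
        counts: dict[str, int] = {}
        for ch in col:
            if ch not in "-.":
                counts[ch] = counts.get(ch, 0) + 1
        top, top_n = max(sorted(counts.items()), key=lambda kv: kv[1])
        if top_n / n >= 0.6:
            consensus.append(top)
        else:
            consensus.append(_iupac_code(set(counts)))
    cons = "".join(consensus)
    return FamilyQuery(
        family_id=family_id,
        sno_class=sno_class,
        members=list(members),
        consensus=cons,
        consensus_boxes=_annotate(cons, sno_class, params),
    )


def _annotate(seq: str, sno_class: str, params: BoxParams) -> BoxSet | None:
    if sno_class == "CD":
        return annotate_cd_boxes(seq, params)
    return annotate_haca_boxes(seq, params)


# ---------------------------------------------------------------------------
# Seeding


def seed_scan(
    query: FamilyQuery, genome: list[SeqRecord], word: int = 9
) -> list[GenomicInterval]:
    """Genomic intervals sharing at least one exact word with any query
    member, on either strand, padded by the query length and merged."""
    words: dict[str, None] = {}
    max_qlen = 0
    for m in query.members:
        s = to_rna(m.seq)
        max_qlen = max(max_qlen, len(s))
        for i in range(len(s) - word + 1):
            words[s[i:i + word]] = None
            words[revcomp_rna(s[i:i + word])] = None

    raw: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for rec in genome:
        g = to_rna(rec.seq)
        fwd_words = {s for s in words}
        for i in range(len(g) - word + 1):
            w = g[i:i + word]
            if w in fwd_words:
                start = max(0, i - max_qlen)
                end = min(len(g), i + word + max_qlen)
                # strand resolved later at extension; seed both orientations
                raw.setdefault((rec.id, "+"), []).append((start, end))
    merged: list[GenomicInterval] = []
    for (chrom, strand), spans in sorted(raw.items()):
        spans.sort()
        cur_s, cur_e = spans[0]
        for s, e in spans[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                merged.append(GenomicInterval(chrom, cur_s, cur_e, strand))
                cur_s, cur_e = s, e
        merged.append(GenomicInterval(chrom, cur_s, cur_e, strand))
    return merged


# ---------------------------------------------------------------------------
# Smith-Waterman extension


@dataclass(frozen=True)
class ExtendResult:
    score: float
    identity: float
    window_span: tuple[int, int]  # on the window sequence, 0-based half-open
    query_span: tuple[int, int]


def make_aligner(scoring: AlignScoring | None = None) -> Align.PairwiseAligner:
    sc = scoring or AlignScoring()
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = sc.match
    aligner.mismatch_score = sc.mismatch
    # Biopython's open_gap_score is the score of the gap's first position.
    aligner.open_gap_score = sc.gap_open + sc.gap_extend
    aligner.extend_gap_score = sc.gap_extend
    return aligner


def extend_align(
    window: str, query: str, scoring: AlignScoring | None = None
) -> ExtendResult:
    """Optimal local alignment of a query member against a genomic window."""
    window, query = to_rna(window), to_rna(query)
    aligner = make_aligner(scoring)
    alns = aligner.align(window, query)
    if len(alns) == 0 or alns.score <= 0:
        return ExtendResult(0.0, 0.0, (0, 0), (0, 0))
    aln = alns[0]
    t_blocks, q_blocks = aln.aligned
    matches = 0
    columns = 0
    prev_t = prev_q = None
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        if prev_t is not None:
            columns += (ts - prev_t) + (qs - prev_q)
        for a, b in zip(window[ts:te], query[qs:qe]):
            matches += a == b
        columns += te - ts
        prev_t, prev_q = te, qe
    identity = matches / columns if columns else 0.0
    w_span = (int(t_blocks[0][0]), int(t_blocks[-1][1]))
    q_span = (int(q_blocks[0][0]), int(q_blocks[-1][1]))
    return ExtendResult(float(aln.score), identity, w_span, q_span)


# ---------------------------------------------------------------------------
# Candidates and filtering


@dataclass
class Candidate:
    family: str
    species: str
    interval: GenomicInterval
    seq: str                      # 5'->3' RNA of the candidate region
    score: float
    identity: float
    coverage: float
    source_member: str
    boxset: BoxSet | None = None
    checks: tuple[StructureCheck, ...] = ()
    status: str = "pending"

    @property
    def retained(self) -> bool:
        return self.status == "retained"


def filter_candidates(
    candidates: list[Candidate], sno_class: str, params: SearchParams | None = None
) -> list[Candidate]:
    """Apply the filter cascade in place: identity/coverage, box presence,
    structure, then trim each survivor to its mature bounds. Rejected
    candidates keep a reason code in ``status``."""
    params = params or SearchParams()
    out = []
    for cand in candidates:
        out.append(_filter_one(cand, sno_class, params))
    return out


def _filter_one(cand: Candidate, sno_class: str, params: SearchParams) -> Candidate:
    bp = params.box_params
    if cand.identity < params.min_id:
        cand.status = "rejected:low_identity"
        return cand
    if cand.coverage < params.min_cov:
        cand.status = "rejected:low_coverage"
        return cand

    seq = cand.seq
    if sno_class == "HACA":
        seq, offset = _trim_to_aca(seq, params)
        if seq is None:
            cand.status = "rejected:no_box_ACA"
            return cand
        boxset = annotate_haca_boxes(seq, bp)
    else:
        offset = 0
        boxset = annotate_cd_boxes(seq, bp)

    if boxset is None:
        missing = _missing_cd_box(seq, bp) if sno_class == "CD" else "H"
        cand.status = f"rejected:no_box_{missing}"
        return cand

    if sno_class == "CD":
        check = check_terminal_stem(seq, boxset, bp)
    else:
        check = check_hairpin_topology(seq, boxset, bp)
    if not check.passed:
        cand.status = "rejected:structure"
        cand.boxset = boxset
        cand.checks = (check,)
        return cand

    trimmed, trim_start = _trim_mature(seq, boxset, check, sno_class)
    total_off = offset + trim_start
    boxset2 = _annotate(trimmed, sno_class, bp)
    if boxset2 is None:
        cand.status = "rejected:trim_boxes"
        cand.boxset = boxset
        cand.checks = (check,)
        return cand
    if sno_class == "CD":
        check2 = check_terminal_stem(trimmed, boxset2, bp)
    else:
        check2 = check_hairpin_topology(trimmed, boxset2, bp)
    if not check2.passed:
        cand.status = "rejected:structure"
        cand.boxset = boxset2
        cand.checks = (check2,)
        return cand
    cand.seq = trimmed
    cand.interval = _shift_interval(cand.interval, total_off, len(trimmed))
    cand.boxset = boxset2
    cand.checks = (check2,)
    cand.status = "retained"
    return cand


def _missing_cd_box(seq: str, bp: BoxParams) -> str:
    from snofamkit.box_annotation import match_iupac

    seq = to_rna(seq)
    has_c = any(
        h.start <= bp.c_start_max for h in match_iupac(bp.patterns["C"], seq)
    )
    has_d = any(
        h.end >= len(seq) - bp.d_end_window for h in match_iupac(bp.patterns["D"], seq)
    )
    if not has_c and not has_d:
        return "C_and_D"
    return "D" if not has_d else "C"


def _trim_to_aca(seq: str, params: SearchParams):
    """Truncate a padded candidate at the rightmost ACA whose end lies
    within the trailing pad window; the mature H/ACA gene ends in ACA."""
    seq = to_rna(seq)
    lo = max(0, len(seq) - (params.pad * 2 + 3))
    for end in range(len(seq), lo + 2, -1):
        if seq[end - 3:end] == "ACA":
            return seq[:end], 0
    return None, 0


def _trim_mature(seq: str, boxset: BoxSet, check: StructureCheck, sno_class: str):
    if sno_class == "CD":
        if check.pairs:
            start = min(p[0] for p in check.pairs)
            end = max(p[1] for p in check.pairs) + 1
        else:
            c, d = boxset.get("C"), boxset.get("D")
            start, end = c.start, d.end
        return seq[start:end], start
    # HACA: first paired position of the 5' hairpin to the ACA end
    start = min((p[0] for p in check.pairs), default=0)
    return seq[start:], start


def _shift_interval(iv: GenomicInterval, offset: int, new_len: int) -> GenomicInterval:
    if iv.strand == "+":
        s = iv.start + offset
        return GenomicInterval(iv.chrom, s, s + new_len, "+")
    e = iv.end - offset
    return GenomicInterval(iv.chrom, e - new_len, e, "-")


def _resolve_cross_family(retained: list[Candidate]) -> list[Candidate]:
    """Within one species, assign each genomic locus to the single best
    family: among overlapping retained candidates the higher alignment
    score wins (ties: 5'-most interval, then family id)."""
    order = sorted(
        retained, key=lambda c: (-c.score, c.interval.chrom, c.interval.start, c.family)
    )
    kept: list[Candidate] = []
    for c in order:
        clash = any(
            k.interval.chrom == c.interval.chrom
            and k.interval.start < c.interval.end
            and c.interval.start < k.interval.end
            for k in kept
        )
        if clash:
            c.status = "rejected:cross_family"
        else:
            kept.append(c)
    return kept


def resolve_overlaps(cands: list[Candidate], cap: int) -> list[Candidate]:
    """Among retained candidates, drop the lower-scoring of any overlapping
    pair (ties: 5'-most wins), then cap the per-species count."""
    retained = [c for c in cands if c.retained]
    retained.sort(key=lambda c: (-c.score, c.interval.start, c.interval.chrom))
    kept: list[Candidate] = []
    for c in retained:
        clash = next(
            (k for k in kept if k.interval.chrom == c.interval.chrom
             and k.interval.start < c.interval.end and c.interval.start < k.interval.end),
            None,
        )
        if clash is None:
            kept.append(c)
        else:
            c.status = "rejected:overlap"
    for c in kept[cap:]:
        c.status = "rejected:cap"
    kept = kept[:cap]
    kept.sort(key=lambda c: (c.interval.chrom, c.interval.start))
    return kept


# ---------------------------------------------------------------------------
# Per-genome search


def search_genome(
    query: FamilyQuery,
    species: str,
    genome: list[SeqRecord],
    params: SearchParams | None = None,
) -> list[Candidate]:
    """Seed, extend, filter and deduplicate one family against one genome."""
    params = params or SearchParams()
    genome_by_id = {rec.id: to_rna(rec.seq) for rec in genome}
    intervals = seed_scan(query, genome, params.word)
    candidates: list[Candidate] = []
    for iv in intervals:
        gseq = genome_by_id[iv.chrom]
        window_fwd = gseq[iv.start:iv.end]
        for strand, window in (("+", window_fwd), ("-", revcomp_rna(window_fwd))):
            best: tuple[ExtendResult, SeqRecord] | None = None
            for m in query.members[: params.extend_members]:
                res = extend_align(window, m.seq, params.scoring)
                if best is None or res.score > best[0].score:
                    best = (res, m)
            res, member = best
            if res.score <= 0:
                continue
            ws, we = res.window_span
            s = max(0, ws - params.pad)
            e = min(len(window), we + params.pad)
            cand_seq = window[s:e]
            if strand == "+":
                g_start, g_end = iv.start + s, iv.start + e
            else:
                g_start, g_end = iv.end - e, iv.end - s
            candidates.append(
                Candidate(
                    family=query.family_id,
                    species=species,
                    interval=GenomicInterval(iv.chrom, g_start, g_end, strand),
                    seq=cand_seq,
                    score=res.score,
                    identity=res.identity,
                    coverage=(res.query_span[1] - res.query_span[0]) / len(member.seq),
                    source_member=member.id,
                )
            )
    filter_candidates(candidates, query.sno_class, params)
    resolve_overlaps(candidates, params.cap_per_species)
    return candidates


# ---------------------------------------------------------------------------
# Iterative multi-genome search


@dataclass
class SearchResult:
    genes: dict[str, list[SnoGene]]            # species -> retained genes
    candidates: list[Candidate]                 # all, with status codes
    counts: dict[str, dict[str, int]]           # family -> species -> count
    alignments: dict[str, FamilyAlignment]


def iterate_search(
    queries: list[FamilyQuery],
    genomes: dict[str, list[SeqRecord]],
    params: SearchParams | None = None,
) -> SearchResult:
    """snoStrip-style iterative mapping of every family to every genome.

    After each round the retained candidate sequences join the family's
    member set (up to ``member_cap``), so a second round can reach homologs
    only recognisable through intermediate species. Deterministic: no
    randomness anywhere in the search path.
    """
    params = params or SearchParams()
    base_members = {q.family_id: list(q.members) for q in queries}
    queries = [
        FamilyQuery(q.family_id, q.sno_class, list(q.members), q.consensus, q.consensus_boxes)
        for q in queries
    ]
    retained: dict[tuple[str, str], list[Candidate]] = {}
    all_cands: list[Candidate] = []
    for _round in range(params.rounds):
        # each round is a full, stateless re-search with the grown query sets
        retained = {}
        all_cands = []
        per_species: dict[str, list[Candidate]] = {sp: [] for sp in genomes}
        for q in queries:
            for species in sorted(genomes):
                cands = search_genome(q, species, genomes[species], params)
                per_species[species].extend(c for c in cands if c.retained)
                all_cands.extend(cands)
        # best-hit assignment: overlapping loci claimed by different
        # families go to the highest-scoring one
        for species in sorted(per_species):
            for c in _resolve_cross_family(per_species[species]):
                retained.setdefault((c.family, species), []).append(c)
        # candidate propagation between rounds
        for q in queries:
            members = list(base_members[q.family_id])
            for (fam, species), cands in sorted(retained.items()):
                if fam != q.family_id:
                    continue
                for c in cands:
                    mid = f"{fam}|{species}|{c.interval.chrom}:{c.interval.start}"
                    if len(members) < params.member_cap and all(m.id != mid for m in members):
                        members.append(SeqRecord(id=mid, seq=c.seq))
            q.members = members

    genes: dict[str, list[SnoGene]] = {sp: [] for sp in genomes}
    counts: dict[str, dict[str, int]] = {q.family_id: {sp: 0 for sp in genomes} for q in queries}
    class_of = {q.family_id: q.sno_class for q in queries}
    for (family, species), cands in sorted(retained.items()):
        for i, c in enumerate(sorted(cands, key=lambda x: (x.interval.chrom, x.interval.start)), 1):
            genes[species].append(
                SnoGene(
                    gene_id=f"{family}_{species}_{i}",
                    species=species,
                    interval=c.interval,
                    sno_class=class_of[family],
                    family=family,
                    seq=c.seq,
                    boxes=c.boxset,
                )
            )
            counts[family][species] += 1
    for sp in genes:
        genes[sp].sort(key=lambda g: (g.interval.chrom, g.interval.start))

    alignments = {}
    for q in queries:
        members = []
        for sp in sorted(genomes):
            for g in genes[sp]:
                if g.family == q.family_id:
                    members.append((g.gene_id, g.seq, g.boxes))
        if members:
            alignments[q.family_id] = align_family(
                q.family_id, q.sno_class, members, params.box_params
            )
    return SearchResult(genes=genes, candidates=all_cands, counts=counts, alignments=alignments)


# ---------------------------------------------------------------------------
# Box-anchored family alignment

_ANCHOR_ORDER = {"CD": ["C", "Dprime", "Cprime", "D"], "HACA": ["H", "ACA"]}
_ANCHOR_LETTER = {"C": "C", "D": "D", "Dprime": "d", "Cprime": "c", "H": "H", "ACA": "A"}

_SP_MATCH, _SP_MISMATCH, _SP_GAP = 1, -1, -2


def sum_of_pairs(columns: list[tuple[str, ...]]) -> int:
    """Sum-of-pairs score of an alignment given as columns; gap-gap scores 0."""
    total = 0
    for col in columns:
        n = len(col)
        for a in range(n):
            for b in range(a + 1, n):
                x, y = col[a], col[b]
                if x == "-" and y == "-":
                    continue
                if x == "-" or y == "-":
                    total += _SP_GAP
                elif x == y:
                    total += _SP_MATCH
                else:
                    total += _SP_MISMATCH
    return total


def _nw2(a: str, b: str) -> tuple[str, str]:
    n, m = len(a), len(b)
    M = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        M[i][0] = i * _SP_GAP
    for j in range(1, m + 1):
        M[0][j] = j * _SP_GAP
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            sub = _SP_MATCH if a[i - 1] == b[j - 1] else _SP_MISMATCH
            M[i][j] = max(M[i - 1][j - 1] + sub, M[i - 1][j] + _SP_GAP, M[i][j - 1] + _SP_GAP)
    ra, rb = [], []
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0:
            sub = _SP_MATCH if a[i - 1] == b[j - 1] else _SP_MISMATCH
            if M[i][j] == M[i - 1][j - 1] + sub:
                ra.append(a[i - 1]); rb.append(b[j - 1]); i -= 1; j -= 1
                continue
        if i > 0 and M[i][j] == M[i - 1][j] + _SP_GAP:
            ra.append(a[i - 1]); rb.append("-"); i -= 1
        else:
            ra.append("-"); rb.append(b[j - 1]); j -= 1
    return "".join(reversed(ra)), "".join(reversed(rb))


def _msa3_exact(a: str, b: str, c: str) -> list[str]:
    """SP-optimal three-way alignment by 3D dynamic programming."""
    import itertools

    def pair(x: str, y: str) -> int:
        if x == "-" and y == "-":
            return 0
        if x == "-" or y == "-":
            return _SP_GAP
        return _SP_MATCH if x == y else _SP_MISMATCH

    la, lb, lc = len(a), len(b), len(c)
    NEG = float("-inf")
    M = {(0, 0, 0): 0}
    back: dict[tuple[int, int, int], tuple[int, int, int]] = {}
    moves = [m for m in itertools.product((0, 1), repeat=3) if any(m)]
    for i in range(la + 1):
        for j in range(lb + 1):
            for k in range(lc + 1):
                if (i, j, k) == (0, 0, 0):
                    continue
                best, arg = NEG, None
                for di, dj, dk in moves:
                    pi, pj, pk = i - di, j - dj, k - dk
                    if pi < 0 or pj < 0 or pk < 0 or (pi, pj, pk) not in M:
                        continue
                    x = a[pi] if di else "-"
                    y = b[pj] if dj else "-"
                    z = c[pk] if dk else "-"
                    cost = pair(x, y) + pair(x, z) + pair(y, z)
                    val = M[(pi, pj, pk)] + cost
                    if val > best:
                        best, arg = val, (di, dj, dk)
                M[(i, j, k)] = best
                back[(i, j, k)] = arg
    ra, rb, rc = [], [], []
    i, j, k = la, lb, lc
    while (i, j, k) != (0, 0, 0):
        di, dj, dk = back[(i, j, k)]
        ra.append(a[i - 1] if di else "-")
        rb.append(b[j - 1] if dj else "-")
        rc.append(c[k - 1] if dk else "-")
        i, j, k = i - di, j - dj, k - dk
    return ["".join(reversed(r)) for r in (ra, rb, rc)]


def _msa_segment(segs: list[str]) -> list[str]:
    """Align one inter-anchor segment across members.

    Exact sum-of-pairs optimum for up to three members; centre-star
    progressive merge (guide first) beyond that.
    """
    if len(segs) == 1:
        return [segs[0]]
    if len(segs) == 2:
        return list(_nw2(segs[0], segs[1]))
    if len(segs) == 3:
        return _msa3_exact(*segs)
    center = segs[0]
    rows = [center]
    for s in segs[1:]:
        gc, gs = _nw2(center, s)
        rows = _merge_star(rows, gc, gs)
    return rows


def _merge_star(rows: list[str], gc: str, gs: str) -> list[str]:
    """'Once a gap, always a gap' merge of a new pairwise alignment of the
    (ungapped) centre into the existing MSA (rows[0] = gapped centre)."""
    out = ["" for _ in range(len(rows) + 1)]
    i = j = 0
    W, Wp = len(rows[0]), len(gc)
    while i < W or j < Wp:
        if i < W and rows[0][i] == "-":
            for r, row in enumerate(rows):
                out[r] += row[i]
            out[-1] += "-"
            i += 1
        elif j < Wp and gc[j] == "-":
            for r in range(len(rows)):
                out[r] += "-"
            out[-1] += gs[j]
            j += 1
        else:
            for r, row in enumerate(rows):
                out[r] += row[i]
            out[-1] += gs[j]
            i += 1
            j += 1
    return out


def align_family(
    family_id: str,
    sno_class: str,
    members: list[tuple[str, str, BoxSet]],
    params: BoxParams | None = None,
) -> FamilyAlignment:
    """Box-anchored family alignment.

    Boxes of like kind are forced into common columns; the segments between
    anchors are aligned progressively in guide order (descending identity
    to the family's most representative member, ties by id). Emits the
    ``#=GC Boxes`` letters (C, D, d, c, H, A) and an ``SS_cons`` line from
    the guide member's structure check.
    """
    params = params or BoxParams()
    if not members:
        raise ValueError("align_family needs at least one member")
    missing = [mid for mid, _, bs in members if bs is None]
    if missing:
        raise ValueError(f"members without mandatory boxes: {missing}")
    members = [(mid, to_rna(seq), bs) for mid, seq, bs in members]

    anchors = [
        a for a in _ANCHOR_ORDER[sno_class]
        if all(bs.get(a) is not None for _, _, bs in members)
    ]

    order = _guide_order(members)
    members = [members[i] for i in order]

    # split members into inter-anchor segments
    seg_lists: list[list[str]] = [[] for _ in range(len(anchors) + 1)]
    anchor_seqs: list[list[str]] = [[] for _ in anchors]
    for mid, seq, bs in members:
        prev_end = 0
        for ai, a in enumerate(anchors):
            h = bs.get(a)
            seg_lists[ai].append(seq[prev_end:h.start])
            anchor_seqs[ai].append(seq[h.start:h.end])
            prev_end = h.end
        seg_lists[-1].append(seq[prev_end:])

    rows = ["" for _ in members]
    boxes_line = ""
    col_is_anchor: list[str] = []
    for ai in range(len(anchors) + 1):
        seg_aln = _msa_segment(seg_lists[ai])
        width = len(seg_aln[0]) if seg_aln else 0
        for r in range(len(members)):
            rows[r] += seg_aln[r]
        boxes_line += "." * width
        if ai < len(anchors):
            w = len(anchor_seqs[ai][0])
            for r in range(len(members)):
                rows[r] += anchor_seqs[ai][r]
            boxes_line += _ANCHOR_LETTER[anchors[ai]] * w

    ss = _consensus_structure(members[0], rows[0], sno_class, params)
    aln = FamilyAlignment(
        family_id=family_id,
        rows={mid: row for (mid, _, _), row in zip(members, rows)},
        gc={"Boxes": boxes_line, "SS_cons": ss},
    )
    return aln


def _guide_order(members) -> list[int]:
    n = len(members)
    if n <= 2:
        return sorted(range(n), key=lambda i: members[i][0])
    # medoid = member with highest mean pairwise identity
    ident = [[0.0] * n for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            a, b = _nw2(members[i][1], members[j][1])
            matches = sum(1 for x, y in zip(a, b) if x == y and x != "-")
            ident[i][j] = ident[j][i] = matches / len(a)
    mean_id = [sum(row) / (n - 1) for row in ident]
    medoid = max(range(n), key=lambda i: (mean_id[i], members[i][0]))
    return sorted(range(n), key=lambda i: (-ident[i][medoid] if i != medoid else -2.0, members[i][0]))


def _consensus_structure(guide, guide_row: str, sno_class: str, params: BoxParams) -> str:
    mid, seq, bs = guide
    if sno_class == "CD":
        check = check_terminal_stem(seq, bs, params)
    else:
        check = check_hairpin_topology(seq, bs, params)
    pos_to_col = {}
    pos = 0
    for col, ch in enumerate(guide_row):
        if ch != "-":
            pos_to_col[pos] = col
            pos += 1
    ss = ["."] * len(guide_row)
    for i, j in check.pairs:
        if i in pos_to_col and j in pos_to_col:
            ss[pos_to_col[i]] = "("
            ss[pos_to_col[j]] = ")"
    return "".join(ss)
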