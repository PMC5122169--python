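"""Guide-target duplex prediction and cross-species conservation.

Box C/D snoRNAs position a 2'-O-methylation by base-pairing an antisense
element (ASE, the 10-15 nt immediately 5' of the D or D' box) with the
target; the methylated residue is the target nucleotide paired with the
fifth guide nucleotide counting from the box (the "+5 rule"). Box H/ACA
snoRNAs clamp the target inside the bipartite interior loop (the
pseudouridylation pocket) of a hairpin, isomerising an unpaired U between
the two half-duplexes.

The duplex model here is deliberately simple: ungapped antiparallel
Watson-Crick + GU complementarity with a small unpaired-budget, which makes
every prediction reproducible by direct window enumeration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from snofamkit.box_annotation import BoxParams, check_hairpin_topology, _hairpin_chains
from snofamkit.core_io import SeqRecord, SnoGene, to_rna
from snofamkit.box_annotation import can_pair


@dataclass
class DuplexParams:
    min_pairs: int = 10          # accepted CD duplexes need this many pairs
    max_unpaired: int = 2        # and at most this many unpaired positions
    mod_offset: int = 5          # the "+5 rule" guide offset from the box
    ase_max_len: int = 15
    ase_min_len: int = 8         # shorter ASEs are flagged, not scanned
    ase_short_flag: int = 10
    haca_max_unpaired: int = 1   # unpaired budget across both pocket halves
    psi_spacer: int = 2          # unpaired target nt between half-duplexes (incl. the U)
    # a *called* site needs a fully paired duplex: with wobble pairs allowed,
    # near-complementary windows occur by chance every few hundred nt, so
    # partially paired scan hits are reported but not called
    call_min_score: float = 1.0
    box_params: BoxParams = field(default_factory=BoxParams)


@dataclass(frozen=True)
class AntisenseElement:
    """A guide region; for H/ACA pockets ``seq`` is the 5' half and
    ``seq2`` the 3' half of the interior loop."""

    gene_id: str
    family: str
    species: str
    location: str            # upstream_D | upstream_Dprime | pocket_5p | pocket_3p
    seq: str
    start: int               # offsets within the snoRNA, 0-based half-open
    end: int
    seq2: str = ""
    start2: int = -1
    end2: int = -1
    short: bool = False


@dataclass(frozen=True)
class TargetSite:
    target_id: str
    window: tuple[int, int]   # 1-based inclusive on the target
    score: float              # paired fraction
    ase: AntisenseElement
    modified_pos: int = 0     # 1-based; 0 until called
    mod_type: str = ""        # Nm | Psi
    duplex: str = ""


def extract_ase(gene: SnoGene, params: DuplexParams | None = None) -> list[AntisenseElement]:
    """The guide elements of one snoRNA.

    CD: up to two ASEs, the <=15 nt immediately 5' of the D and D' boxes
    (truncated where boxes collide). HACA: the unpaired interior-loop halves
    of each hairpin from the constrained-folding topology check.
    """
    params = params or DuplexParams()
    if gene.boxes is None:
        raise ValueError(f"gene {gene.gene_id} has no box annotation")
    bs = gene.boxes
    seq = to_rna(gene.seq)
    out: list[AntisenseElement] = []
    if gene.sno_class == "CD":
        d = bs.get("D")
        if d is None:
            raise ValueError(f"CD gene {gene.gene_id} lacks a D box")
        dp = bs.get("Dprime")
        cp = bs.get("Cprime")
        c = bs.get("C")
        # upstream of D: bounded by the closest preceding box
        lo = max(h.end for h in (c, cp, dp) if h is not None)
        s = max(lo, d.start - params.ase_max_len)
        out.append(_mk_ase(gene, "upstream_D", seq[s:d.start], s, d.start, params))
        if dp is not None and c is not None:
            s = max(c.end, dp.start - params.ase_max_len)
            out.append(_mk_ase(gene, "upstream_Dprime", seq[s:dp.start], s, dp.start, params))
        return out

    check = check_hairpin_topology(seq, bs, params.box_params)
    h = bs.get("H")
    aca = bs.get("ACA")
    segments = [("pocket_5p", 0, h.start), ("pocket_3p", h.end, aca.start)]
    for tag, s0, e0 in segments:
        local = [(i - s0, j - s0) for i, j in check.pairs if s0 <= i and j < e0]
        for chain in _hairpin_chains(local):
            pocket = _find_pocket(chain, params.box_params.min_pocket)
            if pocket is None:
                continue
            (i, j), (i2, j2) = pocket
            out.append(
                AntisenseElement(
                    gene_id=gene.gene_id,
                    family=gene.family,
                    species=gene.species,
                    location=tag,
                    seq=seq[s0 + i + 1: s0 + i2],
                    start=s0 + i + 1,
                    end=s0 + i2,
                    seq2=seq[s0 + j2 + 1: s0 + j],
                    start2=s0 + j2 + 1,
                    end2=s0 + j,
                )
            )
            break
    return out


def _mk_ase(gene: SnoGene, loc: str, seq: str, s: int, e: int, params: DuplexParams) -> AntisenseElement:
    return AntisenseElement(
        gene_id=gene.gene_id,
        family=gene.family,
        species=gene.species,
        location=loc,
        seq=seq,
        start=s,
        end=e,
        short=len(seq) < params.ase_short_flag,
    )


def _find_pocket(chain, min_pocket):
    for p, q in zip(chain, chain[1:]):
        (i, j), (i2, j2) = p, q
        if i2 - i - 1 >= min_pocket and j - j2 - 1 >= min_pocket:
            return p, q
    return None


# ---------------------------------------------------------------------------
# Duplex scanning


def duplex_scan(
    ase: AntisenseElement,
    target: SeqRecord,
    params: DuplexParams | None = None,
    min_paired: int | None = None,
) -> list[TargetSite]:
    """All accepted guide-target duplex windows, best first.

    CD: every ungapped antiparallel window of the ASE against the target
    with >= ``min_paired`` WC/GU pairs (default: max(min_pairs,
    len - max_unpaired)). HACA: both pocket halves must pair around a
    ``psi_spacer``-nt unpaired hinge whose first nucleotide is the
    candidate U.
    """
    params = params or DuplexParams()
    if ase.location.startswith("pocket"):
        return _duplex_scan_haca(ase, target, params)
    guide = to_rna(ase.seq)
    L = len(guide)
    if L < params.ase_min_len:
        return []
    if min_paired is None:
        min_paired = max(params.min_pairs, L - params.max_unpaired)
    tseq = to_rna(target.seq)
    sites = []
    for s in range(len(tseq) - L + 1):
        paired = sum(
            1 for k in range(L) if can_pair(guide[k], tseq[s + L - 1 - k])
        )
        if paired >= min_paired:
            duplex = f"{tseq[s:s + L]}&{guide}"
            sites.append(
                TargetSite(
                    target_id=target.id,
                    window=(s + 1, s + L),
                    score=paired / L,
                    ase=ase,
                    duplex=duplex,
                )
            )
    sites.sort(key=lambda x: (-x.score, x.window[0]))
    return sites


def _duplex_scan_haca(ase: AntisenseElement, target: SeqRecord, params: DuplexParams) -> list[TargetSite]:
    h5, h3 = to_rna(ase.seq), to_rna(ase.seq2)
    if not h5 or not h3:
        return []
    tseq = to_rna(target.seq)
    span = len(h3) + params.psi_spacer + len(h5)
    sites = []
    for s in range(len(tseq) - span + 1):
        # target 5' flank pairs the 3' pocket half, 3' flank the 5' half
        up = sum(1 for k in range(len(h3)) if can_pair(h3[k], tseq[s + len(h3) - 1 - k]))
        dn_start = s + len(h3) + params.psi_spacer
        dn = sum(1 for k in range(len(h5)) if can_pair(h5[k], tseq[dn_start + len(h5) - 1 - k]))
        unpaired = (len(h3) - up) + (len(h5) - dn)
        if unpaired <= params.haca_max_unpaired:
            duplex = f"{tseq[s:s + span]}&{h5}..{h3}"
            sites.append(
                TargetSite(
                    target_id=target.id,
                    window=(s + 1, s + span),
                    score=(up + dn) / (len(h3) + len(h5)),
                    ase=ase,
                    duplex=duplex,
                )
            )
    sites.sort(key=lambda x: (-x.score, x.window[0]))
    return sites


def call_modification_site(
    site: TargetSite, target: SeqRecord, params: DuplexParams | None = None
) -> TargetSite | None:
    """Place the modified residue on an accepted duplex.

    CD (+offset rule): the modified nucleotide is the target partner of the
    ``mod_offset``-th guide nucleotide counting from the box, i.e. window
    start + offset - 1 (1-based); type Nm. HACA: the first unpaired hinge
    nucleotide between the half-duplexes; must be a U (type Psi), otherwise
    the site is rejected (returns None).
    """
    params = params or DuplexParams()
    ase = site.ase
    if ase.location.startswith("upstream"):
        if len(ase.seq) < params.mod_offset:
            raise ValueError(
                f"ASE of {ase.gene_id} shorter than the modification offset "
                f"({len(ase.seq)} < {params.mod_offset})"
            )
        pos = site.window[0] + params.mod_offset - 1
        return TargetSite(
            target_id=site.target_id,
            window=site.window,
            score=site.score,
            ase=ase,
            modified_pos=pos,
            mod_type="Nm",
            duplex=site.duplex,
        )
    # H/ACA: hinge U right after the 5'-side half-duplex
    pos = site.window[0] + len(to_rna(ase.seq2))  # 1-based hinge position
    tseq = to_rna(target.seq)
    if tseq[pos - 1] != "U":
        return None
    return TargetSite(
        target_id=site.target_id,
        window=site.window,
        score=site.score,
        ase=ase,
        modified_pos=pos,
        mod_type="Psi",
        duplex=site.duplex,
    )


def predict_targets(
    genes: list[SnoGene],
    targets: list[SeqRecord],
    params: DuplexParams | None = None,
) -> dict[str, list[TargetSite]]:
    """Accepted, position-called target sites per family (best site per
    gene x ASE x target)."""
    params = params or DuplexParams()
    out: dict[str, list[TargetSite]] = {}
    for gene in genes:
        for ase in extract_ase(gene, params):
            if ase.location.startswith("upstream") and (
                ase.short or len(ase.seq) < params.ase_min_len
            ):
                continue
            for t in targets:
                for raw in duplex_scan(ase, t, params):
                    if raw.score < params.call_min_score:
                        break  # sorted by score: nothing further qualifies
                    called = call_modification_site(raw, t, params)
                    if called is not None:
                        out.setdefault(gene.family, []).append(called)
                        break
    return out


def mark_orphans(
    families: list[str], sites_by_family: dict[str, list[TargetSite]]
) -> list[str]:
    """Families with no accepted target site in any species."""
    return sorted(f for f in families if not sites_by_family.get(f))


# ---------------------------------------------------------------------------
# Conservation tables


@dataclass
class ConservationTable:
    """Cross-species view of one guide-target interaction.

    One row per species, rendered ``targetSegment&ASE`` with the modified
    residue marked ``M`` and the predicted position appended; pair columns
    are classified conserved_pair / compensatory / lost.
    """

    family: str
    species: list[str]
    target_segments: list[str]
    ases: list[str]
    positions: list[int]          # 1-based modification positions per species
    mod_col: int                  # column of the modified residue in the segment
    classes: list[str]
    conservation: list[float]

    def render(self) -> str:
        width = len(self.target_segments[0])
        name_w = max(len(s) for s in self.species)
        lines = [f"# family {self.family}"]
        marker = [" "] * width
        marker[self.mod_col] = "M"
        lines.append(" " * name_w + "  " + "".join(marker))
        for sp, seg, ase, pos in zip(self.species, self.target_segments, self.ases, self.positions):
            lines.append(f"{sp:<{name_w}}  {seg}&{ase}  {pos}")
        lines.append(" " * name_w + "  " + "".join(c[0].upper() if c != "unclassified" else "." for c in self.classes))
        bar = "".join(_bar_char(f) for f in self.conservation)
        lines.append(" " * name_w + "  " + bar)
        return "\n".join(lines) + "\n"


def _bar_char(f: float) -> str:
    return " .:|#"[min(4, int(f * 5))] if f < 1 else "#"


def build_conservation_table(
    family: str, sites: list[TargetSite], targets: dict[str, SeqRecord]
) -> ConservationTable:
    """Classify per-pair-column conservation across >=2 species.

    conserved_pair: the same base pair in every row; compensatory: paired
    in every row with >=2 distinct pair identities; lost: unpaired in >=1
    row while the majority of rows pair; anything else unclassified.
    """
    if len(sites) < 2:
        raise ValueError("conservation table needs at least two species rows")
    L = len(to_rna(sites[0].ase.seq))
    rows = []
    for site in sites:
        seg = to_rna(targets[site.target_id].seq)[site.window[0] - 1: site.window[1]]
        if len(seg) != L or len(to_rna(site.ase.seq)) != L:
            raise ValueError("rows of a conservation table must share the duplex length")
        rows.append((site.ase.species, seg, to_rna(site.ase.seq), site.modified_pos))

    classes = []
    for col in range(L):
        pairs = [(seg[col], ase[L - 1 - col]) for _, seg, ase, _ in rows]
        paired = [can_pair(t, g) for t, g in pairs]
        if all(paired):
            classes.append("conserved_pair" if len(set(pairs)) == 1 else "compensatory")
        elif sum(paired) * 2 > len(paired):
            classes.append("lost")
        else:
            classes.append("unclassified")

    conservation = []
    for col in range(L):
        chars = [seg[col] for _, seg, _, _ in rows]
        conservation.append(max(chars.count(c) for c in set(chars)) / len(chars))

    mod_col = sites[0].modified_pos - sites[0].window[0]
    return ConservationTable(
        family=family,
        species=[r[0] for r in rows],
        target_segments=[r[1] for r in rows],
        ases=[r[2] for r in rows],
        positions=[r[3] for r in rows],
        mod_col=mod_col,
        classes=classes,
        conservation=conservation,
    )
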