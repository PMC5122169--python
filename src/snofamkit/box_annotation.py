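"""Box-motif and structure annotation of snoRNA candidates.

Box C/D snoRNAs carry a C box (RUGAUGA) near the 5' end and a D box (CUGA)
near the 3' end, frequently with more variable internal C'/D' copies; the
flanks fold back into a short terminal stem. Box H/ACA snoRNAs end in an
ACA triplet, carry an H box (ANANNA) in the hinge between two hairpins, and
fold hairpin-hinge-hairpin-tail with an internal-loop "pocket" in each
hairpin.

This module locates the boxes by degenerate (IUPAC) pattern matching with a
per-box mismatch budget, scores consistent box combinations (spacer lengths
between C/D' and C'/D are scored against the typical 12 nt), and validates
the class-specific secondary structure with a base-pair-maximizing
(Nussinov) dynamic program in which box nucleotides are held unpaired.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from snofamkit.core_io import IUPAC_RNA, to_rna

# ---------------------------------------------------------------------------
# Patterns


@dataclass(frozen=True)
class BoxPattern:
    name: str
    iupac: str
    max_mismatch: int = 0

    def __post_init__(self) -> None:
        bad = sorted(set(self.iupac) - set(IUPAC_RNA))
        if bad:
            raise ValueError(f"non-IUPAC characters in pattern {self.name}: {bad}")
        if self.max_mismatch < 0:
            raise ValueError("max_mismatch must be >= 0")


#: Default box patterns. Internal C'/D' copies use the same consensus as
#: C/D but tolerate one extra mismatch, reflecting their higher variability.
DEFAULT_PATTERNS: dict[str, BoxPattern] = {
    "C": BoxPattern("C", "RUGAUGA", 1),
    "D": BoxPattern("D", "CUGA", 1),
    "Cprime": BoxPattern("Cprime", "RUGAUGA", 2),
    "Dprime": BoxPattern("Dprime", "CUGA", 2),
    "H": BoxPattern("H", "ANANNA", 0),
    "ACA": BoxPattern("ACA", "ACA", 0),
}


@dataclass(frozen=True)
class BoxHit:
    name: str
    start: int
    end: int
    mismatches: int


@dataclass(frozen=True)
class BoxSet:
    """The consistent set of boxes annotated on one snoRNA sequence."""

    sno_class: str  # "CD" | "HACA"
    hits: tuple[BoxHit, ...]
    score: float
    spacer_cd_dprime: int | None = None
    spacer_cprime_d: int | None = None

    def get(self, name: str) -> BoxHit | None:
        for h in self.hits:
            if h.name == name:
                return h
        return None

    @property
    def total_mismatches(self) -> int:
        return sum(h.mismatches for h in self.hits)


@dataclass(frozen=True)
class StructureCheck:
    kind: str  # "terminal_stem" | "hairpin_topology"
    passed: bool
    stem_length: int = 0
    pairs: tuple[tuple[int, int], ...] = ()
    details: tuple[tuple[str, object], ...] = ()


@dataclass
class BoxParams:
    """Tunable thresholds for annotation and classification (config-exposed)."""

    patterns: dict[str, BoxPattern] = field(default_factory=lambda: dict(DEFAULT_PATTERNS))
    cd_min_len: int = 50
    cd_max_len: int = 300
    haca_min_len: int = 80
    haca_max_len: int = 300
    c_start_max: int = 10       # C box must start within the 5' leader window
    d_end_window: int = 10      # D box must end within this many nt of the 3' end
    spacer_min: int = 2
    spacer_max: int = 60
    spacer_optimum: int = 12    # typical C/D' and C'/D spacing
    spacer_weight: float = 0.25
    box_bonus: float = 2.0      # reward for an included optional C'/D' box
    hinge_lo: float = 0.35      # H box window as fraction of length
    hinge_hi: float = 0.65
    min_stem: int = 3           # terminal stem pairs required for CD
    flank: int = 6              # nt considered on each side for the terminal stem
    min_hairpin_stem: int = 5   # per-hairpin pairs required for H/ACA
    min_pocket: int = 3         # interior-loop nt per side (the pocket)
    min_helix: int = 3          # shorter helices are ignored in topology calls
    require_kturn_ga: bool = False


def iupac_match(pattern_char: str, seq_char: str) -> bool:
    """True when the two IUPAC codes share at least one concrete base."""
    return not IUPAC_RNA[pattern_char].isdisjoint(IUPAC_RNA[seq_char])


def match_iupac(pattern: BoxPattern, seq: str) -> list[BoxHit]:
    """All windows matching ``pattern`` with at most ``max_mismatch``
    mismatches under IUPAC semantics, sorted by (mismatches, start)."""
    seq = to_rna(seq)
    p = pattern.iupac
    n, m = len(seq), len(p)
    hits = []
    for i in range(n - m + 1):
        mm = sum(1 for k in range(m) if not iupac_match(p[k], seq[i + k]))
        if mm <= pattern.max_mismatch:
            hits.append(BoxHit(pattern.name, i, i + m, mm))
    hits.sort(key=lambda h: (h.mismatches, h.start))
    return hits


# ---------------------------------------------------------------------------
# Box C/D annotation


def annotate_cd_boxes(seq: str, params: BoxParams | None = None) -> BoxSet | None:
    """Annotate C, D and (optionally) D', C' boxes on a candidate.

    The mandatory C box must start within the 5' leader window and the D box
    must end within the 3' window. Optional internal D'/C' boxes are added
    when a placement in [spacer_min, spacer_max] of the respective partner
    box exists and improves the combination score: each included optional
    box earns ``box_bonus`` minus its mismatches, and each present spacer is
    penalised by w * |spacer - optimum|. Returns None when C or D cannot be
    placed.
    """
    params = params or BoxParams()
    seq = to_rna(seq)
    L = len(seq)
    if L < params.cd_min_len or L > params.cd_max_len:
        return None

    c_hits = [h for h in match_iupac(params.patterns["C"], seq) if h.start <= params.c_start_max]
    d_hits = [h for h in match_iupac(params.patterns["D"], seq) if h.end >= L - params.d_end_window]
    if not c_hits or not d_hits:
        return None
    dp_hits = match_iupac(params.patterns["Dprime"], seq)
    cp_hits = match_iupac(params.patterns["Cprime"], seq)

    best: tuple | None = None
    for c in c_hits:
        for d in d_hits:
            if d.start < c.end:
                continue
            for dp in [None] + dp_hits:
                if dp is not None:
                    sp1 = dp.start - c.end
                    if not (params.spacer_min <= sp1 <= params.spacer_max) or dp.end > d.start:
                        continue
                else:
                    sp1 = None
                for cp in [None] + cp_hits:
                    if cp is not None:
                        sp2 = d.start - cp.end
                        if not (params.spacer_min <= sp2 <= params.spacer_max) or cp.start < c.end:
                            continue
                        if dp is not None and cp.start < dp.end:
                            continue
                    else:
                        sp2 = None
                    combo = _score_cd_combo(c, d, dp, cp, sp1, sp2, params)
                    if best is None or combo[0] > best[0]:
                        best = combo
    if best is None:
        return None
    _, boxset = best
    return boxset


def _score_cd_combo(c, d, dp, cp, sp1, sp2, params: BoxParams):
    hits = [c] + ([dp] if dp else []) + ([cp] if cp else []) + [d]
    mism = sum(h.mismatches for h in hits)
    penalty = 0.0
    for sp in (sp1, sp2):
        if sp is not None:
            penalty += params.spacer_weight * abs(sp - params.spacer_optimum)
    bonus = params.box_bonus * (len(hits) - 2)
    score = bonus - mism - penalty
    # best score, then fewer mismatches, then 5'-most
    key = (score, -mism, -c.start, -d.start)
    boxset = BoxSet(
        sno_class="CD",
        hits=tuple(hits),
        score=score,
        spacer_cd_dprime=sp1,
        spacer_cprime_d=sp2,
    )
    return key, boxset


# ---------------------------------------------------------------------------
# Box H/ACA annotation


def annotate_haca_boxes(seq: str, params: BoxParams | None = None) -> BoxSet | None:
    """Annotate the H box (hinge) and the terminal ACA triplet.

    The ACA must occupy the last 3 nt exactly; the H box is searched in the
    hinge window [hinge_lo*L, hinge_hi*L] and the fewest-mismatch, most
    central hit wins. Returns None when either motif is absent.
    """
    params = params or BoxParams()
    seq = to_rna(seq)
    L = len(seq)
    if L < params.haca_min_len or L > params.haca_max_len:
        return None
    if seq[-3:] != "ACA":
        return None
    aca = BoxHit("ACA", L - 3, L, 0)

    lo = int(params.hinge_lo * L)
    hi = int(params.hinge_hi * L)
    h_hits = [
        h for h in match_iupac(params.patterns["H"], seq)
        if h.start >= lo and h.end <= hi
    ]
    if not h_hits:
        return None
    center = L / 2
    h = min(h_hits, key=lambda x: (x.mismatches, abs((x.start + x.end) / 2 - center), x.start))
    return BoxSet(sno_class="HACA", hits=(h, aca), score=-float(h.mismatches))


# ---------------------------------------------------------------------------
# Structure checks

_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}


def can_pair(a: str, b: str) -> bool:
    return (a, b) in _PAIRS


def check_terminal_stem(seq: str, boxset: BoxSet, params: BoxParams | None = None) -> StructureCheck:
    """Longest contiguous antiparallel complementary run (WC + GU) between
    the flank upstream of the C box and the flank downstream of the D box."""
    params = params or BoxParams()
    seq = to_rna(seq)
    c = boxset.get("C")
    d = boxset.get("D")
    if c is None or d is None:
        raise ValueError("terminal stem check requires C and D boxes")
    f5 = seq[max(0, c.start - params.flank): c.start]
    f3 = seq[d.end: d.end + params.flank]
    off5 = max(0, c.start - params.flank)
    off3 = d.end

    best_len, best_pairs = 0, ()
    for i in range(len(f5)):
        for j in range(len(f3) - 1, -1, -1):
            run = []
            a, b = i, j
            while a < len(f5) and b >= 0 and can_pair(f5[a], f3[b]):
                run.append((off5 + a, off3 + b))
                a += 1
                b -= 1
            if len(run) > best_len:
                best_len, best_pairs = len(run), tuple(run)

    ga = {seq[c.start], seq[d.end - 1]} == {"G", "A"}
    passed = best_len >= params.min_stem and (ga or not params.require_kturn_ga)
    return StructureCheck(
        kind="terminal_stem",
        passed=passed,
        stem_length=best_len,
        pairs=best_pairs,
        details=(("kturn_ga", ga),),
    )


_PAIR_UNIT = 512  # packs (pairs, stacked pairs) into one int; stacks < 512


def nussinov(
    seq: str,
    unpaired: frozenset[int] | set[int] = frozenset(),
    min_loop: int = 3,
) -> tuple[int, list[tuple[int, int]]]:
    """Maximum base pairing (WC + GU, hairpin loop >= ``min_loop``) with the
    given positions constrained unpaired; returns (pair count, pair list).

    Among all maximum-pairing structures the one with the most stacked
    (helix-contiguous) pairs is returned, so point changes that open up
    alternative isolated pairs do not reshuffle a well-stacked fold.
    """
    seq = to_rna(seq)
    n = len(seq)
    NEG = -(1 << 40)
    # W[i][j]: best packed score of [i, j]; P[i][j]: best given (i, j) paired
    W = [[0] * n for _ in range(n)]
    P = [[NEG] * n for _ in range(n)]

    def pairable(i: int, j: int) -> bool:
        return (
            j - i > min_loop
            and i not in unpaired
            and j not in unpaired
            and can_pair(seq[i], seq[j])
        )

    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            if pairable(i, j):
                inner = W[i + 1][j - 1]
                stacked = P[i + 1][j - 1] + 1
                P[i][j] = _PAIR_UNIT + (stacked if stacked > inner else inner)
            best = W[i + 1][j]
            for h in range(i + min_loop + 1, j + 1):
                if P[i][h] > NEG:
                    cand = P[i][h] + (W[h + 1][j] if h + 1 <= j else 0)
                    if cand > best:
                        best = cand
            W[i][j] = best

    pairs: list[tuple[int, int]] = []
    stack: list[tuple[int, int, str]] = [(0, n - 1, "W")] if n > 1 else []
    while stack:
        i, j, mode = stack.pop()
        if j - i <= min_loop:
            continue
        if mode == "P":
            pairs.append((i, j))
            if P[i][j] - _PAIR_UNIT == P[i + 1][j - 1] + 1:
                stack.append((i + 1, j - 1, "P"))
            else:
                stack.append((i + 1, j - 1, "W"))
            continue
        if W[i][j] == W[i + 1][j]:
            stack.append((i + 1, j, "W"))
            continue
        for h in range(i + min_loop + 1, j + 1):
            if P[i][h] > NEG and W[i][j] == P[i][h] + (W[h + 1][j] if h + 1 <= j else 0):
                stack.append((i, h, "P"))
                if h + 1 <= j:
                    stack.append((h + 1, j, "W"))
                break
    pairs.sort()
    return (W[0][n - 1] // _PAIR_UNIT if n > 1 else 0), pairs


def _hairpin_chains(pairs: list[tuple[int, int]]) -> list[list[tuple[int, int]]]:
    """Decompose a nested pair set into root-to-terminal-loop pair chains."""
    children: dict[tuple[int, int] | None, list[tuple[int, int]]] = {None: []}
    ordered = sorted(pairs)
    stack: list[tuple[int, int]] = []
    for p in ordered:
        while stack and not (stack[-1][0] < p[0] and p[1] < stack[-1][1]):
            stack.pop()
        parent = stack[-1] if stack else None
        children.setdefault(parent, []).append(p)
        children.setdefault(p, [])
        stack.append(p)

    chains: list[list[tuple[int, int]]] = []

    def walk(p, chain):
        chain = chain + [p]
        kids = children.get(p, [])
        if not kids:
            chains.append(chain)
        elif len(kids) == 1:
            walk(kids[0], chain)
        else:
            for k in kids:  # multiloop: each branch starts a fresh hairpin
                walk(k, [])
            chains.append(chain)

    for root in children[None]:
        walk(root, [])
    return [c for c in chains if c]


def nussinov_helices(
    seq: str,
    unpaired: frozenset[int] | set[int] = frozenset(),
    min_loop: int = 3,
    min_helix: int = 2,
) -> tuple[int, list[tuple[int, int]]]:
    """Base-pair maximization over structures built from helices of at
    least ``min_helix`` stacked pairs (isolated pairs score nothing).

    This is the folding used for topology calls: a point change that opens
    one stray complementary pair cannot outweigh a well-stacked designed
    fold. Ties in pair count favour longer helices.
    """
    seq = to_rna(seq)
    n = len(seq)
    if min_helix <= 1:
        return nussinov(seq, unpaired, min_loop)

    def pairable(i: int, j: int) -> bool:
        return (
            j - i > min_loop
            and i not in unpaired
            and j not in unpaired
            and can_pair(seq[i], seq[j])
        )

    NEG = -(1 << 40)
    W = [[0] * (n + 1) for _ in range(n + 1)]
    # H[i][j]: best packed score of [i, j] with a helix starting at (i, j)
    H = [[NEG] * n for _ in range(n)]
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            # extend a helix (i, j), (i+1, j-1), ... of length >= min_helix
            best_h = NEG
            ell = 0
            while (
                i + ell < j - ell
                and (j - ell) - (i + ell) > min_loop
                and pairable(i + ell, j - ell)
            ):
                ell += 1
                if ell >= min_helix:
                    cand = ell * _PAIR_UNIT + (ell - 1) + W[i + ell][j - ell + 1]
                    if cand > best_h:
                        best_h = cand
            H[i][j] = best_h
            best = W[i + 1][j + 1]
            for h in range(i + min_loop + 1, j + 1):
                if H[i][h] > NEG:
                    cand = H[i][h] + W[h + 1][j + 1]
                    if cand > best:
                        best = cand
            W[i][j + 1] = best  # W indexed [i][j+1] = interval [i, j]

    pairs: list[tuple[int, int]] = []
    stack: list[tuple[int, int, str]] = [(0, n - 1, "W")] if n > 1 else []
    while stack:
        i, j, mode = stack.pop()
        if j - i <= min_loop:
            continue
        if mode == "H":
            ell = 0
            target = H[i][j]
            while True:
                ell += 1
                if (
                    ell >= min_helix
                    and target == ell * _PAIR_UNIT + (ell - 1) + W[i + ell][j - ell + 1]
                ):
                    break
            for k in range(ell):
                pairs.append((i + k, j - k))
            if (j - ell) - (i + ell) > min_loop:
                stack.append((i + ell, j - ell, "W"))
            continue
        if W[i][j + 1] == W[i + 1][j + 1]:
            stack.append((i + 1, j, "W"))
            continue
        for h in range(i + min_loop + 1, j + 1):
            if H[i][h] > NEG and W[i][j + 1] == H[i][h] + W[h + 1][j + 1]:
                stack.append((i, h, "H"))
                if h + 1 <= j:
                    stack.append((h + 1, j, "W"))
                break
    pairs.sort()
    return (W[0][n] // _PAIR_UNIT if n > 1 else 0), pairs


def _filter_helices(
    pairs: list[tuple[int, int]], min_helix: int
) -> list[tuple[int, int]]:
    """Drop helices (maximal stacked runs) shorter than ``min_helix`` —
    isolated pairs are folding noise, not architecture."""
    if min_helix <= 1:
        return list(pairs)
    runs: list[list[tuple[int, int]]] = []
    for p in sorted(pairs):
        if runs and (p[0] - 1, p[1] + 1) == runs[-1][-1]:
            runs[-1].append(p)
        else:
            runs.append([p])
    return [p for run in runs if len(run) >= min_helix for p in run]


def _chain_has_pocket(chain: list[tuple[int, int]], min_pocket: int) -> bool:
    for (i, j), (i2, j2) in zip(chain, chain[1:]):
        if i2 - i - 1 >= min_pocket and j - j2 - 1 >= min_pocket:
            return True
    return False


def check_hairpin_topology(seq: str, boxset: BoxSet, params: BoxParams | None = None) -> StructureCheck:
    """Hairpin-hinge-hairpin check for H/ACA candidates.

    Each of the 5' segment (before the H box) and the 3' segment (between H
    box and ACA) must fold, by constrained base-pair maximization, into at
    least one hairpin with >= ``min_hairpin_stem`` pairs containing an
    interior loop of >= ``min_pocket`` nt per side (the pseudouridylation
    pocket). H-box and ACA nucleotides are held unpaired.
    """
    params = params or BoxParams()
    seq = to_rna(seq)
    h = boxset.get("H")
    aca = boxset.get("ACA")
    if h is None or aca is None:
        raise ValueError("hairpin topology check requires H and ACA boxes")

    segments = [(0, h.start), (h.end, aca.start)]
    all_pairs: list[tuple[int, int]] = []
    seg_pass = []
    for s, e in segments:
        sub = seq[s:e]
        _, pairs = nussinov_helices(sub, min_helix=params.min_helix)
        pairs = _filter_helices(pairs, params.min_helix)
        pairs = [(i + s, j + s) for i, j in pairs]
        all_pairs.extend(pairs)
        ok = False
        for chain in _hairpin_chains([(i - s, j - s) for i, j in pairs]):
            if len(chain) >= params.min_hairpin_stem and _chain_has_pocket(chain, params.min_pocket):
                ok = True
                break
        seg_pass.append(ok)

    return StructureCheck(
        kind="hairpin_topology",
        passed=all(seg_pass),
        stem_length=len(all_pairs),
        pairs=tuple(sorted(all_pairs)),
        details=(("hairpin_5p", seg_pass[0]), ("hairpin_3p", seg_pass[1])),
    )


# ---------------------------------------------------------------------------
# Classification


def classify_snoRNA(
    seq: str, params: BoxParams | None = None
) -> tuple[str, BoxSet, tuple[StructureCheck, ...]] | None:
    """Classify a candidate as box C/D or box H/ACA.

    Both annotations are attempted; candidates with boxes are ranked by
    (structure check passed, box score), ties resolved in favour of CD.
    Returns None when neither class's mandatory boxes can be placed.
    """
    params = params or BoxParams()
    candidates = []

    cd = annotate_cd_boxes(seq, params)
    if cd is not None:
        stem = check_terminal_stem(seq, cd, params)
        candidates.append((("CD", cd, (stem,)), (stem.passed, cd.score, 1)))

    haca = annotate_haca_boxes(seq, params)
    if haca is not None:
        topo = check_hairpin_topology(seq, haca, params)
        candidates.append((("HACA", haca, (topo,)), (topo.passed, haca.score, 0)))

    if not candidates:
        return None
    candidates.sort(key=lambda c: c[1], reverse=True)
    return candidates[0][0]
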