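"""Seeding, local alignment, candidate filtering and family alignment."""

import itertools

import pytest

from snofamkit.box_annotation import annotate_cd_boxes
from snofamkit.core_io import GenomicInterval, SeqRecord, revcomp_rna, to_rna
from snofamkit.homology_search import (
    AlignScoring,
    Candidate,
    SearchParams,
    align_family,
    build_family_query,
    extend_align,
    filter_candidates,
    iterate_search,
    search_genome,
    seed_scan,
    sum_of_pairs,
)

CD_ARCH = (
    "GGCAC" + "AUGAUGA" + "GAUCGAUCGAUC" + "CUGA" + "AAAAAAAAAA"
    + "GUGAUGA" + "CCAUGGCAUCGA" + "CUGA" + "GUGCC"
)


def _query(seq=CD_ARCH, fam="fam1", cls="CD"):
    return build_family_query(fam, cls, [SeqRecord(id="m1", seq=seq)])


def sw_oracle(a: str, b: str, sc: AlignScoring):
    """Independent quadratic Smith-Waterman with affine gaps (Gotoh)."""
    n, m = len(a), len(b)
    NEG = float("-inf")
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consume a)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            X[i][j] = max(
                M[i - 1][j] + sc.gap_open + sc.gap_extend,
                X[i - 1][j] + sc.gap_extend,
            )
            Y[i][j] = max(
                M[i][j - 1] + sc.gap_open + sc.gap_extend,
                Y[i][j - 1] + sc.gap_extend,
            )
            sub = sc.match if a[i - 1] == b[j - 1] else sc.mismatch
            M[i][j] = max(0.0, M[i - 1][j - 1] + sub, X[i][j], Y[i][j])
            best = max(best, M[i][j])
    return best


class TestExtendAlign:
    def test_identical_fifty_mer(self, rng):
        s = "".join(rng.choice(list("ACGU"), size=50))
        res = extend_align(s, s)
        assert res.score == 100.0
        assert res.identity == 1.0
        assert res.window_span == (0, 50) and res.query_span == (0, 50)

    def test_single_substitution_matches_oracle(self, rng):
        sc = AlignScoring()
        for _ in range(20):
            s = "".join(rng.choice(list("ACGU"), size=50))
            pos = int(rng.integers(0, 50))
            alt = [b for b in "ACGU" if b != s[pos]][int(rng.integers(0, 3))]
            t = s[:pos] + alt + s[pos + 1:]
            assert extend_align(s, t).score == sw_oracle(s, t, sc)

    def test_random_pairs_match_oracle(self, rng):
        sc = AlignScoring()
        for _ in range(30):
            w = "".join(rng.choice(list("ACGU"), size=200))
            q = "".join(rng.choice(list("ACGU"), size=40))
            assert extend_align(w, q).score == sw_oracle(w, q, sc)

    def test_no_alignment_on_disjoint_alphabets(self):
        res = extend_align("AAAA", "GGGG")
        assert res.score == 0.0


class TestSeedScan:
    def test_verbatim_plant_found(self, rng):
        bg = "".join(rng.choice(list("ACGT"), size=4000))
        genome = [SeqRecord(id="chr1", seq=bg[:2000] + CD_ARCH.replace("U", "T") + bg[2000:])]
        ivs = seed_scan(_query(), genome, word=9)
        assert any(iv.start <= 2000 and iv.end >= 2000 + len(CD_ARCH) for iv in ivs)

    def test_n_genome_empty(self):
        genome = [SeqRecord(id="chr1", seq="N" * 1000)]
        assert seed_scan(_query(), genome, word=9) == []

    def test_preserved_word_detection_matches_enumeration(self, rng):
        """A diverged copy is seeded iff it retains >= 1 exact query word."""
        q = _query()
        word = 9
        qwords = set()
        s = to_rna(CD_ARCH)
        for i in range(len(s) - word + 1):
            qwords.add(s[i:i + word])
        for _ in range(30):
            copy = list(CD_ARCH)
            for pos in rng.choice(len(copy), size=int(0.1 * len(copy)), replace=False):
                copy[pos] = [b for b in "ACGU" if b != copy[pos]][int(rng.integers(0, 3))]
            copy = "".join(copy)
            preserved = any(
                copy[i:i + word] in qwords for i in range(len(copy) - word + 1)
            )
            genome = [SeqRecord(id="c", seq="A" * 300 + copy.replace("U", "T") + "A" * 300)]
            ivs = seed_scan(q, genome, word)
            hit = any(iv.start < 300 + len(copy) and iv.end > 300 for iv in ivs)
            assert hit == preserved

    def test_minus_strand_seeded(self):
        genome = [SeqRecord(id="c", seq="A" * 200 + revcomp_rna(CD_ARCH).replace("U", "T") + "A" * 200)]
        ivs = seed_scan(_query(), genome, word=9)
        assert ivs


def _mk_candidate(seq, identity=1.0, coverage=1.0):
    return Candidate(
        family="fam1", species="sp1",
        interval=GenomicInterval("chr1", 100, 100 + len(seq)),
        seq=seq, score=2.0 * len(seq), identity=identity, coverage=coverage,
        source_member="m1",
    )


class TestFilterCandidates:
    def test_planted_zero_divergence_retained(self):
        cand = _mk_candidate("AAA" + CD_ARCH + "AAA")
        filter_candidates([cand], "CD")
        assert cand.retained
        assert cand.seq == CD_ARCH  # trimmed to mature bounds

    def test_low_identity_rejected(self):
        cand = _mk_candidate("AAA" + CD_ARCH + "AAA", identity=0.3)
        filter_candidates([cand], "CD")
        assert cand.status == "rejected:low_identity"

    def test_missing_d_box_rejected(self):
        broken = CD_ARCH.replace("CUGA" + "GUGCC", "AAAA" + "GUGCC")
        cand = _mk_candidate("AAA" + broken + "AAA")
        filter_candidates([cand], "CD")
        assert cand.status.startswith("rejected:no_box")
        assert "D" in cand.status

    def test_reject_reasons_are_reported(self):
        cands = [
            _mk_candidate("AAA" + CD_ARCH + "AAA"),
            _mk_candidate("AAA" + CD_ARCH + "AAA", coverage=0.1),
        ]
        filter_candidates(cands, "CD")
        assert cands[0].retained
        assert cands[1].status == "rejected:low_coverage"


class TestSearchGenome:
    def test_perfect_copy_recovered_with_exact_coordinates(self, rng):
        bg = "".join(rng.choice(list("ACGT"), size=3000))
        insert = "AAA" + CD_ARCH.replace("U", "T") + "AAA"
        genome = [SeqRecord(id="chr1", seq=bg[:1500] + insert + bg[1500:])]
        cands = search_genome(_query(), "sp1", genome)
        kept = [c for c in cands if c.retained]
        assert len(kept) == 1
        c = kept[0]
        assert (c.interval.start, c.interval.end) == (1503, 1503 + len(CD_ARCH))
        assert to_rna(c.seq) == to_rna(CD_ARCH)

    def test_minus_strand_copy_recovered(self, rng):
        bg = "".join(rng.choice(list("ACGT"), size=3000))
        insert = "TTT" + revcomp_rna(CD_ARCH).replace("U", "T") + "TTT"
        genome = [SeqRecord(id="chr1", seq=bg[:1500] + insert + bg[1500:])]
        kept = [c for c in search_genome(_query(), "sp1", genome) if c.retained]
        assert len(kept) == 1
        assert kept[0].interval.strand == "-"
        assert to_rna(kept[0].seq) == to_rna(CD_ARCH)


class TestIterateSearch:
    def test_one_family_two_genomes(self, rng):
        genomes = {}
        for sp in ("sp1", "sp2"):
            bg = "".join(rng.choice(list("ACGT"), size=2500))
            genomes[sp] = [
                SeqRecord(id="chr1", seq=bg[:1000] + "AAA" + CD_ARCH.replace("U", "T") + "AAA" + bg[1000:])
            ]
        res = iterate_search([_query()], genomes)
        assert res.counts["fam1"] == {"sp1": 1, "sp2": 1}
        assert "fam1" in res.alignments

    def test_no_copy_genome_counts_zero(self, rng):
        genomes = {"sp1": [SeqRecord(id="chr1", seq="".join(rng.choice(list("ACGT"), size=2000)))]}
        res = iterate_search([_query()], genomes)
        assert res.counts["fam1"]["sp1"] == 0

    def test_divergence_chain_needs_second_round(self):
        """A copy reachable only through an intermediate species is found in
        round 2 but not in round 1 (snoStrip-style propagation)."""
        # mutation slots <= 8 nt apart and outside box-critical positions,
        # split alternately between the intermediate and the far copy: the
        # far copy then shares no 9-mer with the original query.
        slots = [1, 9, 16, 22, 30, 37, 46, 50, 56, 63]
        swap = {"A": "C", "C": "A", "G": "U", "U": "G"}
        inter = list(CD_ARCH)
        far = list(CD_ARCH)
        for k, pos in enumerate(slots):
            far[pos] = swap[far[pos]]
            if k % 2 == 0:
                inter[pos] = swap[inter[pos]]
        inter, far = "".join(inter), "".join(far)
        # sanity of the construction itself
        assert annotate_cd_boxes(inter) is not None
        assert annotate_cd_boxes(far) is not None
        q9 = {to_rna(CD_ARCH)[i:i + 9] for i in range(len(CD_ARCH) - 8)}
        assert not any(to_rna(far)[i:i + 9] in q9 for i in range(len(far) - 8))

        pad = "GGAAGGAAGG" * 60
        genomes = {
            "spA": [SeqRecord(id="c", seq=(pad + "AAA" + inter.replace("U", "T") + "AAA" + pad))],
            "spB": [SeqRecord(id="c", seq=(pad + "AAA" + far.replace("U", "T") + "AAA" + pad))],
        }
        one = iterate_search([_query()], genomes, SearchParams(rounds=1))
        two = iterate_search([_query()], genomes, SearchParams(rounds=2))
        assert one.counts["fam1"]["spB"] == 0
        assert one.counts["fam1"]["spA"] == 1
        assert two.counts["fam1"]["spB"] == 1

    def test_deterministic(self, rng):
        bg = "".join(rng.choice(list("ACGT"), size=2500))
        genomes = {"sp1": [SeqRecord(id="chr1", seq=bg[:800] + "AAA" + CD_ARCH.replace("U", "T") + "AAA" + bg[800:])]}
        r1 = iterate_search([_query()], genomes)
        r2 = iterate_search([_query()], genomes)
        assert [(g.gene_id, g.interval) for g in r1.genes["sp1"]] == [
            (g.gene_id, g.interval) for g in r2.genes["sp1"]
        ]


class TestSensitivityDegradation:
    def test_sensitivity_monotone_in_divergence(self):
        """Planted-copy recovery is monotone non-increasing in the
        substitution rate (checked at 0/5/10/20% with a fixed seed)."""
        import numpy as np

        from snofamkit.synthetic_data import (
            _background,
            make_cd_archetype,
            mutate_sequence,
        )

        arch = make_cd_archetype("fam1", np.random.default_rng(3))
        q = build_family_query("fam1", "CD", [SeqRecord(id="m1", seq=arch.seq)])
        sens = []
        for mu in (0.0, 0.05, 0.10, 0.20):
            rng_mu = np.random.default_rng(1000 + int(mu * 100))
            chunks, truth, pos = [], [], 0
            for _ in range(12):
                chunks.append(_background(rng_mu, 1500, 0.5))
                pos += 1500
                copy = mutate_sequence(arch.seq, arch.protected, mu, 0.05, rng_mu)
                chunks.append("AAA" + copy.replace("U", "T") + "AAA")
                truth.append((pos + 3, pos + 3 + len(copy)))
                pos += len(copy) + 6
            chunks.append(_background(rng_mu, 1500, 0.5))
            genome = [SeqRecord(id="chr1", seq="".join(chunks))]
            kept = [c for c in search_genome(q, "sp", genome) if c.retained]
            found = sum(
                any(k.interval.start < e and s < k.interval.end for k in kept)
                for s, e in truth
            )
            sens.append(found / 12)
        assert all(a >= b for a, b in zip(sens, sens[1:])), sens
        assert sens[0] == 1.0


class TestAlignFamily:
    def _members(self, seqs):
        out = []
        for i, s in enumerate(seqs):
            bs = annotate_cd_boxes(s)
            assert bs is not None
            out.append((f"m{i}", s, bs))
        return out

    def test_two_identical_members_gapless(self):
        aln = align_family("f", "CD", self._members([CD_ARCH, CD_ARCH]))
        assert set(aln.rows.values()) == {to_rna(CD_ARCH)}
        assert "-" not in next(iter(aln.rows.values()))
        letters = set(aln.boxes_line)
        assert letters <= {"C", "D", "d", "c", "."}

    def test_length_difference_gets_gap_columns(self):
        longer = CD_ARCH.replace("AAAAAAAAAA", "AAAAAAAAAAAA")  # mid 10 -> 12
        aln = align_family("f", "CD", self._members([CD_ARCH, longer]))
        rows = list(aln.rows.values())
        assert len(rows[0]) == len(rows[1])
        assert sum(ch == "-" for ch in rows[0]) == 2
        # box columns identical across rows
        for col, letter in enumerate(aln.boxes_line):
            if letter != ".":
                assert rows[0][col] == rows[1][col] != "-"

    def test_missing_mandatory_box_raises(self):
        members = self._members([CD_ARCH])
        members.append(("bad", CD_ARCH, None))
        with pytest.raises(ValueError, match="bad"):
            align_family("f", "CD", members)

    def test_sum_of_pairs_optimal_for_three_members(self):
        """The 3-way inter-anchor alignment beats every exhaustively
        enumerated alignment under the same anchor constraint."""
        variants = [
            CD_ARCH,
            CD_ARCH.replace("AAAAAAAAAA", "AAAAAAAA"),
            CD_ARCH.replace("AAAAAAAAAA", "AAAACAAAAA"),
        ]
        members = self._members(variants)
        aln = align_family("f", "CD", members)
        cols = list(zip(*aln.rows.values()))
        got = sum_of_pairs(cols)

        # exhaustive check on the variable segment (the D'-C' spacer):
        mids = ["AAAAAAAAAA", "AAAAAAAA", "AAAACAAAAA"]
        best = _best_sp_exhaustive(mids)
        # compare the same segment inside the full alignment
        start = aln.boxes_line.index("d") + 4
        end = aln.boxes_line.index("c")
        seg_cols = cols[start:end]
        assert sum_of_pairs(seg_cols) >= best


def _best_sp_exhaustive(seqs):
    """Brute-force optimum SP score for <=3 short sequences by enumerating
    all gapped alignments via iterative deepening over alignment length."""
    assert len(seqs) == 3
    a, b, c = seqs
    best = None
    # enumerate monotone paths through the 3D lattice (DP is exact; here we
    # just re-run an independent exhaustive recursion with memoisation)
    import functools

    @functools.lru_cache(None)
    def rec(i, j, k):
        if (i, j, k) == (len(a), len(b), len(c)):
            return 0
        out = []
        for di, dj, dk in itertools.product((0, 1), repeat=3):
            if not (di or dj or dk):
                continue
            if i + di > len(a) or j + dj > len(b) or k + dk > len(c):
                continue
            x = a[i] if di else "-"
            y = b[j] if dj else "-"
            z = c[k] if dk else "-"
            col = sum_of_pairs([(x, y, z)])
            out.append(col + rec(i + di, j + dj, k + dk))
        return max(out)

    return rec(0, 0, 0)


class TestFamilyQuery:
    def test_consensus_of_identical_members(self):
        q = build_family_query(
            "f", "CD", [SeqRecord(id="a", seq=CD_ARCH), SeqRecord(id="b", seq=CD_ARCH)]
        )
        assert q.consensus == to_rna(CD_ARCH)
        assert q.consensus_boxes is not None

    def test_member_without_boxes_rejected(self):
        with pytest.raises(ValueError, match="nope"):
            build_family_query("f", "CD", [SeqRecord(id="nope", seq="A" * 80)])
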