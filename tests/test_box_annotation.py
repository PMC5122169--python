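"""Motif matching, box assembly, folding and classification."""

import random
from functools import lru_cache

import numpy as np
import pytest

from snofamkit.box_annotation import (
    BoxParams,
    BoxPattern,
    DEFAULT_PATTERNS,
    annotate_cd_boxes,
    annotate_haca_boxes,
    can_pair,
    check_hairpin_topology,
    check_terminal_stem,
    classify_snoRNA,
    match_iupac,
    nussinov,
    nussinov_helices,
)
from snofamkit.core_io import IUPAC_RNA


def brute_iupac(pattern: BoxPattern, seq: str):
    """Independent per-position window scan."""
    out = []
    m = len(pattern.iupac)
    for i in range(len(seq) - m + 1):
        mm = sum(
            1
            for k in range(m)
            if IUPAC_RNA[pattern.iupac[k]].isdisjoint(IUPAC_RNA[seq[i + k]])
        )
        if mm <= pattern.max_mismatch:
            out.append((i, mm))
    return sorted(out, key=lambda x: (x[1], x[0]))


class TestMatchIupac:
    def test_degenerate_r_matches_g(self):
        hits = match_iupac(BoxPattern("C", "RUGAUGA", 0), "GUGAUGA")
        assert len(hits) == 1 and hits[0].start == 0 and hits[0].mismatches == 0

    def test_exact_d_box(self):
        hits = match_iupac(BoxPattern("D", "CUGA", 0), "CUGA")
        assert [(h.start, h.mismatches) for h in hits] == [(0, 0)]

    def test_equals_bruteforce_oracle(self, rng):
        patterns = list(DEFAULT_PATTERNS.values())
        for _ in range(150):
            seq = "".join(rng.choice(list("ACGU"), size=200))
            for p in patterns:
                got = [(h.start, h.mismatches) for h in match_iupac(p, seq)]
                assert got == brute_iupac(p, seq)

    def test_bad_pattern_rejected(self):
        with pytest.raises(ValueError):
            BoxPattern("X", "ACZ", 0)


def _cd_sequence():
    """The canonical planted box C/D layout used throughout these tests."""
    leader, tail = "GGCAC", "GUGCC"
    ase1 = "GAUCGAUCGAUC"
    ase2 = "CCAUGGCAUCGA"
    mid = "AAAAAAAAAA"
    seq = leader + "AUGAUGA" + ase1 + "CUGA" + mid + "GUGAUGA" + ase2 + "CUGA" + tail
    return seq


class TestAnnotateCD:
    def test_planted_boxes_recovered(self):
        seq = _cd_sequence()
        bs = annotate_cd_boxes(seq)
        assert bs is not None
        got = {(h.name, h.start, h.end) for h in bs.hits}
        assert ("C", 5, 12) in got and ("D", len(seq) - 9, len(seq) - 5) in got
        assert ("Dprime", 24, 28) in got and ("Cprime", 38, 45) in got
        assert bs.spacer_cd_dprime == 12 and bs.spacer_cprime_d == 12

    def test_poly_a_has_no_boxes(self):
        assert annotate_cd_boxes("A" * 90) is None

    def test_too_short_returns_none(self):
        assert annotate_cd_boxes("AUGAUGACUGA") is None

    def test_boxes_within_positional_windows(self, rng):
        params = BoxParams()
        for _ in range(60):
            seq = "".join(rng.choice(list("ACGU"), size=120))
            bs = annotate_cd_boxes(seq, params)
            if bs is None:
                continue
            assert bs.get("C").start <= params.c_start_max
            assert bs.get("D").end >= len(seq) - params.d_end_window

    def test_planted_minimal_pair_recovered_vs_exhaustive(self, rng):
        """With only C and D planted (no internal boxes), the unique
        zero-mismatch combination must be found."""
        for _ in range(40):
            filler = "".join(rng.choice(list("AC"), size=60))  # no G/U: no spurious boxes
            seq = "UAA" + "AUGAUGA" + filler + "CUGA" + "CAA"
            bs = annotate_cd_boxes(seq)
            assert bs is not None
            assert (bs.get("C").start, bs.get("D").start) == (3, 70)
            assert bs.total_mismatches == 0


class TestAnnotateHACA:
    def test_planted_h_and_aca(self):
        body = "GC" * 20
        L = 100
        h_start = 47
        seq = ("G" * h_start + "AUAGGA" + "C" * (L - h_start - 9) + "ACA")
        bs = annotate_haca_boxes(seq)
        assert bs is not None
        assert bs.get("H").start == h_start
        assert (bs.get("ACA").start, bs.get("ACA").end) == (L - 3, L)

    def test_no_terminal_aca_returns_none(self):
        seq = "G" * 47 + "AUAGGA" + "C" * 44 + "ACC"
        assert annotate_haca_boxes(seq) is None

    def test_h_must_lie_in_hinge_window(self):
        # H box present only near the 5' end: outside [0.35 L, 0.65 L]
        seq = "AUAGGA" + "G" * 91 + "ACA"
        assert annotate_haca_boxes(seq) is None

    def test_best_h_is_fewest_mismatch_then_central(self):
        L = 100
        seq = list("G" * L)
        seq[40:46] = "ACAGGA"   # exact ANANNA
        seq[52:58] = "AGACCA"   # also exact, further from centre? both valid
        seq[-3:] = "ACA"
        bs = annotate_haca_boxes("".join(seq))
        # centres: 43 vs 55; L/2 = 50 -> the 52-start hit is more central
        assert bs.get("H").start == 52


class TestTerminalStem:
    def test_designed_complementary_flanks_pass(self):
        seq = _cd_sequence()
        bs = annotate_cd_boxes(seq)
        check = check_terminal_stem(seq, bs)
        assert check.passed and check.stem_length >= 4

    def test_non_complementary_flanks_fail(self):
        seq = "AAAAA" + _cd_sequence()[5:-5] + "AAAAA"
        bs = annotate_cd_boxes(seq)
        check = check_terminal_stem(seq, bs)
        assert not check.passed

    def test_stem_equals_bruteforce_run(self, rng):
        params = BoxParams()
        core = _cd_sequence()[5:-5]
        for _ in range(100):
            f5 = "".join(rng.choice(list("ACGU"), size=5))
            f3 = "".join(rng.choice(list("ACGU"), size=5))
            seq = f5 + core + f3
            bs = annotate_cd_boxes(seq)
            if bs is None:
                continue
            check = check_terminal_stem(seq, bs)
            c, d = bs.get("C"), bs.get("D")
            w5 = seq[max(0, c.start - params.flank): c.start]
            w3 = seq[d.end: d.end + params.flank]
            best = 0
            for i in range(len(w5)):
                for j in range(len(w3)):
                    run, a, b = 0, i, j
                    while a < len(w5) and b >= 0 and can_pair(w5[a], w3[b]):
                        run += 1
                        a += 1
                        b -= 1
                    best = max(best, run)
            assert check.stem_length == best


def brute_max_pairs(seq: str, min_loop: int = 3) -> int:
    """Exhaustive enumeration of nested structures (recursive optimum)."""

    @lru_cache(None)
    def f(i, j):
        if j - i <= min_loop:
            return 0
        best = f(i + 1, j)
        for h in range(i + min_loop + 1, j + 1):
            if can_pair(seq[i], seq[h]):
                best = max(best, 1 + f(i + 1, h - 1) + (f(h + 1, j) if h + 1 <= j else 0))
        return best

    return f(0, len(seq) - 1) if len(seq) > 1 else 0


class TestNussinov:
    def test_two_letter_alphabet_exhaustive(self):
        """Every G/C string up to length 12: DP equals enumeration."""
        from itertools import product

        for L in range(1, 13):
            for tup in product("GC", repeat=L):
                seq = "".join(tup)
                n, pairs = nussinov(seq)
                assert n == brute_max_pairs(seq)
                assert len(pairs) == n

    def test_random_four_letter(self, rng):
        for _ in range(150):
            seq = "".join(rng.choice(list("ACGU"), size=int(rng.integers(2, 21))))
            n, pairs = nussinov(seq)
            assert n == brute_max_pairs(seq)
            for i, j in pairs:
                assert can_pair(seq[i], seq[j]) and j - i > 3

    def test_constraint_respected(self):
        seq = "GGGGAAAACCCC"
        _, pairs = nussinov(seq, unpaired={0, 1})
        assert all(0 not in p and 1 not in p for p in pairs)

    def test_pairs_nested(self, rng):
        seq = "".join(rng.choice(list("ACGU"), size=40))
        _, pairs = nussinov(seq)
        for a in pairs:
            for b in pairs:
                if a < b:
                    assert b[1] < a[1] or b[0] > a[1], f"crossing {a} {b}"

    def test_helix_variant_never_exceeds_max_pairs(self, rng):
        for _ in range(80):
            seq = "".join(rng.choice(list("ACGU"), size=25))
            full, _ = nussinov(seq)
            hx, pairs = nussinov_helices(seq, min_helix=3)
            assert hx <= full
            assert len(pairs) == hx


def _haca_sequence():
    hp = lambda pocketL: "GGGGG" + pocketL + "GGGGG" + "AAAA" + "CCCCC" + "A" * 7 + "CCCCC"
    return hp("ACCACAA") + "AA" + "AUAGGA" + "AA" + hp("CACACAA") + "A" + "ACA"


class TestHairpinTopology:
    def test_designed_two_hairpin_pass(self):
        seq = _haca_sequence()
        bs = annotate_haca_boxes(seq)
        assert bs is not None
        check = check_hairpin_topology(seq, bs)
        assert check.passed
        assert dict(check.details)["hairpin_5p"] and dict(check.details)["hairpin_3p"]

    def test_unstructured_fails(self):
        seq = "A" * 40 + "AUAGGA" + "A" * 40 + "ACA"
        bs = annotate_haca_boxes(seq)
        assert bs is not None
        assert not check_hairpin_topology(seq, bs).passed

    def test_box_nucleotides_unpaired(self):
        seq = _haca_sequence()
        bs = annotate_haca_boxes(seq)
        check = check_hairpin_topology(seq, bs)
        h, aca = bs.get("H"), bs.get("ACA")
        forbidden = set(range(h.start, h.end)) | set(range(aca.start, aca.end))
        for i, j in check.pairs:
            assert i not in forbidden and j not in forbidden


class TestClassify:
    def test_planted_cd_gene(self):
        res = classify_snoRNA(_cd_sequence())
        assert res is not None
        cls, bs, checks = res
        assert cls == "CD" and checks[0].passed

    def test_planted_haca_gene(self):
        res = classify_snoRNA(_haca_sequence())
        assert res is not None
        cls, bs, checks = res
        assert cls == "HACA" and checks[0].passed

    def test_false_positive_rate_on_random(self):
        """Monte-Carlo: random 150-mers classified with a passing structure
        check in < 5% of cases."""
        rng = np.random.default_rng(1234)
        fp = 0
        n = 500
        for _ in range(n):
            seq = "".join(rng.choice(list("ACGU"), size=150))
            res = classify_snoRNA(seq)
            if res is not None and res[2][0].passed:
                fp += 1
        assert fp / n < 0.05

    def test_zero_divergence_planted_classes(self, dataset_zero_noise):
        ds = dataset_zero_noise
        for fam in ds.families.values():
            res = classify_snoRNA(fam.archetype.seq)
            assert res is not None and res[0] == fam.archetype.sno_class
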