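"""Folding oracle equivalence and loop-decomposition properties.

The independent oracle enumerates every pseudoknot-free structure of a
sequence recursively and reports the maximal pair count (and, among
maximizers, the minimal pair energy); the production folder must match it.
"""

from functools import lru_cache

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from prnascreen import (
    SecondaryStructure,
    eligible_loop_pairs,
    fold_max_pairing,
    parse_junctions,
    score_structure,
)
from prnascreen.structure_fold import pair_strength

MIN_HAIRPIN = 3


def enumerate_structures(seq, min_hairpin=MIN_HAIRPIN, allow_gu=True):
    """Yield every valid pair set (as a frozen set of (i, j) tuples)."""

    def rec(positions):
        if not positions:
            yield frozenset()
            return
        first, rest = positions[0], positions[1:]
        # first unpaired
        for s in rec(rest):
            yield s
        # first paired with an admissible partner
        for idx, k in enumerate(rest):
            if k - first <= min_hairpin:
                continue
            if pair_strength(seq[first], seq[k], allow_gu) == 0:
                continue
            inside = tuple(p for p in rest[:idx] if first < p < k)
            outside = tuple(p for p in rest[idx + 1 :])
            for s_in in rec(inside):
                for s_out in rec(outside):
                    yield s_in | s_out | {(first, k)}

    yield from rec(tuple(range(len(seq))))


def oracle_best(seq, min_hairpin=MIN_HAIRPIN, allow_gu=True):
    """(max pair count, min energy among maximizers) by full enumeration."""
    best_n, best_e = 0, 0
    for s in enumerate_structures(seq, min_hairpin, allow_gu):
        n = len(s)
        e = -sum(pair_strength(seq[i], seq[j], allow_gu) for i, j in s)
        if (n, -e) > (best_n, -best_e):
            best_n, best_e = n, e
    return best_n, best_e


def oracle_count_memo(seq, min_hairpin=MIN_HAIRPIN):
    """Top-down memoized maximal pair count (independent of the kernel)."""

    @lru_cache(maxsize=None)
    def f(i, j):
        if j - i <= min_hairpin:
            return 0
        best = f(i + 1, j)
        for k in range(i + min_hairpin + 1, j + 1):
            if pair_strength(seq[i], seq[k]) > 0:
                best = max(best, 1 + f(i + 1, k - 1) + f(k + 1, j))
        return best

    return f(0, len(seq) - 1)


def random_rna(rng, n):
    return "".join(rng.choice(list("ACGU"), size=n))


class TestFoldOracle:
    def test_no_complementary_bases(self):
        s = fold_max_pairing("AAAAAA")
        assert s.dotbracket == "......"

    def test_simple_hairpin(self):
        s = fold_max_pairing("GGGAAACCC")
        assert s.dotbracket == "(((...)))"
        assert s.n_pairs == 3

    def test_short_sequence_empty_structure(self):
        s = fold_max_pairing("GAUC")
        assert s.n_pairs == 0

    @pytest.mark.parametrize("length", range(6, 13))
    def test_matches_exhaustive_enumeration(self, rng, length):
        for _ in range(25):
            seq = random_rna(rng, length)
            want_n, want_e = oracle_best(seq)
            got = fold_max_pairing(seq)
            sc = score_structure(got)
            assert sc.n_pairs == want_n
            assert sc.pair_energy_total == want_e

    def test_matches_memo_oracle_longer(self, rng):
        for _ in range(100):
            seq = random_rna(rng, int(rng.integers(13, 26)))
            assert fold_max_pairing(seq).n_pairs == oracle_count_memo(seq)

    @pytest.mark.parametrize("length", range(8, 13))
    def test_no_lonely_pairs_matches_filtered_enumeration(self, rng, length):
        def no_lonely(pair_set):
            pairs = dict(pair_set)
            pairs.update({j: i for i, j in pair_set})
            return all(
                (pairs.get(i + 1) == j - 1) or (pairs.get(i - 1) == j + 1)
                for i, j in pair_set
            )

        for _ in range(15):
            seq = random_rna(rng, length)
            best_n, best_e = 0, 0
            for s in enumerate_structures(seq):
                if not no_lonely(s):
                    continue
                n = len(s)
                e = -sum(pair_strength(seq[i], seq[j], True) for i, j in s)
                if (n, -e) > (best_n, -best_e):
                    best_n, best_e = n, e
            got = score_structure(fold_max_pairing(seq, min_helix=2))
            assert got.n_pairs == best_n
            assert got.pair_energy_total == best_e
        # no isolated pairs in the produced structures
        for _ in range(30):
            seq = random_rna(rng, 40)
            st = fold_max_pairing(seq, min_helix=2)
            by_pos = {i: j for i, j in enumerate(st.pairs) if j != -1}
            for i, j in by_pos.items():
                if j > i:
                    assert by_pos.get(i + 1) == j - 1 or by_pos.get(i - 1) == j + 1

    def test_gu_toggle(self):
        # G:U is the only possible pair here
        seq = "GGGGGGUUU"
        assert fold_max_pairing(seq, allow_gu=True).n_pairs == 3
        assert fold_max_pairing(seq, allow_gu=False).n_pairs == 0

    def test_deterministic(self, rng):
        seq = random_rna(rng, 40)
        assert fold_max_pairing(seq).pairs == fold_max_pairing(seq).pairs

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(seq=st.text(alphabet="ACGU", min_size=1, max_size=20))
    def test_fold_always_returns_valid_optimal_structure(self, seq):
        st_ = fold_max_pairing(seq)  # constructor enforces validity
        assert len(st_.dotbracket) == len(seq)
        if len(seq) > MIN_HAIRPIN + 1:
            assert st_.n_pairs == oracle_count_memo(seq)


class TestScoreStructure:
    @pytest.mark.parametrize(
        "seq,db,expected",
        [
            ("GGGAAACCC", "(((...)))", -9),
            ("GGGAAACCC", ".........", 0),
            ("GAUAAAUC", "((....))", -5),
        ],
    )
    def test_known_scores(self, seq, db, expected):
        s = SecondaryStructure.from_dotbracket(seq, db)
        assert score_structure(s).pair_energy_total == expected


class TestJunctions:
    def test_single_hairpin(self):
        s = SecondaryStructure.from_dotbracket("GGGAAACCC", "(((...)))")
        r = parse_junctions(s)
        assert len(r.hairpins) == 1
        assert len(r.multiloops) == 0
        assert not r.has_3wj

    def test_cloverleaf_degree_four(self):
        # three stems off one loop, closed by a fourth helix: degree 4
        db = "((..((...))..((...))..((...))..))"
        seq = "GG" + "AA" + "GGAAACC" + "AA" + "GGAAACC" + "AA" + "GGAAACC" + "AA" + "CC"
        s = SecondaryStructure.from_dotbracket(seq, db)
        r = parse_junctions(s)
        assert len(r.multiloops) == 1
        assert r.multiloops[0].degree == 4
        assert not r.has_3wj

    def test_y_shape_is_3wj(self):
        db = "(((..((...))..((...))..)))"
        seq = "GGG" + "AA" + "GGAAACC" + "AA" + "GGAAACC" + "AA" + "CCC"
        s = SecondaryStructure.from_dotbracket(seq, db)
        r = parse_junctions(s)
        assert len(r.multiloops) == 1
        assert r.multiloops[0].degree == 3
        assert r.has_3wj

    def test_loop_decomposition_is_partition(self, rng):
        for _ in range(200):
            seq = random_rna(rng, int(rng.integers(10, 61)))
            s = fold_max_pairing(seq)
            r = parse_junctions(s)
            regions = [set(r.exterior_unpaired)]
            regions += [set(range(h.start, h.end)) for h in r.hairpins]
            regions += [
                set(range(*b.span5)) | set(range(*b.span3)) for b in r.bulges_internal
            ]
            regions += [set(m.unpaired) for m in r.multiloops]
            unpaired = {i for i, j in enumerate(s.pairs) if j == -1}
            counted = [i for reg in regions for i in reg]
            assert len(counted) == len(set(counted)), "regions overlap"
            assert set(counted) == unpaired, "regions do not cover all unpaired"

    def test_scaffold_recovery(self, prna_instance):
        # the screen folds with min_helix=2 (no lonely pairs)
        s = fold_max_pairing(prna_instance.record.residues, min_helix=2)
        r = parse_junctions(s)
        assert r.has_3wj
        spans = {(h.start, h.end) for h in r.hairpins}
        ann = prna_instance.annotation
        assert ann.rh_loop in spans and ann.lh_loop in spans


class TestEligibleLoopPairs:
    def _structure(self, n_hairpins):
        unit = "GGAAAACCA"
        db = "((....))." * n_hairpins
        return SecondaryStructure.from_dotbracket(unit * n_hairpins, db)

    @pytest.mark.parametrize("n,expected", [(1, 0), (2, 2), (3, 6)])
    def test_ordered_pair_counts(self, n, expected):
        s = self._structure(n)
        r = parse_junctions(s)
        pairs = eligible_loop_pairs(s, r, min_loop=3, max_loop=10)
        assert len(pairs) == expected

    def test_length_bounds_filter(self):
        s = self._structure(2)
        r = parse_junctions(s)
        assert eligible_loop_pairs(s, r, min_loop=5, max_loop=10) == []
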