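"""Distance models, NJ additive recovery, and patristic reports."""

import math

import numpy as np
import pytest

from prnascreen import (
    DistanceMatrix,
    SeqRecord,
    distance_matrix,
    load_newick,
    nj_tree,
    patristic_report,
)
from prnascreen.io_formats import ParseError
from prnascreen.phylo_distance import patristic_distances


def _rows(*seqs):
    return [SeqRecord(id=f"t{i}", residues=s) for i, s in enumerate(seqs)]


class RandomTree:
    """Random binary tree with positive branch lengths; its own path sums
    serve as the independent oracle for NJ recovery."""

    def __init__(self, n_leaves, rng):
        nodes = [(f"L{i}",) for i in range(n_leaves)]
        self.edges = {}
        nid = 0
        while len(nodes) > 1:
            i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
            a, b = nodes[j], nodes[i]
            parent = (f"N{nid}", a, b)
            nid += 1
            self.edges[a[0]] = (parent[0], float(rng.uniform(0.05, 2.0)))
            self.edges[b[0]] = (parent[0], float(rng.uniform(0.05, 2.0)))
            nodes = [n for k, n in enumerate(nodes) if k not in (i, j)]
            nodes.append(parent)
        self.root = nodes[0][0]
        self.leaves = [f"L{i}" for i in range(n_leaves)]

    def _path_to_root(self, leaf):
        out = {}
        node, dist = leaf, 0.0
        while node != self.root:
            parent, ln = self.edges[node]
            dist += ln
            out[parent] = dist
            node = parent
        return out

    def distance_matrix(self):
        n = len(self.leaves)
        d = np.zeros((n, n))
        paths = {lf: self._path_to_root(lf) for lf in self.leaves}
        for i in range(n):
            for j in range(i + 1, n):
                pi, pj = paths[self.leaves[i]], paths[self.leaves[j]]
                mrca_dist = min(
                    pi[a] + pj[a] for a in pi.keys() & pj.keys()
                )
                d[i, j] = d[j, i] = mrca_dist
        return DistanceMatrix(labels=tuple(self.leaves), d=d)


class TestDistanceMatrix:
    def test_identical_rows_zero(self):
        m = distance_matrix(_rows("ACGUACGU", "ACGUACGU"))
        assert m.d[0, 1] == 0.0

    def test_p_distance_definition(self):
        a = "A" * 100
        b = "G" * 3 + "A" * 97
        m = distance_matrix(_rows(a, b), model="p")
        assert m.d[0, 1] == pytest.approx(0.03)

    def test_jc69_closed_form(self):
        a = "A" * 100
        b = "G" * 3 + "A" * 97
        m = distance_matrix(_rows(a, b), model="jc69")
        assert m.d[0, 1] == pytest.approx(-0.75 * math.log(0.96))
        assert m.d[0, 1] == pytest.approx(0.0306165, abs=1e-7)

    def test_jc69_saturation_infinite_or_strict_error(self):
        a = "ACGU" * 5
        b = "GAUC" * 5  # all 20 sites differ
        m = distance_matrix(_rows(a, b), model="jc69")
        assert math.isinf(m.d[0, 1])
        with pytest.raises(ValueError, match="undefined"):
            distance_matrix(_rows(a, b), model="jc69", strict=True)

    def test_pairwise_deletion(self):
        a = "ACGUACGUAC"
        b = "AC--ACGAAC"  # 8 compared columns, 1 mismatch
        m = distance_matrix(_rows(a, b), model="p")
        assert m.d[0, 1] == pytest.approx(1 / 8)

    def test_jc69_at_least_p(self, rng):
        for _ in range(20):
            s1 = "".join(rng.choice(list("ACGU"), size=60))
            s2 = "".join(rng.choice(list("ACGU"), size=60))
            p = distance_matrix(_rows(s1, s2), model="p")
            j = distance_matrix(_rows(s1, s2), model="jc69")
            if np.isfinite(j.d[0, 1]):
                assert j.d[0, 1] >= p.d[0, 1]


class TestNJTree:
    def test_requires_three_taxa(self):
        m = DistanceMatrix(labels=("a", "b"), d=np.array([[0.0, 1.0], [1.0, 0.0]]))
        with pytest.raises(ValueError):
            nj_tree(m)

    def test_four_taxon_additive_recovery(self):
        # leaf edges a=2, b=3, c=4, d=5; internal edge 1
        d = np.array(
            [
                [0, 5, 7, 8],
                [5, 0, 8, 9],
                [7, 8, 0, 9],
                [8, 9, 9, 0],
            ],
            dtype=float,
        )
        m = DistanceMatrix(labels=("a", "b", "c", "d"), d=d)
        t = nj_tree(m)
        got = patristic_distances(t)
        for i, la in enumerate(m.labels):
            for j, lb in enumerate(m.labels):
                assert got.value(la, lb) == pytest.approx(d[i, j], abs=1e-9)

    def test_three_taxon_closed_form(self):
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        m = DistanceMatrix(labels=("a", "b", "c"), d=d)
        got = patristic_distances(nj_tree(m))
        assert got.value("a", "b") == pytest.approx(3.0)
        assert got.value("a", "c") == pytest.approx(4.0)
        assert got.value("b", "c") == pytest.approx(5.0)

    def test_random_additive_recovery(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 9))
            tree = RandomTree(n, rng)
            m = tree.distance_matrix()
            got = patristic_distances(nj_tree(m))
            for i, la in enumerate(m.labels):
                for j, lb in enumerate(m.labels):
                    assert got.value(la, lb) == pytest.approx(m.d[i, j], abs=1e-9)

    def test_patristic_metric_axioms(self, rng):
        tree = RandomTree(7, rng)
        got = patristic_distances(nj_tree(tree.distance_matrix()))
        d = got.d
        assert np.allclose(d, d.T)
        assert np.all(np.diagonal(d) == 0)
        n = len(got.labels)
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert d[i, j] <= d[i, k] + d[k, j] + 1e-9


class TestNewickAndReport:
    def test_two_leaf_path_sum(self, tmp_path):
        p = tmp_path / "t.nwk"
        p.write_text("(A:1,B:2);\n")
        t = load_newick(p)
        df = patristic_report(t, "A")
        assert df.set_index("leaf").loc["B", "substitutions_per_site"] == pytest.approx(3.0)
        assert df.set_index("leaf").loc["A", "substitutions_per_site"] == 0.0

    def test_three_leaf_path(self, tmp_path):
        p = tmp_path / "t.nwk"
        p.write_text("((A:1,B:1):1,C:2);\n")
        df = patristic_report(load_newick(p), "A")
        assert df.set_index("leaf").loc["C", "substitutions_per_site"] == pytest.approx(4.0)

    def test_missing_branch_lengths_default_zero(self, tmp_path, caplog):
        p = tmp_path / "t.nwk"
        p.write_text("((A:1,B),C:2);\n")
        with caplog.at_level("WARNING"):
            t = load_newick(p)
        df = patristic_report(t, "A")
        assert df.set_index("leaf").loc["B", "substitutions_per_site"] == pytest.approx(1.0)

    def test_malformed_newick_rejected(self, tmp_path):
        p = tmp_path / "t.nwk"
        p.write_text("(A:1,B:2\n")
        with pytest.raises(ParseError):
            load_newick(p)

    def test_unknown_reference_leaf(self, tmp_path):
        p = tmp_path / "t.nwk"
        p.write_text("(A:1,B:2);\n")
        with pytest.raises(KeyError):
            patristic_report(load_newick(p), "Z")
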