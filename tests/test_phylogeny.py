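"""Poisson distances, neighbor-joining, bootstrap, subfamily assignment."""

import math

import numpy as np
import pytest

from aaapsurvey import (
    DistanceMatrix,
    assign_subfamily,
    bootstrap_support,
    nj_tree,
    poisson_distance,
)
from aaapsurvey.phylogeny import SaturationError
from oracles import least_squares_topology, random_additive_matrix, tree_bipartitions


def _dm(labels, matrix):
    m = np.asarray(matrix, dtype=float)
    return DistanceMatrix(labels=labels, d=m, n_sites=np.ones_like(m, dtype=int))


class TestPoissonDistance:
    def test_identical_sequences(self):
        dm = poisson_distance([("a", "AAAA"), ("b", "AAAA")])
        assert dm.d[0, 1] == 0.0

    def test_half_differing_sites(self):
        dm = poisson_distance([("a", "AAAA"), ("b", "AAWW")])
        assert dm.d[0, 1] == pytest.approx(-math.log(0.5), abs=1e-4)

    def test_gappy_column_dropped_and_p_recounted(self):
        # column 1 has a gap in 1/3 sequences -> coverage 2/3 < 0.95 -> dropped
        msa = [
            ("a", "-AAAAAAAAA"),
            ("b", "WAAAAAAAAW"),
            ("c", "WAAAAAAAAA"),
        ]
        dm = poisson_distance(msa, site_coverage=0.95)
        # over the 9 retained columns b vs c differ at exactly 1
        p = 1 / 9
        assert dm.d[1, 2] == pytest.approx(-math.log(1 - p))
        assert dm.n_sites[1, 2] == 9

    def test_correction_inflates(self, rng):
        seqs = ["".join(rng.choice(list("ACDEFGHIKL"), size=100)) for _ in range(4)]
        msa = [(f"s{i}", s) for i, s in enumerate(seqs)]
        dm = poisson_distance(msa)
        arr = np.array([list(s) for s in seqs])
        for i in range(4):
            for j in range(i + 1, 4):
                p = (arr[i] != arr[j]).mean()
                assert dm.d[i, j] >= p - 1e-12

    def test_saturated_pair_flagged(self):
        dm = poisson_distance([("a", "AAAA"), ("b", "WWWW"), ("c", "AAAW")])
        assert ("a", "b") in dm.saturated_pairs
        with pytest.raises(SaturationError):
            nj_tree(dm)


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        tree = nj_tree(_dm(["a", "b", "c"], [[0, 2, 4], [2, 0, 4], [4, 4, 0]]))
        lengths = {c.name: c.length for c in tree.root.children}
        assert lengths == {"a": 1.0, "b": 1.0, "c": 3.0}

    def test_recovers_additive_topology(self, rng):
        labels = list("abcde")
        for _ in range(10):
            edges, d = random_additive_matrix(labels, rng)
            tree = nj_tree(_dm(labels, d))
            assert tree.bipartitions() == tree_bipartitions(edges, labels)

    def test_matches_least_squares_oracle(self, rng):
        labels = list("abcde")
        edges, d = random_additive_matrix(labels, rng)
        tree = nj_tree(_dm(labels, d))
        assert tree.bipartitions() == least_squares_topology(labels, d)

    def test_label_permutation_gives_isomorphic_tree(self, rng):
        labels = list("abcde")
        _, d = random_additive_matrix(labels, rng)
        tree = nj_tree(_dm(labels, d))
        perm = [3, 1, 4, 0, 2]
        tree2 = nj_tree(
            _dm([labels[i] for i in perm], d[np.ix_(perm, perm)])
        )
        assert tree.bipartitions() == tree2.bipartitions()

    def test_branch_lengths_nonnegative(self, rng):
        # a noisy (non-additive) matrix can produce negative NJ estimates;
        # clamp-and-transfer must keep all branch lengths >= 0
        labels = list("abcdef")
        for _ in range(10):
            m = rng.uniform(0.1, 1.0, size=(6, 6))
            d = (m + m.T) / 2
            np.fill_diagonal(d, 0)
            tree = nj_tree(_dm(labels, d))

            def walk(node):
                assert node.length >= 0
                for c in node.children:
                    walk(c)

            for child in tree.root.children:
                walk(child)

    def test_newick_parses_with_dendropy(self, rng):
        import dendropy

        labels = list("abcde")
        _, d = random_additive_matrix(labels, rng)
        newick = nj_tree(_dm(labels, d)).newick()
        tree = dendropy.Tree.get(data=newick, schema="newick")
        assert {t.label for t in tree.taxon_namespace} == set(labels)

    def test_matches_skbio_topology(self, rng):
        skbio = pytest.importorskip("skbio")
        labels = list("abcdef")
        m = rng.uniform(0.2, 1.0, size=(6, 6))
        d = (m + m.T) / 2
        np.fill_diagonal(d, 0)
        ours = nj_tree(_dm(labels, d))
        ref = skbio.tree.nj(skbio.DistanceMatrix(d, ids=labels))
        ref_splits = set()
        all_leaves = frozenset(labels)
        anchor = sorted(labels)[0]
        for node in ref.non_tips():
            side = frozenset(t.name for t in node.tips())
            if 1 < len(side) < len(all_leaves) - 1:
                ref_splits.add(side if anchor not in side else all_leaves - side)
        assert ours.bipartitions() == ref_splits


def _two_cluster_msa(rng, n_cols=120):
    """Two 4-taxon groups separated by many substitutions."""
    base = rng.choice(list("ACDEFGHIKL"), size=n_cols)
    other = base.copy()
    flip = rng.choice(n_cols, size=n_cols // 2, replace=False)
    for i in flip:
        other[i] = "W" if other[i] != "W" else "Y"
    msa = []
    for k in range(2):
        src = base if k == 0 else other
        for t in range(2):
            seq = src.copy()
            jitter = rng.choice(n_cols, size=2, replace=False)
            for i in jitter:
                seq[i] = "M"
            msa.append((f"g{k}t{t}", "".join(seq)))
    return msa


class TestBootstrap:
    def test_strong_signal_gets_high_central_support(self, rng):
        msa = _two_cluster_msa(rng)
        tree = bootstrap_support(msa, n_reps=200, seed=11)
        supports = [n.support for n in tree.internal_nodes() if n.support is not None]
        assert supports and min(supports) >= 95.0

    def test_same_seed_is_deterministic(self, rng):
        msa = _two_cluster_msa(rng)
        t1 = bootstrap_support(msa, n_reps=50, seed=3)
        t2 = bootstrap_support(msa, n_reps=50, seed=3)
        assert t1.newick() == t2.newick()

    def test_supports_are_percentages(self, rng):
        seqs = ["".join(rng.choice(list("ACDEFG"), size=60)) for _ in range(6)]
        msa = [(f"s{i}", s) for i, s in enumerate(seqs)]
        tree = bootstrap_support(msa, n_reps=30, seed=5)
        for node in tree.internal_nodes():
            if node.support is not None:
                assert 0.0 <= node.support <= 100.0

    def test_seed_required(self, rng):
        with pytest.raises(ValueError):
            bootstrap_support(_two_cluster_msa(rng), n_reps=10, seed=None)


class TestSubfamilyAssignment:
    def _tree(self):
        # ((q1, refA1), refA2, (refB1, refB2)) with unit branches
        d = np.array(
            [
                [0, 0.2, 0.4, 1.6, 1.6],
                [0.2, 0, 0.4, 1.6, 1.6],
                [0.4, 0.4, 0, 1.5, 1.5],
                [1.6, 1.6, 1.5, 0, 0.2],
                [1.6, 1.6, 1.5, 0.2, 0],
            ]
        )
        return nj_tree(_dm(["q1", "refA1", "refA2", "refB1", "refB2"], d))

    def test_sister_reference_wins(self):
        tree = self._tree()
        refs = {"refA1": "AAP", "refA2": "AAP", "refB1": "LHT", "refB2": "LHT"}
        assert assign_subfamily(tree, refs)["q1"] == "AAP"

    def test_no_references_is_error(self):
        with pytest.raises(ValueError):
            assign_subfamily(self._tree(), {"ghost": "AAP"})

    def test_monophyletic_simulation_fully_recovered(self, rng):
        # 4 subfamilies x 3 leaves on well-separated additive clusters
        labels, fams = [], {}
        blocks = []
        for f in range(4):
            for t in range(3):
                labels.append(f"f{f}t{t}")
                blocks.append(f)
                if t > 0:
                    fams[f"f{f}t{t}"] = f"SF{f}"
        n = len(labels)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = 0.2 if blocks[i] == blocks[j] else 2.0 + 0.1 * abs(
                    blocks[i] - blocks[j]
                )
        tree = nj_tree(_dm(labels, d))
        assigned = assign_subfamily(tree, fams)
        for f in range(4):
            assert assigned[f"f{f}t0"] == f"SF{f}"
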