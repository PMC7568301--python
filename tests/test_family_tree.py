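"""Neighbor joining: additive exactness, invariances, bootstrap support."""

import itertools

import numpy as np
import pytest

from hydrolase_duo.family import (
    bipartitions,
    bootstrap_support,
    msa_distance_matrix,
    nj_tree,
)
from hydrolase_duo.synth import FamilySpec, gen_family_msa


def tree_distances(tree):
    """Leaf-to-leaf path lengths of a TreeNode tree."""
    paths = {}

    def walk(node, depth, acc):
        acc = acc + [(node, depth)]
        if node.is_leaf:
            paths[node.name] = acc
            return
        for c in node.children:
            walk(c, depth + c.length, acc)

    walk(tree, 0.0, [])
    leaves = sorted(paths)
    out = {}
    for a, b in itertools.combinations(leaves, 2):
        ancestors_a = {id(n): d for n, d in paths[a]}
        shared = max((d for n, d in paths[b] if id(n) in ancestors_a), default=0.0)
        da = paths[a][-1][1]
        db = paths[b][-1][1]
        out[(a, b)] = da + db - 2 * shared
    return out


def additive_matrix_4taxon():
    """Distances generated by the tree ((A:1,B:2):1,(C:3,D:4))."""
    taxa = ["A", "B", "C", "D"]
    d = np.array(
        [
            [0, 3, 5, 6],
            [3, 0, 6, 7],
            [5, 6, 0, 7],
            [6, 7, 7, 0],
        ],
        dtype=float,
    )
    return d, taxa


class TestAdditiveExactness:
    def test_four_taxon_topology_and_path_lengths(self):
        d, taxa = additive_matrix_4taxon()
        tree = nj_tree(d, taxa)
        assert bipartitions(tree) == {frozenset({"C", "D"})}
        dist = tree_distances(tree)
        for (a, b), expected in {
            ("A", "B"): 3, ("A", "C"): 5, ("A", "D"): 6,
            ("B", "C"): 6, ("B", "D"): 7, ("C", "D"): 7,
        }.items():
            assert dist[(a, b)] == pytest.approx(expected)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_random_additive_six_taxon_trees_recovered(self, seed):
        """NJ reproduces topology and path lengths of a random additive tree."""
        rng = np.random.default_rng(seed)
        # caterpillar tree over 6 taxa with random positive branch lengths
        taxa = list("ABCDEF")
        lengths = rng.uniform(0.5, 3.0, size=9)
        # leaf branch lengths l0..l5, internal i0..i2 along a spine
        leaf = lengths[:6]
        spine = lengths[6:]
        pos = {  # distance of each leaf's attachment point along the spine
            "A": 0.0, "B": 0.0, "C": spine[0], "D": spine[0] + spine[1],
            "E": spine[0] + spine[1] + spine[2], "F": spine[0] + spine[1] + spine[2],
        }
        d = np.zeros((6, 6))
        for i, a in enumerate(taxa):
            for j, b in enumerate(taxa):
                if i < j:
                    d[i, j] = d[j, i] = leaf[i] + leaf[j] + abs(pos[a] - pos[b])
        tree = nj_tree(d, taxa)
        dist = tree_distances(tree)
        for i, a in enumerate(taxa):
            for j, b in enumerate(taxa):
                if i < j:
                    key = (a, b) if (a, b) in dist else (b, a)
                    assert dist[key] == pytest.approx(d[i, j], abs=1e-9)

    def test_agreement_with_independent_nj_implementation(self):
        """Same topology as scikit-bio's neighbor joining on a noisy matrix."""
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(5)
        n = 7
        taxa = [f"t{i}" for i in range(n)]
        base, _ = additive_matrix_4taxon()
        d = rng.uniform(0.2, 1.0, size=(n, n))
        d = 0.5 * (d + d.T)
        np.fill_diagonal(d, 0.0)
        ours = bipartitions(nj_tree(d, taxa))
        dm = skbio.DistanceMatrix(d, ids=taxa)
        theirs_tree = skbio.tree.nj(dm)
        theirs = set()
        all_taxa = set(taxa)
        anchor = min(all_taxa)
        for node in theirs_tree.non_tips():
            below = {t.name for t in node.tips()}
            if 1 < len(below) < n - 1:
                theirs.add(frozenset(below if anchor not in below else all_taxa - below))
        assert ours == theirs


class TestInvariances:
    def test_three_taxa_star_from_three_point_formulas(self):
        d = np.array([[0, 4, 6], [4, 0, 8], [6, 8, 0]], dtype=float)
        tree = nj_tree(d, ["A", "B", "C"])
        lengths = {c.name: c.length for c in tree.children}
        assert lengths == pytest.approx({"A": 1.0, "B": 3.0, "C": 5.0})

    def test_taxon_permutation_leaves_splits_unchanged(self):
        rng = np.random.default_rng(9)
        n = 6
        d = rng.uniform(0.2, 1.0, size=(n, n))
        d = 0.5 * (d + d.T)
        np.fill_diagonal(d, 0.0)
        taxa = [f"t{i}" for i in range(n)]
        ref = bipartitions(nj_tree(d, taxa))
        perm = rng.permutation(n)
        d2 = d[np.ix_(perm, perm)]
        taxa2 = [taxa[i] for i in perm]
        assert bipartitions(nj_tree(d2, taxa2)) == ref

    def test_negative_branch_lengths_clamped_sum_preserved(self):
        # a matrix known to produce a negative NJ branch estimate
        d = np.array(
            [[0.0, 0.1, 0.6, 0.6], [0.1, 0.0, 0.65, 0.65],
             [0.6, 0.65, 0.0, 0.1], [0.6, 0.65, 0.1, 0.0]]
        )
        tree = nj_tree(d, list("ABCD"))

        def all_lengths(node):
            yield node.length
            for c in node.children:
                yield from all_lengths(c)

        assert all(ln >= 0 for ln in all_lengths(tree))

    @pytest.mark.parametrize(
        "bad, message",
        [
            (np.array([[0, 1], [1, 0]], float), "at least 3"),
            (np.array([[0, 1, 2], [5, 0, 1], [2, 1, 0]], float), "asymmetric"),
            (np.array([[1, 1, 2], [1, 0, 1], [2, 1, 1]], float), "diagonal"),
        ],
    )
    def test_invalid_matrices_rejected(self, bad, message):
        with pytest.raises(ValueError, match=message):
            nj_tree(bad, [f"t{i}" for i in range(len(bad))])


class TestBootstrap:
    def test_subfamily_split_gets_strong_support(self, two_subfamily_data):
        """The planted A/B divergence shows up as a >95% supported bipartition."""
        msa = two_subfamily_data.msa
        labels = two_subfamily_data.labels
        tree = bootstrap_support(msa, n_boot=60, seed=4)
        b_side = frozenset(i for i in msa.ids if labels[i] == "B")
        splits = {}

        def collect(node):
            for c in node.children:
                collect(c)
            if not node.is_leaf and node.support is not None:
                splits[frozenset(node.leaves())] = node.support

        collect(tree)
        matching = [s for leaves, s in splits.items()
                    if leaves == b_side or leaves == set(msa.ids) - b_side]
        assert matching and max(matching) > 0.95

    def test_same_seed_reproduces_supports(self, two_subfamily_data):
        msa = two_subfamily_data.msa
        a = bootstrap_support(msa, n_boot=20, seed=11).to_newick()
        b = bootstrap_support(msa, n_boot=20, seed=11).to_newick()
        assert a == b

    def test_newick_output_parses_with_dendropy(self, two_subfamily_data):
        dendropy = pytest.importorskip("dendropy")
        tree = bootstrap_support(two_subfamily_data.msa, n_boot=15, seed=2)
        parsed = dendropy.Tree.get(data=tree.to_newick(), schema="newick")
        assert len(parsed.leaf_nodes()) == two_subfamily_data.msa.n_sequences

    def test_short_alignment_warns(self):
        fam = gen_family_msa(FamilySpec(n_sequences=6, length=8), seed=1)
        with pytest.warns(UserWarning, match="columns"):
            bootstrap_support(fam.msa, n_boot=10, seed=0)

    def test_identity_distance_matrix_properties(self, two_subfamily_data):
        rows = list(two_subfamily_data.msa.rows)
        d = msa_distance_matrix(rows)
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)
        assert d.max() <= 1.0
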