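import numpy as np
import pytest

from parashore.datamodel import GenotypeMatrix
from parashore.phylo import (
    DistanceMatrix,
    bootstrap_support,
    chord_distance,
    midpoint_root,
    nj_tree,
)


def _random_additive(n, seed):
    """Random binary tree -> taxa, additive distance matrix."""
    rng = np.random.default_rng(seed)
    clusters = [([i], {i: 0.0}) for i in range(n)]
    D = np.zeros((n, n))
    while len(clusters) > 1:
        ia, ib = rng.choice(len(clusters), size=2, replace=False)
        a, b = clusters[ia], clusters[ib]
        clusters = [c for k, c in enumerate(clusters) if k not in (ia, ib)]
        la, lb = rng.uniform(0.1, 1.0, 2)
        for i in a[0]:
            for j in b[0]:
                D[i, j] = D[j, i] = a[1][i] + la + b[1][j] + lb
        clusters.append((
            a[0] + b[0],
            {**{i: d + la for i, d in a[1].items()},
             **{j: d + lb for j, d in b[1].items()}},
        ))
    return [f"T{i}" for i in range(n)], D


def _tree_distances(tree, labels):
    pdm = tree.phylogenetic_distance_matrix()
    tns = tree.taxon_namespace
    n = len(labels)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = pdm.patristic_distance(
                tns.get_taxon(labels[i]), tns.get_taxon(labels[j])
            )
    return out


class TestChordDistance:
    def test_identical_individuals_zero(self):
        gm = GenotypeMatrix(np.array([[1, 0, 2], [1, 0, 2]], dtype=np.int8),
                            ["a", "b"], [(1, 0), (2, 0), (3, 0)])
        assert chord_distance(gm).values[0, 1] == 0.0

    def test_opposite_homozygotes_closed_form(self):
        gm = GenotypeMatrix(np.array([[0] * 5, [2] * 5], dtype=np.int8),
                            ["a", "b"], [(j, 0) for j in range(1, 6)])
        expected = (2 / np.pi) * np.sqrt(2.0)
        assert chord_distance(gm).values[0, 1] == pytest.approx(expected)

    def test_hand_computed_three_loci(self):
        # dosages a=(0,1,2), b=(2,1,0): per-locus profiles
        # c1 = 1 - sqrt(0*1) - sqrt(1*0) = 1; c2 = 1 - .5 - .5 = 0; c3 = 1
        # D = (2/pi) * sqrt(2*(1+0+1)/3)
        gm = GenotypeMatrix(np.array([[0, 1, 2], [2, 1, 0]], dtype=np.int8),
                            ["a", "b"], [(1, 0), (2, 0), (3, 0)])
        expected = (2 / np.pi) * np.sqrt(2 * 2 / 3)
        assert chord_distance(gm).values[0, 1] == pytest.approx(expected)

    def test_pairwise_complete_denominator(self):
        gm = GenotypeMatrix(np.array([[0, -1, 2], [2, 1, -1]], dtype=np.int8),
                            ["a", "b"], [(1, 0), (2, 0), (3, 0)])
        dm = chord_distance(gm)
        assert dm.pair_loci[0, 1] == 1  # only locus 1 shared
        assert dm.values[0, 1] == pytest.approx((2 / np.pi) * np.sqrt(2.0))

    def test_no_shared_loci_names_pair(self):
        gm = GenotypeMatrix(np.array([[0, -1], [-1, 1]], dtype=np.int8),
                            ["a", "b"], [(1, 0), (2, 0)])
        with pytest.raises(ValueError, match="'a' and 'b'"):
            chord_distance(gm)


class TestNeighborJoining:
    @pytest.mark.parametrize("n,seed", [(4, 1), (5, 2), (6, 3), (7, 4), (8, 5)])
    def test_inverts_additive_matrices(self, n, seed):
        labels, D = _random_additive(n, seed)
        tree = nj_tree(DistanceMatrix(D, labels, np.ones_like(D)))
        np.testing.assert_allclose(_tree_distances(tree, labels), D, atol=1e-9)

    def test_matches_skbio_topology(self):
        from skbio import DistanceMatrix as SkDM
        from skbio.tree import nj as sknj

        labels, D = _random_additive(7, seed=11)
        ours = nj_tree(DistanceMatrix(D, labels, np.ones_like(D)))
        theirs = sknj(SkDM(D, ids=labels))
        d_ours = _tree_distances(ours, labels)
        sk = np.array([[theirs.find(a).distance(theirs.find(b))
                        for b in labels] for a in labels])
        np.testing.assert_allclose(d_ours, sk, atol=1e-6)

    def test_three_taxa_closed_form(self):
        D = np.array([[0, 2, 3], [2, 0, 5], [3, 5, 0]], dtype=float)
        tree = nj_tree(DistanceMatrix(D, ["a", "b", "c"], np.ones((3, 3))))
        dist = _tree_distances(tree, ["a", "b", "c"])
        np.testing.assert_allclose(dist, D, atol=1e-9)

    def test_negative_lengths_clamped_raw_retained(self):
        # triangle-inequality violation forces a negative branch estimate
        D = np.array([[0.0, 1.0, 1.0],
                      [1.0, 0.0, 3.0],
                      [1.0, 3.0, 0.0]])
        tree = nj_tree(DistanceMatrix(D, list("abc"), np.ones((3, 3))))
        raws = [nd.raw_length for nd in tree
                if getattr(nd, "raw_length", None) is not None]
        assert any(r < 0 for r in raws)
        assert all(nd.edge.length >= 0 for nd in tree
                   if nd.edge.length is not None)

    def test_rejects_nan(self):
        D = np.zeros((3, 3))
        D[0, 1] = D[1, 0] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            nj_tree(DistanceMatrix(D, list("abc"), np.ones((3, 3))))


class TestBootstrap:
    def _clustered_gm(self, seed=6):
        rng = np.random.default_rng(seed)
        p = rng.uniform(0.05, 0.3, 150)
        q = np.clip(p + 0.6, 0.05, 0.95)
        d = np.vstack([rng.binomial(2, p, (6, 150)),
                       rng.binomial(2, q, (6, 150))]).astype(np.int8)
        return GenotypeMatrix(d, [f"x{i}" for i in range(6)] +
                              [f"y{i}" for i in range(6)],
                              [(j + 1, 0) for j in range(150)])

    def test_clear_clusters_high_support(self):
        gm = self._clustered_gm()
        tree = bootstrap_support(gm, n_boot=50, seed=1)
        tree.encode_bipartitions()
        cluster = {f"y{i}" for i in range(6)}
        found = []
        for node in tree.preorder_node_iter():
            if node.is_leaf() or node is tree.seed_node:
                continue
            leaves = {t.taxon.label for t in node.leaf_iter()}
            if leaves == cluster or leaves == (set(gm.sample_ids) - cluster):
                found.append(node.support)
        assert found and max(found) >= 0.95 * 50

    def test_single_replicate_support_binary(self):
        gm = self._clustered_gm()
        tree = bootstrap_support(gm, n_boot=1, seed=2)
        supports = [nd.support for nd in tree.preorder_internal_node_iter()
                    if nd is not tree.seed_node]
        assert set(supports) <= {0, 1}

    def test_seeded_reproducibility(self):
        gm = self._clustered_gm()
        t1 = bootstrap_support(gm, n_boot=10, seed=3)
        t2 = bootstrap_support(gm, n_boot=10, seed=3)
        s1 = sorted(nd.support for nd in t1.preorder_internal_node_iter()
                    if nd is not t1.seed_node)
        s2 = sorted(nd.support for nd in t2.preorder_internal_node_iter()
                    if nd is not t2.seed_node)
        assert s1 == s2


class TestMidpointRoot:
    def test_balances_longest_path(self):
        labels, D = _random_additive(8, seed=21)
        tree = midpoint_root(nj_tree(DistanceMatrix(D, labels, np.ones_like(D))))
        pdm = tree.phylogenetic_distance_matrix()
        tns = tree.taxon_namespace
        longest = max(
            pdm.patristic_distance(a, b)
            for a, b in pdm.distinct_taxon_pair_iter()
        )
        depths = {}
        for leaf in tree.leaf_node_iter():
            depths[leaf.taxon.label] = leaf.distance_from_root()
        deepest = sorted(depths.values())[-2:]
        assert abs(deepest[0] - deepest[1]) <= longest / 2 + 1e-9
        assert max(depths.values()) == pytest.approx(longest / 2, rel=1e-6)

    def test_zero_length_tree_warns(self):
        D = np.zeros((3, 3))
        tree = nj_tree(DistanceMatrix(D, list("abc"), np.ones((3, 3))))
        with pytest.warns(UserWarning, match="zero"):
            midpoint_root(tree)
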