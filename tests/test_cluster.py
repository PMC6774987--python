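"""UPGMA clustering, bootstrap node support, stable clusters, CCC, Newick."""

import numpy as np
import pytest

from levensong.cluster import (
    SupportedDendrogram,
    cophenetic_correlation,
    multiscale_bootstrap,
    stable_clusters,
    to_newick,
    upgma,
)
from levensong.seqsim import SimilarityMatrix


def naive_upgma(D: np.ndarray):
    """Reference average-linkage clustering by direct cluster-pair averaging.

    Returns merges as (leafset, height) in merge order.
    """
    D = np.asarray(D, dtype=float)
    clusters: list[frozenset[int]] = [frozenset((i,)) for i in range(len(D))]
    merges = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                h = np.mean([D[a, b] for a in clusters[i] for b in clusters[j]])
                if best is None or h < best[0]:
                    best = (h, i, j)
        h, i, j = best
        merged = clusters[i] | clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
        merges.append((merged, h))
    return merges


def test_upgma_two_items():
    tree = upgma(np.array([[0.0, 0.4], [0.4, 0.0]]), ids=("A", "B"))
    assert tree.heights.tolist() == [0.4]
    assert tree.leaf_names(0) == frozenset({"A", "B"})


def test_upgma_three_item_hand_example():
    D = np.array([[0.0, 2.0, 4.0], [2.0, 0.0, 6.0], [4.0, 6.0, 0.0]])
    tree = upgma(D, ids=("A", "B", "C"))
    assert tree.heights.tolist() == [2.0, 5.0]
    assert tree.leaf_names(0) == frozenset({"A", "B"})


def test_upgma_rejects_asymmetric_input():
    with pytest.raises(ValueError, match="symmetric"):
        upgma(np.array([[0.0, 1.0], [2.0, 0.0]]))


def test_upgma_cophenetic_is_ultrametric():
    rng = np.random.default_rng(0)
    n = 7
    D = rng.uniform(0.1, 1.0, (n, n))
    D = (D + D.T) / 2
    np.fill_diagonal(D, 0.0)
    tree = upgma(D)
    from scipy.spatial.distance import squareform

    C = squareform(tree.cophenetic())
    for i in range(n):
        for j in range(n):
            for k in range(n):
                assert C[i, j] <= max(C[i, k], C[k, j]) + 1e-9


def test_upgma_agrees_with_naive_reference():
    rng = np.random.default_rng(42)
    for _ in range(100):
        n = int(rng.integers(3, 9))
        D = rng.uniform(0.0, 1.0, (n, n))
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0.0)
        tree = upgma(D)
        ref = naive_upgma(D)
        got = [(tree.leafset(k), tree.heights[k]) for k in range(n - 1)]
        for (ls_ref, h_ref), (ls_got, h_got) in zip(ref, got):
            assert ls_ref == ls_got
            assert h_got == pytest.approx(h_ref, abs=1e-9)


def _sim_from_distance(D, ids):
    S = 1.0 - np.asarray(D, dtype=float)
    np.fill_diagonal(S, 1.0)
    return SimilarityMatrix(ids=tuple(ids), values=S)


def test_bootstrap_deterministic_under_seed():
    rng = np.random.default_rng(3)
    X = rng.normal(0.0, 1.0, (12, 8))
    t1 = multiscale_bootstrap(X, B=100, seed=5)
    t2 = multiscale_bootstrap(X, B=100, seed=5)
    np.testing.assert_array_equal(t1.au, t2.au)
    np.testing.assert_array_equal(t1.bp, t2.bp)
    np.testing.assert_array_equal(t1.se, t2.se)


def test_bootstrap_separated_blocks_strongly_supported():
    rng = np.random.default_rng(0)
    X = rng.normal(0.0, 1.0, (30, 10))
    X[:, 5:] += 5.0
    tree = multiscale_bootstrap(X, ids=[f"i{k}" for k in range(10)], B=200, seed=1)
    blocks = (frozenset(f"i{k}" for k in range(5)),
              frozenset(f"i{k}" for k in range(5, 10)))
    support = [tree.au[k] for k in range(9) if tree.leaf_names(k) in blocks]
    assert support and min(support) > 0.95


def test_bootstrap_support_in_unit_interval_and_au_ge_bp_signature():
    """Multiscale signature: for genuine clusters whose recovery grows with
    the resampling ratio, the extrapolated AU is not below the plain BP."""
    rng = np.random.default_rng(2)
    X = rng.normal(0.0, 1.0, (20, 12))
    X[:, 6:] += 1.5  # moderate separation: support away from both extremes
    tree = multiscale_bootstrap(X, B=500, seed=4)
    assert np.all(tree.au >= 0) and np.all(tree.au <= 1)
    assert np.all(tree.bp >= 0) and np.all(tree.bp <= 1)
    block = frozenset(str(k) for k in range(6, 12))
    for k in range(tree.n_leaves - 1):
        if tree.leaf_names(k) == block and 0.2 < tree.bp[k] < 0.98:
            assert tree.au[k] >= tree.bp[k] - 0.05


def test_bootstrap_requires_minimum_replicates():
    with pytest.raises(ValueError, match="B"):
        multiscale_bootstrap(np.zeros((4, 4)), B=10)


def _planted_tree(au_values):
    """5-leaf tree: ((A,B),(C,D)) then +E; au given in merge order."""
    Z = np.array(
        [
            [0.0, 1.0, 0.2, 2.0],
            [2.0, 3.0, 0.3, 2.0],
            [5.0, 6.0, 0.5, 4.0],
            [4.0, 7.0, 0.8, 5.0],
        ]
    )
    au = np.asarray(au_values, dtype=float)
    return SupportedDendrogram(
        ids=("A", "B", "C", "D", "E"), merges=Z, au=au, bp=au.copy(),
        se=np.zeros(4),
    )


def test_stable_clusters_empty_when_no_support():
    assert len(stable_clusters(_planted_tree([0.0, 0.0, 0.0, 0.0]))) == 0


def test_stable_clusters_maximality_reports_outer_only():
    tree = _planted_tree([0.99, 0.98, 0.97, 0.1])
    found = stable_clusters(tree).clusters
    assert found == [frozenset({"A", "B", "C", "D"})]


def test_stable_clusters_planted_boxes():
    tree = _planted_tree([0.99, 0.2, 0.3, 0.96])
    # root excluded even though AU > threshold; {A,B} is the only box
    found = stable_clusters(tree).clusters
    assert found == [frozenset({"A", "B"})]


def test_ccc_is_one_for_ultrametric_input():
    D = np.array(
        [
            [0.0, 0.2, 0.8, 0.8],
            [0.2, 0.0, 0.8, 0.8],
            [0.8, 0.8, 0.0, 0.4],
            [0.8, 0.8, 0.4, 0.0],
        ]
    )
    tree = upgma(D)
    assert cophenetic_correlation(tree, D) == pytest.approx(1.0)


def test_ccc_four_point_hand_example():
    # merges by hand: (A,B)@1; +C@mean(5,5.5)=5.25; +D@mean(9,9.5,8)=8.8333
    D = np.array(
        [
            [0.0, 1.0, 5.0, 9.0],
            [1.0, 0.0, 5.5, 9.5],
            [5.0, 5.5, 0.0, 8.0],
            [9.0, 9.5, 8.0, 0.0],
        ]
    )
    tree = upgma(D, ids=("A", "B", "C", "D"))
    orig = [1.0, 5.0, 9.0, 5.5, 9.5, 8.0]  # AB AC AD BC BD CD
    h3 = (9.0 + 9.5 + 8.0) / 3
    coph = [1.0, 5.25, h3, 5.25, h3, h3]
    expected = np.corrcoef(orig, coph)[0, 1]
    assert cophenetic_correlation(tree, D) == pytest.approx(expected, abs=1e-12)


def test_ccc_undefined_below_three_items():
    tree = upgma(np.array([[0.0, 0.4], [0.4, 0.0]]))
    with pytest.raises(ValueError, match="< 3"):
        cophenetic_correlation(tree, np.array([[0.0, 0.4], [0.4, 0.0]]))


def test_newick_two_leaf_shape():
    tree = upgma(np.array([[0.0, 0.4], [0.4, 0.0]]), ids=("A", "B"))
    assert to_newick(tree) == "(A:0.2,B:0.2);"


def test_newick_round_trip_preserves_topology_and_heights():
    import dendropy

    rng = np.random.default_rng(1)
    D = rng.uniform(0.1, 1.0, (6, 6))
    D = (D + D.T) / 2
    np.fill_diagonal(D, 0.0)
    ids = tuple("abcdef")
    tree = upgma(D, ids=ids)
    parsed = dendropy.Tree.get(data=to_newick(tree), schema="newick")
    clades = {
        frozenset(l.taxon.label for l in node.leaf_iter())
        for node in parsed.preorder_internal_node_iter()
    }
    for k in range(5):
        assert tree.leaf_names(k) in clades
    pd_mat = parsed.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in parsed.taxon_namespace}
    from scipy.spatial.distance import squareform

    C = squareform(tree.cophenetic())
    for i in range(6):
        for j in range(i + 1, 6):
            assert pd_mat.distance(taxa[ids[i]], taxa[ids[j]]) == pytest.approx(
                C[i, j], abs=1e-6
            )


def test_newick_quotes_names_with_spaces():
    tree = upgma(
        np.array([[0.0, 0.4], [0.4, 0.0]]), ids=("singer one", "singer two")
    )
    nwk = to_newick(tree)
    assert "'singer one'" in nwk and "'singer two'" in nwk
    import dendropy

    parsed = dendropy.Tree.get(data=nwk, schema="newick")
    assert {t.label for t in parsed.taxon_namespace} == {"singer one", "singer two"}


def test_newick_includes_support_labels():
    rng = np.random.default_rng(6)
    X = rng.normal(0.0, 1.0, (10, 5))
    tree = multiscale_bootstrap(X, B=100, seed=0)
    assert "AU=" in to_newick(tree) and "BP=" in to_newick(tree)
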