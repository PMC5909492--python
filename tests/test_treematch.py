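"""Pseudo-haplotypes, 3D embedding, GMM dG, Procrustes, permutation, trees."""
import io

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import cdist

import cylmap as cm
from cylmap.errors import InputError
from cylmap.geometry import random_rotation


def hap_table(seqs, counts):
    counts = np.asarray(counts, dtype=float)
    return pd.DataFrame({
        "sequence": seqs, "count": counts, "frequency": counts / counts.sum()})


# ---------------------------------------------------------------------------
# Pseudo-haplotype collapsing
# ---------------------------------------------------------------------------

def test_collapse_with_k_equal_n_is_identity():
    t = hap_table(["AAAA", "AAAC", "CCCC"], [5, 3, 2])
    ps = cm.collapse_pseudohaplotypes(t, k=3)
    assert ps.k == 3
    assert set(ps.sequences) == {"AAAA", "AAAC", "CCCC"}
    assert ps.frequencies.sum() == pytest.approx(1.0)


def test_collapse_merges_well_separated_pairs():
    # 3 planted pairs: members differ by 1, pairs differ by >= 6
    seqs = ["AAAAAAAA", "AAAAAAAC",
            "GGGGGGGG", "GGGGGGGT",
            "CCCCCCCC", "CCCCCCCA"]
    counts = [10, 2, 8, 1, 5, 4]
    ps = cm.collapse_pseudohaplotypes(hap_table(seqs, counts), k=3)
    assert ps.k == 3
    # representative = highest-count member of each pair
    assert set(ps.sequences) == {"AAAAAAAA", "GGGGGGGG", "CCCCCCCC"}
    assert sorted(np.round(ps.frequencies * 30).astype(int).tolist()) == [9, 9, 12]
    # members of each planted pair land in the same pseudo-haplotype
    assert ps.members[0] == ps.members[1]
    assert ps.members[2] == ps.members[3]
    assert ps.members[4] == ps.members[5]


def test_collapse_k1_pools_everything():
    t = hap_table(["AAAA", "CCCC", "GGGG"], [1, 1, 2])
    ps = cm.collapse_pseudohaplotypes(t, k=1)
    assert ps.k == 1
    assert ps.frequencies[0] == pytest.approx(1.0)


def test_collapse_requires_enough_haplotypes():
    with pytest.raises(InputError, match="k <="):
        cm.collapse_pseudohaplotypes(hap_table(["AAAA", "CCCC"], [1, 1]), k=5)


# ---------------------------------------------------------------------------
# Classical MDS embedding
# ---------------------------------------------------------------------------

def test_embed_recovers_3d_distances_exactly():
    rng = np.random.default_rng(0)
    pts = rng.normal(size=(8, 3)) * 2
    d = cdist(pts, pts)
    coords = cm.embed_3d(d)
    assert np.allclose(cdist(coords, coords), d, atol=1e-6)


def test_embed_regular_simplex_has_equal_distances():
    d = np.ones((4, 4)) - np.eye(4)
    coords = cm.embed_3d(d)
    dd = cdist(coords, coords)
    off = dd[~np.eye(4, dtype=bool)]
    assert np.allclose(off, off[0], atol=1e-8)


def test_embed_two_points_on_a_line():
    d = np.array([[0.0, 2.5], [2.5, 0.0]])
    coords = cm.embed_3d(d)
    assert np.linalg.norm(coords[0] - coords[1]) == pytest.approx(2.5)
    assert np.allclose(coords[:, 1:], 0.0, atol=1e-9)


def test_embed_sign_convention_is_deterministic():
    rng = np.random.default_rng(1)
    pts = rng.normal(size=(6, 3))
    d = cdist(pts, pts)
    c1, c2 = cm.embed_3d(d), cm.embed_3d(d.copy())
    assert np.array_equal(c1, c2)
    for axis in range(3):
        v = c1[:, axis]
        nz = np.flatnonzero(np.abs(v) > 1e-12)
        if nz.size:
            assert v[nz[0]] > 0


# ---------------------------------------------------------------------------
# dG
# ---------------------------------------------------------------------------

def grid_delta_g(g1, g2, span=4.0, step=0.125):
    """Numeric oracle: trapezoid integration of (f1 - f2)^2 on a 3D grid."""
    lo = np.minimum(g1.means.min(0), g2.means.min(0)) - span
    hi = np.maximum(g1.means.max(0), g2.means.max(0)) + span
    axes = [np.arange(lo[i], hi[i] + step, step) for i in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    diff2 = (g1.density(pts) - g2.density(pts)) ** 2
    return float(diff2.sum() * step ** 3)


@pytest.fixture(scope="module")
def gmm_pair():
    rng = np.random.default_rng(5)
    m1 = rng.normal(size=(4, 3))
    m2 = m1 + rng.normal(scale=0.4, size=(4, 3))
    w1 = np.array([0.4, 0.3, 0.2, 0.1])
    w2 = np.array([0.25, 0.25, 0.3, 0.2])
    return (cm.PopulationGMM(m1, w1, 0.25), cm.PopulationGMM(m2, w2, 0.25))


def test_delta_g_identical_gmms_is_zero(gmm_pair):
    g1, _ = gmm_pair
    assert cm.delta_g(g1, g1) == pytest.approx(0.0, abs=1e-15)


def test_delta_g_matches_grid_integration(gmm_pair):
    g1, g2 = gmm_pair
    assert cm.delta_g(g1, g2) == pytest.approx(grid_delta_g(g1, g2), abs=1e-4)


def test_delta_g_increases_monotonically_with_separation(gmm_pair):
    g1, _ = gmm_pair
    vals = [cm.delta_g(g1, g1.transformed(np.eye(3), np.array([t, 0, 0])))
            for t in (0.0, 0.5, 1.0, 2.0, 5.0)]
    assert all(a < b for a, b in zip(vals, vals[1:]))
    # far separation approaches the sum of the two self-overlap terms
    far = g1.transformed(np.eye(3), np.array([100.0, 0, 0]))
    from cylmap.treematch import _cross_term
    assert cm.delta_g(g1, far) == pytest.approx(2 * _cross_term(g1, g1), rel=1e-9)


def test_delta_g_invariant_to_component_order(gmm_pair):
    g1, g2 = gmm_pair
    perm = [2, 0, 3, 1]
    g2p = cm.PopulationGMM(g2.means[perm], g2.weights[perm], g2.sigma2)
    assert cm.delta_g(g1, g2p) == pytest.approx(cm.delta_g(g1, g2), abs=1e-14)


# ---------------------------------------------------------------------------
# Procrustes superposition
# ---------------------------------------------------------------------------

def test_procrustes_recovers_rigid_and_mirror_transforms(gmm_pair):
    g1, _ = gmm_pair
    rng = np.random.default_rng(9)
    for mirror in (False, True) * 5:
        rot = random_rotation(rng, mirror=mirror)
        moved = g1.transformed(rot, rng.normal(scale=5.0, size=3))
        res = cm.procrustes_superimpose(g1, moved)
        assert res.delta_g < 1e-8
        assert np.allclose(res.rotation @ res.rotation.T, np.eye(3), atol=1e-8)


def test_procrustes_permuted_frequencies_raise_delta_g(gmm_pair):
    g1, _ = gmm_pair
    perm = cm.PopulationGMM(g1.means, g1.weights[[1, 2, 3, 0]], g1.sigma2)
    assert cm.procrustes_superimpose(g1, perm).delta_g > 1e-4


def test_procrustes_requires_matching_component_count(gmm_pair):
    g1, _ = gmm_pair
    g3 = cm.PopulationGMM(np.zeros((3, 3)), np.ones(3) / 3, 1.0)
    with pytest.raises(InputError):
        cm.procrustes_superimpose(g1, g3)


# ---------------------------------------------------------------------------
# Permutation test
# ---------------------------------------------------------------------------

def test_permutation_p_for_equal_frequencies_is_one(gmm_pair):
    g1, _ = gmm_pair
    u1 = g1.with_weights(np.full(4, 0.25))
    u2 = cm.PopulationGMM(g1.means + 0.1, np.full(4, 0.25), g1.sigma2)
    res = cm.permutation_test(u1, u2, n_perm=50, seed=0)
    assert res.p_value == pytest.approx(1.0)


def test_permutation_is_seed_reproducible_and_bounded(gmm_pair):
    g1, g2 = gmm_pair
    r1 = cm.permutation_test(g1, g2, n_perm=99, seed=4)
    r2 = cm.permutation_test(g1, g2, n_perm=99, seed=4)
    assert r1.p_value == r2.p_value
    assert 1 / 100 <= r1.p_value <= 1.0


def test_identical_gmms_with_skewed_frequencies_give_small_p():
    rng = np.random.default_rng(12)
    means = rng.normal(scale=3.0, size=(10, 3))
    w = 1.0 / np.arange(1, 11)
    w /= w.sum()
    g = cm.PopulationGMM(means, w, 0.2)
    res = cm.permutation_test(g, g, n_perm=500, seed=1)
    assert res.delta_g == pytest.approx(0.0, abs=1e-12)
    assert res.p_value < 0.05


# ---------------------------------------------------------------------------
# NJ trees
# ---------------------------------------------------------------------------

def test_nj_recovers_additive_four_taxon_tree():
    # classic additive matrix: ((A:2,B:3):3,(C:4,D:5)) style
    d = np.array([
        [0, 5, 9, 9],
        [5, 0, 10, 10],
        [9, 10, 0, 8],
        [9, 10, 8, 0],
    ], dtype=float)
    from skbio import TreeNode
    tree = TreeNode.read(io.StringIO(cm.nj_tree(d, list("ABCD"))))
    tt = tree.tip_tip_distances(list("ABCD"))
    for i, a in enumerate("ABCD"):
        for j, b in enumerate("ABCD"):
            assert tt[a, b] == pytest.approx(d[i, j], abs=1e-9)


def test_nj_three_taxa_closed_form():
    d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
    from skbio import TreeNode
    tree = TreeNode.read(io.StringIO(cm.nj_tree(d, list("ABC"))))
    # star resolution: branch lengths a=(3+4-5)/2=1, b=(3+5-4)/2=2, c=(4+5-3)/2=3
    lengths = {t.name: t.length for t in tree.tips()}
    assert lengths == {"A": pytest.approx(1.0), "B": pytest.approx(2.0),
                       "C": pytest.approx(3.0)}


def test_nj_topology_matches_upgma_on_ultrametric_matrix():
    # ultrametric: ((A,B),(C,D)) with heights 1 and 3
    d = np.array([
        [0, 2, 6, 6],
        [2, 0, 6, 6],
        [6, 6, 0, 2],
        [6, 6, 2, 0],
    ], dtype=float)
    import io as _io

    from scipy.cluster.hierarchy import average, to_tree
    from scipy.spatial.distance import squareform
    from skbio import TreeNode

    nj = TreeNode.read(_io.StringIO(cm.nj_tree(d, list("ABCD"))))

    def newick_from_scipy(node, names):
        if node.is_leaf():
            return names[node.id]
        left = newick_from_scipy(node.get_left(), names)
        right = newick_from_scipy(node.get_right(), names)
        return f"({left},{right})"

    upgma_root = to_tree(average(squareform(d)))
    upgma = TreeNode.read(_io.StringIO(newick_from_scipy(upgma_root, list("ABCD")) + ";"))
    assert nj.compare_rfd(upgma) == 0.0


def test_nj_requires_three_taxa():
    with pytest.raises(InputError):
        cm.nj_tree(np.array([[0.0, 1.0], [1.0, 0.0]]))


# ---------------------------------------------------------------------------
# Tanglegram edges
# ---------------------------------------------------------------------------

def test_tanglegram_identity_coords_connect_matching_leaves():
    rng = np.random.default_rng(2)
    pts = rng.normal(scale=4.0, size=(10, 3))
    edges = cm.tanglegram_edges(pts, pts, k_nn=5)
    assert {(i, i) for i in range(10)} <= set(edges)


def test_tanglegram_far_outlier_has_no_edges():
    rng = np.random.default_rng(3)
    pts1 = rng.normal(size=(6, 3))
    pts2 = pts1.copy()
    pts1 = np.vstack([pts1, [[500.0, 0, 0]]])
    pts2 = np.vstack([pts2, [[-500.0, 0, 0]]])
    edges = cm.tanglegram_edges(pts1, pts2, k_nn=2)
    assert all(6 not in (i, j) for i, j in edges)


def test_tanglegram_knn_equal_n_is_complete_bipartite():
    rng = np.random.default_rng(4)
    pts1 = rng.normal(size=(5, 3))
    pts2 = rng.normal(size=(5, 3))
    edges = cm.tanglegram_edges(pts1, pts2, k_nn=5)
    assert len(set(edges)) == 25
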