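import itertools

import dendropy
import numpy as np
import pandas as pd
import pytest

from metaclone import phylogeny as ph

# ---------------------------------------------------------------------------
# independent oracles: enumeration of unrooted topologies + least-squares fit


def enumerate_topologies(n):
    """All unrooted binary topologies over taxa 0..n-1 as edge lists."""
    base = [(0, -1), (1, -1), (2, -1)]
    trees = [base]
    next_internal = -2
    for t in range(3, n):
        new_trees = []
        for edges in trees:
            for i, (u, v) in enumerate(edges):
                w = next_internal
                rest = edges[:i] + edges[i + 1:]
                new_trees.append(rest + [(u, w), (w, v), (t, w)])
        trees = new_trees
        next_internal -= 1
    return trees


def _paths(edges, n):
    adj = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    out = {}
    for a in range(n):
        prev = {a: None}
        stack = [a]
        while stack:
            x = stack.pop()
            for y in adj[x]:
                if y not in prev:
                    prev[y] = x
                    stack.append(y)
        for b in range(a + 1, n):
            path = []
            x = b
            while prev[x] is not None:
                path.append(frozenset((x, prev[x])))
                x = prev[x]
            out[(a, b)] = path
    return out


def ls_fit_ss(edges, n, D):
    """Least-squares residual of fitting branch lengths to distances D."""
    edge_ids = {frozenset(e): i for i, e in enumerate(edges)}
    pairs = list(itertools.combinations(range(n), 2))
    A = np.zeros((len(pairs), len(edges)))
    y = np.array([D[a, b] for a, b in pairs])
    paths = _paths(edges, n)
    for r, (a, b) in enumerate(pairs):
        for e in paths[(a, b)]:
            A[r, edge_ids[e]] = 1.0
    x, *_ = np.linalg.lstsq(A, y, rcond=None)
    return float(np.sum((A @ x - y) ** 2))


def topology_splits(edges, n):
    """Nontrivial bipartitions induced by the internal edges."""
    adj = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    splits = set()
    for u, v in edges:
        if u >= 0 or v >= 0:
            continue
        # leaves on the u side of edge (u, v)
        seen = {v, u}
        stack = [u]
        side = set()
        while stack:
            x = stack.pop()
            if x >= 0:
                side.add(x)
            for y in adj[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        if 1 < len(side) < n - 1:
            splits.add(frozenset((frozenset(side),
                                  frozenset(range(n)) - frozenset(side))))
    return splits


def dendropy_splits(tree, labels):
    idx = {l: i for i, l in enumerate(labels)}
    n = len(labels)
    splits = set()
    for node in tree.preorder_node_iter():
        leaves = frozenset(idx[lf.taxon.label] for lf in node.leaf_iter()
                           if lf.taxon.label in idx)
        if 1 < len(leaves) < n - 1:
            splits.add(frozenset((leaves, frozenset(range(n)) - leaves)))
    return splits


def random_additive(n, rng):
    """Random binary tree with random branch lengths; returns (D, splits)."""
    topos = enumerate_topologies(n)
    edges = topos[rng.integers(len(topos))]
    lengths = {frozenset(e): rng.uniform(0.5, 2.0) for e in edges}
    paths = _paths(edges, n)
    D = np.zeros((n, n))
    for (a, b), path in paths.items():
        D[a, b] = D[b, a] = sum(lengths[e] for e in path)
    return D, topology_splits(edges, n)


# ---------------------------------------------------------------------------


class TestDistanceMatrix:
    def test_identical_profiles_zero_distance(self):
        prof = pd.DataFrame([[2, 2, 3], [2, 2, 3]], index=["a", "b"])
        d = ph.cna_distance_matrix(prof, min_shared_bins=1)
        assert d.loc["a", "b"] == 0.0

    def test_direct_arithmetic(self):
        prof = pd.DataFrame([[2, 2, 4], [2, 2, 2]], index=["a", "b"])
        d = ph.cna_distance_matrix(prof, min_shared_bins=1)
        assert d.loc["a", "b"] == pytest.approx(2 / 3)

    def test_symmetry_zero_diagonal_triangle(self):
        rng = np.random.default_rng(0)
        prof = pd.DataFrame(rng.integers(1, 5, size=(4, 200)),
                            index=list("abcd"))
        d = ph.cna_distance_matrix(prof).to_numpy()
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0)
        for i, j, k in itertools.permutations(range(4), 3):
            assert d[i, j] <= d[i, k] + d[k, j] + 1e-12

    def test_few_shared_bins_flagged_unreliable(self):
        prof = pd.DataFrame([[2, 3], [2, 2]], index=["a", "b"])
        mask = pd.DataFrame([[True, True], [True, False]], index=["a", "b"])
        with pytest.warns(UserWarning):
            d = ph.cna_distance_matrix(prof, mask, min_shared_bins=100)
        assert ("a", "b") in d.attrs["unreliable_pairs"]

    def test_planted_lineage_distances(self, noise_free_analysis):
        d = noise_free_analysis.distances
        assert d.loc["Pr1", "Pr3"] < d.loc["Pr1", "Pr4"]


class TestNjTree:
    def test_additive_four_taxon_exact(self):
        labels = ["A", "B", "C", "D"]
        D = pd.DataFrame([[0, 3, 9, 10], [3, 0, 10, 11],
                          [9, 10, 0, 7], [10, 11, 7, 0]],
                         index=labels, columns=labels, dtype=float)
        tree = ph.build_nj_tree(D, outgroup="A")
        splits = dendropy_splits(tree, labels)
        assert frozenset((frozenset({0, 1}), frozenset({2, 3}))) in splits
        # branch lengths: patristic distances reproduce the additive matrix
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        for a, b in itertools.combinations(labels, 2):
            assert pdm.distance(taxa[a], taxa[b]) == pytest.approx(D.loc[a, b], abs=1e-6)

    def test_two_samples_cherry(self):
        D = pd.DataFrame([[0.0, 4.0], [4.0, 0.0]], index=["a", "b"],
                         columns=["a", "b"])
        tree = ph.build_nj_tree(D, outgroup="a")
        lengths = [lf.edge.length for lf in tree.leaf_node_iter()]
        assert sum(lengths) == pytest.approx(4.0)

    @pytest.mark.parametrize("n", [5, 6])
    def test_matches_exhaustive_least_squares(self, n):
        """On additive matrices the NJ topology equals the unique
        zero-residual topology found by exhaustive least-squares search."""
        rng = np.random.default_rng(42 + n)
        for _ in range(5):
            D, true_splits = random_additive(n, rng)
            labels = [f"t{i}" for i in range(n)]
            topos = enumerate_topologies(n)
            scores = [ls_fit_ss(e, n, D) for e in topos]
            best = int(np.argmin(scores))
            assert scores[best] < 1e-18
            assert topology_splits(topos[best], n) == true_splits
            dm = pd.DataFrame(D, index=labels, columns=labels)
            tree = ph.build_nj_tree(dm, outgroup=labels[0])
            assert dendropy_splits(tree, labels) == true_splits

    @pytest.mark.parametrize("n", [7, 8])
    def test_recovers_random_additive_trees(self, n):
        """NJ recovers the generating topology of additive matrices
        (Robinson-Foulds distance zero)."""
        rng = np.random.default_rng(n)
        for _ in range(5):
            D, true_splits = random_additive(n, rng)
            labels = [f"t{i}" for i in range(n)]
            dm = pd.DataFrame(D, index=labels, columns=labels)
            tree = ph.build_nj_tree(dm, outgroup=labels[0])
            assert dendropy_splits(tree, labels) == true_splits

    def test_sample_permutation_gives_isomorphic_tree(self):
        rng = np.random.default_rng(3)
        D, _ = random_additive(6, rng)
        labels = [f"t{i}" for i in range(6)]
        dm = pd.DataFrame(D, index=labels, columns=labels)
        perm = ["t3", "t0", "t5", "t1", "t4", "t2"]
        t1 = ph.build_nj_tree(dm, outgroup="t0")
        t2 = ph.build_nj_tree(dm.loc[perm, perm], outgroup="t0")
        assert dendropy_splits(t1, labels) == dendropy_splits(t2, labels)

    def test_non_finite_distances_error(self):
        D = pd.DataFrame([[0, np.inf], [np.inf, 0]], index=["a", "b"],
                         columns=["a", "b"], dtype=float)
        with pytest.raises(ValueError):
            ph.build_nj_tree(D, outgroup="a")

    def test_simulated_cohort_root_split(self, noise_free_analysis):
        split = set(noise_free_analysis.root_split)
        assert split == {frozenset({"Pr1", "Pr2", "Pr3"}),
                         frozenset({"Pr4", "VT", "M1", "M2", "M3", "M4"})}


class TestNearestNeighbors:
    def test_unique_minima(self):
        D = pd.DataFrame([[0, 1, 5], [1, 0, 4], [5, 4, 0]],
                         index=list("abc"), columns=list("abc"), dtype=float)
        rep = ph.nearest_neighbor_report(D).set_index("sample")
        assert rep.loc["a", "nearest"] == "b"
        assert rep.loc["c", "nearest"] == "b"

    def test_all_equal_distances_all_tied(self):
        D = pd.DataFrame(1.0 - np.eye(3), index=list("abc"), columns=list("abc"))
        rep = ph.nearest_neighbor_report(D).set_index("sample")
        assert rep.loc["a", "nearest"] == "b,c"

    def test_vt_and_m3_mutual_nearest(self, noise_free_analysis):
        """VT and M3 carry identical planted events: mutual nearest
        neighbours at distance ~0."""
        rep = noise_free_analysis.neighbors.set_index("sample")
        assert "M3" in rep.loc["VT", "nearest"].split(",")
        assert "VT" in rep.loc["M3", "nearest"].split(",")
        assert rep.loc["VT", "distance"] < 0.01

    def test_pr4_nearest_is_m2(self, noise_free_analysis):
        rep = noise_free_analysis.neighbors.set_index("sample")
        assert rep.loc["Pr4", "nearest"] == "M2"
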