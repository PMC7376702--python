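"""p-distance / identity score, neighbor joining and Newick output."""

import io
import itertools

import numpy as np
import pytest
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj as skbio_nj

from sweepscan import (
    bootstrap_support, identity_score_matrix, nei_distance_matrix, nj_tree,
    p_distance, p_distance_matrix,
)

from conftest import make_gm

MISSING = -1


class TestPDistance:
    def test_identical_samples_distance_zero(self):
        gm = make_gm(np.array([[0, 1, 2], [0, 1, 2]], dtype=np.int8))
        assert p_distance(gm, 0, 1) == 0.0

    def test_opposite_homozygotes_distance_one(self):
        gm = make_gm(np.array([[0, 0, 0], [2, 2, 2]], dtype=np.int8))
        assert p_distance(gm, 0, 1) == 1.0

    def test_mixed_dosage_differences_average(self):
        # |Δ| of 0, 1, 2 equally -> (0 + 0.5 + 1)/3
        gm = make_gm(np.array([[0, 0, 0], [0, 1, 2]], dtype=np.int8))
        assert p_distance(gm, 0, 1) == pytest.approx(0.5)

    def test_missing_sites_excluded_pairwise(self):
        gm = make_gm(np.array([[0, MISSING, 2], [2, 1, MISSING]],
                              dtype=np.int8))
        assert p_distance(gm, 0, 1) == pytest.approx(1.0)  # only site 0 shared

    def test_no_shared_site_names_the_pair(self):
        gm = make_gm(np.array([[0, MISSING], [MISSING, 1]], dtype=np.int8))
        with pytest.raises(ValueError, match="s1.*s2"):
            p_distance(gm, 0, 1)

    def test_identity_score_is_complement(self):
        rng = np.random.default_rng(0)
        gm = make_gm(rng.integers(0, 3, size=(6, 40)).astype(np.int8))
        pd = p_distance_matrix(gm)
        ids, is_mat = identity_score_matrix(gm)
        assert ids == gm.sample_ids
        np.testing.assert_allclose(is_mat + pd.data, 1.0)
        np.testing.assert_allclose(np.diag(is_mat), 1.0)

    def test_heterozygote_vs_homozygote_half(self):
        gm = make_gm(np.array([[1], [0]], dtype=np.int8))
        _, is_mat = identity_score_matrix(gm)
        assert is_mat[0, 1] == pytest.approx(0.5)


def random_additive_tree(rng, taxa):
    """Random unrooted binary tree with positive branch lengths; returns
    (leaf-to-leaf distance dict, set of non-trivial bipartitions)."""
    # build by sequential leaf insertion on an edge list
    # represent tree as adjacency: node -> {neighbor: length}
    adj = {}

    def add_edge(a, b, w):
        adj.setdefault(a, {})[b] = w
        adj.setdefault(b, {})[a] = w

    def del_edge(a, b):
        del adj[a][b]
        del adj[b][a]

    nxt = [0]

    def inner():
        nxt[0] += 1
        return f"__i{nxt[0]}"

    blen = lambda: float(rng.uniform(0.05, 1.0))
    add_edge(taxa[0], taxa[1], blen())
    for leaf in taxa[2:]:
        edges = [(a, b) for a in adj for b in adj[a] if a < b]
        a, b = edges[rng.integers(0, len(edges))]
        w = adj[a][b]
        del_edge(a, b)
        mid = inner()
        split = float(rng.uniform(0.2, 0.8))
        add_edge(a, mid, w * split)
        add_edge(mid, b, w * (1 - split))
        add_edge(mid, leaf, blen())

    def leaf_dists(src):
        out, seen = {}, {src}
        stack = [(src, 0.0)]
        while stack:
            node, d = stack.pop()
            for nb, w in adj[node].items():
                if nb not in seen:
                    seen.add(nb)
                    if not str(nb).startswith("__i"):
                        out[nb] = d + w
                    stack.append((nb, d + w))
        return out

    dists = {}
    for t in taxa:
        for u, d in leaf_dists(t).items():
            dists[(t, u)] = d

    splits = set()
    for node in [n for n in adj if str(n).startswith("__i")]:
        for nb in adj[node]:
            side = set()
            seen = {node}
            stack = [nb]
            seen.add(nb)
            while stack:
                x = stack.pop()
                if not str(x).startswith("__i"):
                    side.add(x)
                for y in adj[x]:
                    if y not in seen:
                        seen.add(y)
                        stack.append(y)
            if 2 <= len(side) <= len(taxa) - 2:
                anchor = min(taxa)
                canon = frozenset(set(taxa) - side) if anchor in side \
                    else frozenset(side)
                splits.add(canon)
    return dists, splits


def dm_from_dists(dists, taxa):
    n = len(taxa)
    m = np.zeros((n, n))
    for i, a in enumerate(taxa):
        for j, b in enumerate(taxa):
            if i != j:
                m[i, j] = dists[(a, b)]
    m = (m + m.T) / 2  # path sums differ by ~1e-16 per direction
    return DistanceMatrix(m, ids=taxa)


class TestNeighborJoining:
    def test_two_taxa_single_edge(self):
        t = nj_tree(DistanceMatrix(np.array([[0, 0.4], [0.4, 0]]),
                                   ids=["A", "B"]))
        assert t.to_newick() == "(A:0.2,B:0.2);"

    def test_four_taxon_additive_recovery(self):
        rng = np.random.default_rng(1)
        taxa = ["A", "B", "C", "D"]
        dists, splits = random_additive_tree(rng, taxa)
        tree = nj_tree(dm_from_dists(dists, taxa))
        assert tree.bipartitions() == splits
        path = tree.path_length_matrix()
        for a, b in itertools.combinations(taxa, 2):
            assert path[a, b] == pytest.approx(dists[(a, b)], abs=1e-9)

    def test_additive_six_taxon_recovery_batch(self):
        rng = np.random.default_rng(2)
        taxa = list("ABCDEF")
        for _ in range(10):
            dists, splits = random_additive_tree(rng, taxa)
            tree = nj_tree(dm_from_dists(dists, taxa))
            assert tree.bipartitions() == splits
            path = tree.path_length_matrix()
            for a, b in itertools.combinations(taxa, 2):
                assert path[a, b] == pytest.approx(dists[(a, b)], abs=1e-9)

    def test_five_taxon_topology_matches_least_squares_search(self):
        """Exhaustive oracle: enumerate all 15 unrooted 5-taxon topologies,
        fit branch lengths by non-negative least squares, and check NJ picks
        the best-fitting topology on an additive matrix."""
        from scipy.optimize import nnls

        taxa = list("ABCDE")
        rng = np.random.default_rng(3)
        dists, _ = random_additive_tree(rng, taxa)
        dm = dm_from_dists(dists, taxa)
        pairs = list(itertools.combinations(range(5), 2))
        y = np.array([dm.data[i, j] for i, j in pairs])

        best = (np.inf, None)
        for topo_id, edges in enumerate(_five_taxon_topologies()):
            # edges: list of leaf-sets below each branch (7 branches)
            X = np.zeros((len(pairs), len(edges)))
            for col, below in enumerate(edges):
                for row, (i, j) in enumerate(pairs):
                    if (i in below) != (j in below):
                        X[row, col] = 1.0
            coef, _ = nnls(X, y)
            rss = float(((X @ coef - y) ** 2).sum())
            if rss < best[0]:
                internal = frozenset(
                    frozenset(taxa[k] for k in below)
                    for below in edges if len(below) == 2)
                best = (rss, internal)

        tree = nj_tree(dm)
        got = frozenset(
            s if len(s) == 2 else frozenset(set(taxa) - s)
            for s in tree.bipartitions())
        assert got == best[1]
        assert best[0] == pytest.approx(0.0, abs=1e-16)

    def test_matches_skbio_on_noisy_matrix(self):
        """Independent-implementation cross-check on a non-additive input."""
        rng = np.random.default_rng(4)
        taxa = list("ABCDEFG")
        dists, _ = random_additive_tree(rng, taxa)
        m = dm_from_dists(dists, taxa).data
        noise = rng.uniform(0, 0.02, size=m.shape)
        m = m + noise + noise.T
        np.fill_diagonal(m, 0)
        dm = DistanceMatrix(m, ids=taxa)
        mine = nj_tree(dm)
        theirs = skbio_nj(dm)
        their_splits = set()
        all_taxa = set(taxa)
        anchor = min(all_taxa)
        for node in theirs.non_tips(include_self=False):
            side = {t.name for t in node.tips()}
            if 2 <= len(side) <= len(taxa) - 2:
                their_splits.add(frozenset(
                    all_taxa - side if anchor in side else side))
        assert mine.bipartitions() == their_splits

    def test_input_order_invariance(self):
        rng = np.random.default_rng(5)
        taxa = list("ABCDEF")
        dists, _ = random_additive_tree(rng, taxa)
        dm = dm_from_dists(dists, taxa)
        shuffled = dm_from_dists(dists, ["D", "A", "F", "B", "E", "C"])
        assert nj_tree(dm).to_newick() == nj_tree(shuffled).to_newick()

    def test_invalid_matrices_rejected(self):
        with pytest.raises(Exception):
            nj_tree(DistanceMatrix(np.array([[0, 1], [2, 0]]), ids=["A", "B"]))
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(np.zeros((1, 1)), ids=["A"]))

    def test_negative_branch_clamped_and_logged(self):
        # classic non-additive matrix driving a negative NJ branch
        m = np.array([
            [0.0, 0.2, 0.5, 0.55, 0.9],
            [0.2, 0.0, 0.45, 0.5, 0.85],
            [0.5, 0.45, 0.0, 0.1, 0.6],
            [0.55, 0.5, 0.1, 0.0, 0.2],
            [0.9, 0.85, 0.6, 0.2, 0.0],
        ])
        tree = nj_tree(DistanceMatrix(m, ids=list("ABCDE")))
        lengths = []

        def walk(n):
            for c, l in n.children:
                lengths.append(l)
                walk(c)

        walk(tree.root)
        assert all(l >= 0 for l in lengths)


class TestNewick:
    def test_deterministic_serialization(self):
        rng = np.random.default_rng(6)
        taxa = list("ABCD")
        dists, _ = random_additive_tree(rng, taxa)
        dm = dm_from_dists(dists, taxa)
        assert nj_tree(dm).to_newick() == nj_tree(dm).to_newick()

    def test_roundtrip_through_skbio_parser(self):
        rng = np.random.default_rng(7)
        taxa = list("ABCDEF")
        dists, _ = random_additive_tree(rng, taxa)
        tree = nj_tree(dm_from_dists(dists, taxa))
        parsed = TreeNode.read(io.StringIO(tree.to_newick()))
        # isomorphism: identical tip set and tip-to-tip path lengths
        assert {t.name for t in parsed.tips()} == set(taxa)
        mine = tree.path_length_matrix()
        for a, b in itertools.combinations(taxa, 2):
            theirs = parsed.find(a).distance(parsed.find(b))
            assert theirs == pytest.approx(mine[a, b], abs=1e-9)


class TestBootstrapAndNei:
    def test_bootstrap_support_range_and_clear_split(self):
        rng = np.random.default_rng(8)
        # two well-separated clusters of 3 samples each
        block = np.zeros((6, 60), dtype=np.int8)
        block[3:, :30] = 2
        block[:3, 30:] = 2
        noise = rng.integers(0, 2, size=(6, 60)).astype(np.int8)
        gm = make_gm(np.clip(block + (rng.random((6, 60)) < 0.05) * noise,
                             0, 2).astype(np.int8))
        tree = bootstrap_support(gm, n_replicates=50, seed=0)
        supports = []

        def walk(n):
            if n.support is not None:
                supports.append(n.support)
            for c, _ in n.children:
                walk(c)

        walk(tree.root)
        assert supports and all(0 <= s <= 100 for s in supports)
        assert max(supports) > 90  # the cluster split is unambiguous

    def test_bootstrap_seed_reproducible(self):
        rng = np.random.default_rng(9)
        gm = make_gm(rng.integers(0, 3, size=(5, 30)).astype(np.int8))
        a = bootstrap_support(gm, 20, seed=11).to_newick(include_support=True)
        b = bootstrap_support(gm, 20, seed=11).to_newick(include_support=True)
        assert a == b

    def test_nei_distance_zero_for_identical_groups(self):
        rng = np.random.default_rng(10)
        d = rng.integers(0, 3, size=(4, 50)).astype(np.int8)
        gm = make_gm(np.vstack([d, d]))
        groups = {"X": gm.sample_ids[:4], "Y": gm.sample_ids[4:]}
        dm = nei_distance_matrix(gm, groups)
        assert dm["X", "Y"] == pytest.approx(0.0, abs=1e-12)

    def test_nei_distance_positive_for_diverged_groups(self):
        g1 = np.zeros((4, 50), dtype=np.int8)
        g2 = np.full((4, 50), 2, dtype=np.int8)
        g1[:, ::7] = 1  # keep some shared polymorphism
        gm = make_gm(np.vstack([g1, g2]))
        dm = nei_distance_matrix(gm, {"X": gm.sample_ids[:4],
                                      "Y": gm.sample_ids[4:]})
        assert dm["X", "Y"] > 0.5


def _five_taxon_topologies():
    """All 15 unrooted binary topologies on 5 leaves, each as the list of
    leaf-index sets below its 7 branches (5 pendant + 2 internal)."""
    out = []
    # choose the cherry pair {a,b} and the second cherry {c,d} from the rest;
    # topology = ((a,b),(c,d),e): 15 = C(5,2)*C(3,2)/... enumerate directly
    seen = set()
    for a, b in itertools.combinations(range(5), 2):
        rest = [x for x in range(5) if x not in (a, b)]
        for c, d in itertools.combinations(rest, 2):
            key = frozenset([frozenset([a, b]), frozenset([c, d])])
            if key in seen:
                continue
            seen.add(key)
            pendant = [{k} for k in range(5)]
            internal = [{a, b}, {c, d}]
            out.append(pendant + internal)
    assert len(out) == 15
    return out
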