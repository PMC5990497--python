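import numpy as np
import pytest

from deepneurite.connection import (CallableDissimilarity, SiameseConfig,
                                    UnitDissimilarity, build_dmst,
                                    build_pair_training_set, dissimilarity,
                                    load_siamese, merge_pair_sets,
                                    minimum_spanning_forest, save_siamese,
                                    train_siamese)
from deepneurite.detection import DetectedSignal
from deepneurite.imaging import Patch
from deepneurite.synthetic import SyntheticSpec, make_corpus

K = 15
SPEC = SyntheticSpec(dims=(96, 96, 32), axon_length=80, dendrite_length=(20, 35))


def prufer_mst_weight(weights: np.ndarray) -> float:
    """Brute-force minimum spanning tree weight of a complete graph by
    enumerating every labeled tree via its Prüfer sequence."""
    import itertools

    n = weights.shape[0]
    if n == 1:
        return 0.0
    if n == 2:
        return float(weights[0, 1])
    best = np.inf
    for seq in itertools.product(range(n), repeat=n - 2):
        degree = [1] * n
        for v in seq:
            degree[v] += 1
        seq_list = list(seq)
        total = 0.0
        deg = degree[:]
        import heapq

        leaves = [i for i in range(n) if deg[i] == 1]
        heapq.heapify(leaves)
        for v in seq_list:
            leaf = heapq.heappop(leaves)
            total += weights[leaf, v]
            deg[v] -= 1
            if deg[v] == 1:
                heapq.heappush(leaves, v)
        a = heapq.heappop(leaves)
        b = heapq.heappop(leaves)
        total += weights[a, b]
        best = min(best, total)
    return float(best)


def signals_of(points):
    return [DetectedSignal(float(x), float(y), float(z), 1.0, "final3d")
            for x, y, z in points]


def tree_edges(tree):
    return {tuple(sorted(((n.x, n.y, n.z),
                          (tree.node(n.parent).x, tree.node(n.parent).y,
                           tree.node(n.parent).z))))
            for n in tree.nodes if n.parent != -1}


class TestPairs:
    @pytest.fixture(scope="class")
    def scene(self):
        return make_corpus(1, SPEC, seed=31)[0]

    def test_chain_gives_edge_count_positives(self, scene):
        stack, tree, _ = scene
        ps = build_pair_training_set(stack, tree, k=K, neg_min_separation=30, seed=0)
        n_edges = sum(1 for n in tree.nodes if n.parent != -1)
        assert (ps.labels == 1).sum() == n_edges
        assert (ps.labels == 0).sum() == n_edges  # balanced

    def test_unreachable_separation_raises(self, scene):
        stack, tree, _ = scene
        with pytest.raises(RuntimeError, match="separated"):
            build_pair_training_set(stack, tree, k=K, neg_min_separation=1e6, seed=0)

    def test_fixed_seed_reproducible(self, scene):
        stack, tree, _ = scene
        a = build_pair_training_set(stack, tree, k=K, neg_min_separation=30, seed=5)
        b = build_pair_training_set(stack, tree, k=K, neg_min_separation=30, seed=5)
        for pa, pb in zip(a.patches_b, b.patches_b):
            assert np.array_equal(pa.pixels, pb.pixels)


class TestSiamese:
    @pytest.fixture(scope="class")
    def pairset(self):
        corpus = make_corpus(2, SPEC, seed=60)
        sets = [build_pair_training_set(s, t, k=K, neg_min_separation=30, seed=i)
                for i, (s, t, _) in enumerate(corpus)]
        return merge_pair_sets(sets)

    def test_positive_pairs_less_dissimilar(self, pairset):
        model = train_siamese(pairset, SiameseConfig(m=32, epochs=6), seed=0)
        stats = model.val_stats
        assert stats["median_pos"] < stats["median_neg"]
        assert stats["auc"] >= 0.8

    def test_shuffled_labels_no_signal(self, pairset):
        g = np.random.default_rng(0)
        shuffled = merge_pair_sets([pairset])
        shuffled.labels = g.permutation(shuffled.labels)
        model = train_siamese(shuffled, SiameseConfig(m=32, epochs=3), seed=0)
        assert abs(model.val_stats["auc"] - 0.5) < 0.2

    def test_fixed_seed_identical_model(self, pairset):
        a = train_siamese(pairset, SiameseConfig(m=16, epochs=2), seed=3)
        b = train_siamese(pairset, SiameseConfig(m=16, epochs=2), seed=3)
        for pa, pb in zip(a.net.params(), b.net.params()):
            assert np.array_equal(pa, pb)

    def test_dissimilarity_identity_symmetry_formula(self, pairset):
        model = train_siamese(pairset, SiameseConfig(m=16, epochs=1), seed=0)
        p, q = pairset.patches_a[0], pairset.patches_b[1]
        assert dissimilarity(model, p, p) == pytest.approx(0.0, abs=1e-9)
        assert dissimilarity(model, p, q) == pytest.approx(
            dissimilarity(model, q, p))
        e = model.embed([p, q])
        assert dissimilarity(model, p, q) == pytest.approx(
            float(np.sqrt(((e[0] - e[1]) ** 2).sum())))

    def test_roundtrip_through_file(self, pairset, tmp_path):
        model = train_siamese(pairset, SiameseConfig(m=16, epochs=1), seed=0)
        path = tmp_path / "siamese.model"
        save_siamese(model, path)
        back = load_siamese(path)
        p = pairset.patches_a[:4]
        assert np.array_equal(back.embed(p), model.embed(p))


class TestDMST:
    def test_collinear_points_chain_topology(self):
        sigs = signals_of([(0, 0, 0), (5, 0, 0), (10, 0, 0)])
        tree = build_dmst(sigs, model=None, complete=True)
        assert len(tree) == 3
        assert sorted(n.parent for n in tree.nodes) == [-1, 1, 2]

    def test_low_dissimilarity_diagonal_preferred(self):
        # unit square + one diagonal made nearly free by the stub model
        pts = [(0, 0, 0), (10, 0, 0), (10, 10, 0), (0, 10, 0)]
        sigs = signals_of(pts)

        def fn(p, q):
            ends = {tuple(p.center), tuple(q.center)}
            if ends == {(0.0, 0.0, 0.0), (10.0, 10.0, 0.0)}:
                return 0.001
            return 1.0

        # patches need real centers: fake a stack of zeros
        from deepneurite.imaging import ImageStack

        stack = ImageStack(np.zeros((3, 16, 16)))

        class StubModel(CallableDissimilarity):
            pass

        tree = build_dmst(sigs, stack, model=StubModel(fn), k=3, complete=True)
        edges = tree_edges(tree)
        assert tuple(sorted(((0.0, 0.0, 0.0), (10.0, 10.0, 0.0)))) in edges
        # oracle: exhaustive enumeration over all 16 labeled spanning trees
        w = np.zeros((4, 4))
        for i in range(4):
            for j in range(4):
                if i != j:
                    d = np.linalg.norm(np.subtract(pts[i], pts[j]))
                    dis = 0.001 if {i, j} == {0, 2} else 1.0
                    w[i, j] = d * dis
        got = 0.0
        for n in tree.nodes:
            if n.parent != -1:
                p = tree.node(n.parent)
                i = pts.index((n.x, n.y, n.z))
                j = pts.index((p.x, p.y, p.z))
                got += w[i, j]
        assert got == pytest.approx(prufer_mst_weight(w))

    def test_clusters_beyond_cutoff_stay_separate(self):
        sigs = signals_of([(0, 0, 0), (2, 0, 0), (200, 0, 0), (202, 0, 0)])
        tree = build_dmst(sigs, model=None, knn=3, max_edge_len=50)
        assert sum(n.parent == -1 for n in tree.nodes) == 2

    def test_empty_input_empty_tree(self):
        assert len(build_dmst([], model=None)) == 0

    def test_duplicate_coordinates_joined_first(self):
        sigs = signals_of([(0, 0, 0), (0, 0, 0), (5, 0, 0)])
        tree = build_dmst(sigs, model=None, complete=True)
        assert len(tree) == 3
        tree.validate()

    def test_unit_dissimilarity_equals_euclidean_mst_scipy(self, rng):
        """Independent route: scipy's sparse-graph MST on 50 random sets."""
        from scipy.sparse.csgraph import minimum_spanning_tree as scipy_mst
        from scipy.spatial.distance import squareform, pdist

        for trial in range(50):
            n = int(rng.integers(4, 13))
            pts = rng.uniform(0, 50, (n, 3))
            sigs = signals_of(pts)
            tree = build_dmst(sigs, model=None, complete=True)
            got = 0.0
            for node in tree.nodes:
                if node.parent != -1:
                    p = tree.node(node.parent)
                    got += np.linalg.norm(np.array([node.x, node.y, node.z]) -
                                          np.array([p.x, p.y, p.z]))
            w = squareform(pdist(pts))
            expect = scipy_mst(w).sum()
            assert got == pytest.approx(expect, rel=1e-9)

    def test_matches_prufer_bruteforce_on_random_weights(self, rng):
        """Exhaustive Prüfer enumeration oracle on 20 complete graphs."""
        for trial in range(20):
            n = int(rng.integers(3, 8))
            pts = rng.uniform(0, 30, (n, 3))
            dis = rng.uniform(0.1, 2.0, (n, n))
            dis = (dis + dis.T) / 2
            w = np.zeros((n, n))
            for i in range(n):
                for j in range(n):
                    if i != j:
                        w[i, j] = np.linalg.norm(pts[i] - pts[j]) * dis[i, j]
            edges = [(w[i, j], i, j) for i in range(n) for j in range(i + 1, n)]
            chosen = minimum_spanning_forest(n, edges)
            got = sum(w[i, j] for i, j in chosen)
            assert got == pytest.approx(prufer_mst_weight(w), rel=1e-9)

    def test_physical_units_respect_anisotropy(self, rng):
        from scipy.sparse.csgraph import minimum_spanning_tree as scipy_mst
        from scipy.spatial.distance import pdist, squareform

        from deepneurite.imaging import ImageStack

        voxel_size = np.array([1.0, 1.0, 5.0])
        pts = rng.uniform(0, 8, (8, 3))
        sigs = signals_of(pts)
        stack = ImageStack(np.zeros((10, 10, 10)), voxel_size=tuple(voxel_size))
        t_um = build_dmst(sigs, stack, model=None, complete=True, units="um")
        got = 0.0
        for node in t_um.nodes:
            if node.parent != -1:
                p = t_um.node(node.parent)
                got += np.linalg.norm(
                    (np.array([node.x, node.y, node.z]) -
                     np.array([p.x, p.y, p.z])) * voxel_size)
        expect = scipy_mst(squareform(pdist(pts * voxel_size))).sum()
        assert got == pytest.approx(expect, rel=1e-9)
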