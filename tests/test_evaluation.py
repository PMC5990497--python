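import numpy as np
import pytest

from deepneurite.evaluation import (BACKGROUND, FOREGROUND, classify_nodes,
                                    connect_gaps, consistency_score,
                                    cross_validated_consistency,
                                    evaluate_reconstruction)
from deepneurite.morphology import NeuronNode, NeuronTree
from deepneurite.patch_classifier import ConstantClassifier, TrainConfig
from deepneurite.synthetic import SyntheticSpec, make_corpus

K = 15
ALWAYS_FG = ConstantClassifier(K, [0.0, 1.0])
ALWAYS_BG = ConstantClassifier(K, [1.0, 0.0])


def chain(n, direction=(1, 0, 0), start=(0, 0, 0), type_code=3, id0=1, parent0=-1):
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    s = np.asarray(start, float)
    nodes = []
    for i in range(n):
        p = s + i * d
        nodes.append(NeuronNode(id0 + i, type_code, *p, 1.0,
                                parent0 if i == 0 else id0 + i - 1))
    return nodes


class TestClassifyNodes:
    @pytest.fixture(scope="class")
    def scene(self):
        return make_corpus(1, SyntheticSpec(), seed=55)[0]

    def test_stub_all_foreground(self, scene):
        stack, tree, _ = scene
        labels, scores = classify_nodes(tree, stack, ALWAYS_FG, k=K)
        assert all(v == FOREGROUND for v in labels.values())
        assert all(s == 1.0 for s in scores.values())

    def test_stub_all_background(self, scene):
        stack, tree, _ = scene
        labels, _ = classify_nodes(tree, stack, ALWAYS_BG, k=K)
        assert all(v == BACKGROUND for v in labels.values())


class TestConnectGaps:
    def make_gapped_chain(self, gap_start=10, gap_len=10, total=30,
                          direction=(1, 0, 0)):
        """Straight chain; nodes [gap_start, gap_start+gap_len) labeled bg."""
        nodes = chain(total, direction=direction)
        tree = NeuronTree(nodes)
        labels = {}
        for i, n in enumerate(tree.nodes):
            inside_gap = gap_start <= i < gap_start + gap_len
            labels[n.id] = BACKGROUND if inside_gap else FOREGROUND
        return tree, labels

    def test_collinear_short_gap_reinstated(self):
        tree, labels = self.make_gapped_chain(gap_len=10)
        refined, n = connect_gaps(tree, labels, angle_max=30, dist_max=30)
        assert n == 1
        assert all(v == FOREGROUND for v in refined.values())

    def test_long_gap_not_reinstated(self):
        tree, labels = self.make_gapped_chain(gap_len=40, total=90)
        refined, n = connect_gaps(tree, labels, angle_max=30, dist_max=30)
        assert n == 0
        assert refined == labels

    def test_angled_runs_not_reinstated(self):
        # two runs meeting at 45 degrees across a 5-voxel gap
        run_a = chain(10, direction=(1, 0, 0))
        elbow = np.array([9.0, 0, 0])
        d_b = np.array([np.cos(np.deg2rad(45)), np.sin(np.deg2rad(45)), 0])
        gap_nodes = []
        for i in range(5):
            p = elbow + (i + 1) * d_b
            gap_nodes.append(NeuronNode(11 + i, 3, *p, 1.0, 10 + i))
        run_b = []
        for i in range(10):
            p = elbow + (6 + i) * d_b
            run_b.append(NeuronNode(16 + i, 3, *p, 1.0, 15 + i))
        tree = NeuronTree(run_a + gap_nodes + run_b)
        labels = {n.id: BACKGROUND if 11 <= n.id <= 15 else FOREGROUND
                  for n in tree.nodes}
        refined, n = connect_gaps(tree, labels, angle_max=30, dist_max=30)
        assert n == 0

    def test_boundary_exactly_30_voxels_excluded(self):
        # strict inequality: tip distance exactly 30 must NOT connect
        run_a = chain(10, direction=(1, 0, 0))  # tips at x=0..9
        run_b = chain(10, direction=(1, 0, 0), start=(39, 0, 0), id0=11,
                      parent0=10)
        # bridge nodes between x=9 and x=39 along the tree path
        bridge = chain(29, direction=(1, 0, 0), start=(10, 0, 0), id0=21,
                       parent0=10)
        nodes = run_a + bridge
        run_b = chain(10, direction=(1, 0, 0), start=(39, 0, 0), id0=50,
                      parent0=49)
        tree = NeuronTree(nodes + run_b)
        labels = {n.id: FOREGROUND if (n.id <= 10 or n.id >= 50) else BACKGROUND
                  for n in tree.nodes}
        # tip at x=9 (id 10) and tip at x=39 (id 50): distance exactly 30
        refined, n = connect_gaps(tree, labels, angle_max=30, dist_max=30)
        assert n == 0
        refined, n = connect_gaps(tree, labels, angle_max=30, dist_max=30.01)
        assert n == 1

    def test_boundary_exactly_30_degrees_excluded(self):
        theta = np.deg2rad(30.0)
        run_a = chain(10, direction=(1, 0, 0))
        d_b = np.array([np.cos(theta), np.sin(theta), 0.0])
        start_b = np.array([9.0, 0, 0]) + 5 * d_b
        gap = []
        for i in range(4):
            p = np.array([9.0, 0, 0]) + (i + 1) * d_b
            gap.append(NeuronNode(11 + i, 3, *p, 1.0, 10 + i))
        run_b = []
        for i in range(10):
            p = start_b + i * d_b
            run_b.append(NeuronNode(15 + i, 3, *p, 1.0, 14 + i))
        tree = NeuronTree(run_a + gap + run_b)
        labels = {n.id: BACKGROUND if 11 <= n.id <= 14 else FOREGROUND
                  for n in tree.nodes}
        refined, n = connect_gaps(tree, labels, angle_max=30.0, dist_max=30)
        assert n == 0  # angle is exactly 30 degrees: strict rule
        refined, n = connect_gaps(tree, labels, angle_max=30.1, dist_max=30)
        assert n == 1

    def test_zero_thresholds_are_identity(self):
        tree, labels = self.make_gapped_chain()
        for am, dm in ((0, 30), (30, 0)):
            refined, n = connect_gaps(tree, labels, angle_max=am, dist_max=dm)
            assert refined == labels and n == 0

    def test_never_decreases_foreground(self):
        tree, labels = self.make_gapped_chain(gap_len=3)
        refined, _ = connect_gaps(tree, labels)
        before = sum(v == FOREGROUND for v in labels.values())
        after = sum(v == FOREGROUND for v in refined.values())
        assert after >= before


class TestConsistencyScore:
    def make_labeled(self, n_fg, n_total):
        tree = NeuronTree(chain(n_total, type_code=2))
        labels = {i + 1: FOREGROUND if i < n_fg else BACKGROUND
                  for i in range(n_total)}
        return tree, labels

    @pytest.mark.parametrize("n_fg,expect", [(100, 100.0), (98, 98.0), (0, 0.0)])
    def test_formula(self, n_fg, expect):
        tree, labels = self.make_labeled(n_fg, 100)
        rep = consistency_score(tree, labels)
        assert rep.c_overall == pytest.approx(expect)

    def test_per_type_scores(self):
        axon = chain(10, type_code=2)
        dend = chain(10, type_code=3, start=(0, 5, 0), id0=11)
        tree = NeuronTree(axon + dend)
        labels = {n.id: FOREGROUND for n in tree.nodes}
        for i in (1, 2):  # two axon nodes background
            labels[i] = BACKGROUND
        rep = consistency_score(tree, labels)
        assert rep.c_axon == pytest.approx(80.0)
        assert rep.c_dendrite == pytest.approx(100.0)
        assert rep.c_overall == pytest.approx(90.0)

    def test_invariant_under_node_reordering(self):
        tree, labels = self.make_labeled(7, 10)
        shuffled = NeuronTree(list(reversed(tree.nodes)))
        a = consistency_score(tree, labels).c_overall
        b = consistency_score(shuffled, labels).c_overall
        assert a == b

    def test_empty_tree_raises(self):
        with pytest.raises(ValueError, match="empty"):
            consistency_score(NeuronTree([]), {})

    def test_bounded_by_100(self):
        tree, labels = self.make_labeled(10, 10)
        assert consistency_score(tree, labels).c_overall <= 100.0


class TestCrossValidation:
    @pytest.fixture(scope="class")
    def corpus(self):
        spec = SyntheticSpec(dims=(64, 64, 32), axon_length=50,
                             dendrite_length=(15, 25), n_dendrite_trunks=2,
                             snr=8.0)
        return [(s, t) for s, t, _ in make_corpus(10, spec, seed=123)]

    def test_fold_arithmetic_disjoint_cover(self, corpus):
        results = cross_validated_consistency(
            corpus, n_folds=5, train_config=TrainConfig(epochs=3), seed=0, k=K)
        assert len(results) == 5
        held = [i for r in results for i in r["held_out"]]
        assert sorted(held) == list(range(10))
        assert all(len(r["held_out"]) == 2 for r in results)
        assert all(len(r["reports"]) == 2 for r in results)

    def test_too_few_datasets_raises(self, corpus):
        with pytest.raises(ValueError, match="fewer"):
            cross_validated_consistency(corpus[:3], n_folds=5)

    def test_high_snr_corpus_scores_high(self, corpus):
        results = cross_validated_consistency(
            corpus, n_folds=5, train_config=TrainConfig(epochs=6), seed=0, k=K)
        mean_c = np.mean([r["mean_c"] for r in results])
        assert mean_c >= 95.0
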