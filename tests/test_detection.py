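import numpy as np
import pytest
from scipy.spatial import cKDTree

from deepneurite.detection import (DetectionParams, detect, detect_2d,
                                   detection_f1, map_to_3d, mean_shift_refine,
                                   refine_3d, signals_to_frame, signals_to_swc,
                                   DetectedSignal)
from deepneurite.imaging import ImageStack, mip_xy, normalize_polarity
from deepneurite.patch_classifier import (ConstantClassifier, TrainConfig,
                                          build_detection_training_set,
                                          merge_sets, train)
from deepneurite.synthetic import SyntheticSpec, make_corpus

K = 15
SPEC = SyntheticSpec()  # default study conditions: 128x128x32, SNR 4, p_gap 0.3


@pytest.fixture(scope="module")
def trained():
    corpus = make_corpus(4, SPEC, seed=10)
    sets = [build_detection_training_set(s, t, k=K, seed=i)
            for i, (s, t, _) in enumerate(corpus)]
    return train(merge_sets(sets), TrainConfig(epochs=6), seed=0)


@pytest.fixture(scope="module")
def scene():
    return make_corpus(1, SPEC, seed=99)[0]


ALWAYS_FG = ConstantClassifier(K, [0.0, 1.0])
ALWAYS_BG = ConstantClassifier(K, [1.0, 0.0])


class TestDetect2D:
    def test_always_background_gives_empty(self):
        assert detect_2d(np.zeros((32, 32)), ALWAYS_BG, stride=4, k=K) == []

    def test_always_foreground_counts_grid(self):
        out = detect_2d(np.zeros((10, 10)), ALWAYS_FG, stride=10, k=K)
        assert len(out) == 1
        assert out[0].stage == "2d"

    def test_bad_threshold_rejected(self):
        with pytest.raises(ValueError, match="threshold"):
            detect_2d(np.zeros((10, 10)), ALWAYS_FG, threshold=0.0)

    def test_grid_recall_near_neurite(self, trained, scene):
        stack, tree, rend = scene
        mip = mip_xy(normalize_polarity(stack))
        out = detect_2d(mip, trained, stride=3, k=K)
        pts = np.array([[s.x, s.y] for s in out])
        kdt = cKDTree(pts)
        index = tree._index()
        lit_xy = np.array([[index[i].x, index[i].y] for i in rend.lit_node_ids])
        d, _ = kdt.query(lit_xy)
        assert (d <= 5).mean() >= 0.9


class TestMeanShift:
    def gaussian_blob(self, cx, cy, sigma=3.0, size=41):
        yy, xx = np.mgrid[0:size, 0:size]
        return np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sigma**2))

    def test_converges_to_blob_argmax(self):
        img = self.gaussian_blob(20.3, 17.7)
        s = DetectedSignal(23.0, 19.0, 0, 0.9, "2d")  # ~3 px off
        out = mean_shift_refine([s], img, bandwidth=6.0, tol=0.05)
        iy, ix = np.unravel_index(img.argmax(), img.shape)
        assert np.hypot(out[0].x - ix, out[0].y - iy) <= 0.5

    def test_constant_image_leaves_signal_in_place(self):
        s = DetectedSignal(10.0, 12.0, 0, 0.9, "2d")
        out = mean_shift_refine([s], np.full((32, 32), 5.0), bandwidth=5.0)
        assert (out[0].x, out[0].y) == (10.0, 12.0)

    def test_two_signals_on_one_blob_merge(self):
        img = self.gaussian_blob(20, 20)
        sigs = [DetectedSignal(18.0, 20.0, 0, 0.8, "2d"),
                DetectedSignal(22.0, 20.0, 0, 0.9, "2d")]
        out = mean_shift_refine(sigs, img, bandwidth=6.0)
        assert len(out) == 1
        assert out[0].score == 0.9  # highest score kept


class TestMapTo3D:
    def test_single_bright_voxel_column(self):
        v = np.zeros((12, 8, 8))
        v[7, 3, 4] = 100.0
        out = map_to_3d([DetectedSignal(4, 3, 0, 0.9, "refined2d")], ImageStack(v))
        assert out[0].z == 7

    def test_constant_column_tie_breaks_to_zero(self):
        out = map_to_3d([DetectedSignal(2, 2, 0, 0.5, "refined2d")],
                        ImageStack(np.full((9, 5, 5), 3.0)))
        assert out[0].z == 0

    def test_matches_bruteforce_argmax_of_smoothed_profile(self):
        g = np.random.default_rng(0)
        for _ in range(100):
            v = g.uniform(0, 100, (16, 4, 4))
            x, y = int(g.integers(0, 4)), int(g.integers(0, 4))
            out = map_to_3d([DetectedSignal(x, y, 0, 0.5, "refined2d")],
                            ImageStack(v))
            prof = v[:, y, x]
            # oracle: explicit [1, 2, 1]/4 tap with edge replication
            sm = [(prof[max(i - 1, 0)] + 2 * prof[i] + prof[min(i + 1, 15)]) / 4
                  for i in range(16)]
            assert out[0].z == int(np.argmax(sm))


class TestRefine3D:
    def test_always_foreground_passes_all(self, tiny_stack):
        sigs = [DetectedSignal(4, 3, 2, 0.7, "mapped3d")]
        out = refine_3d(sigs, tiny_stack, ConstantClassifier(3, [0.1, 0.9]), k=3)
        assert len(out) == 1
        assert out[0].score == pytest.approx(0.9)
        assert out[0].stage == "final3d"

    def test_always_background_removes_all(self, tiny_stack):
        sigs = [DetectedSignal(4, 3, 2, 0.7, "mapped3d")]
        assert refine_3d(sigs, tiny_stack, ConstantClassifier(3, [0.9, 0.1]), k=3) == []


class TestEndToEnd:
    def test_blank_stack_yields_nothing(self, trained, rng):
        v = rng.normal(100, 4, (16, 64, 64)).astype(np.float32)
        out = detect(ImageStack(v), trained, DetectionParams(stride=4, bandwidth=3.0))
        assert len(out) <= 3  # essentially nothing on pure noise

    def test_monotone_stage_counts(self, trained, scene):
        stack, _, _ = scene
        final, stages = detect(stack, trained,
                               DetectionParams(stride=3, bandwidth=3.0),
                               return_stages=True)
        grid = (np.ceil(128 / 3) ** 2)
        assert len(stages["2d"]) <= grid
        assert len(stages["refined2d"]) <= len(stages["2d"])
        assert len(stages["mapped3d"]) == len(stages["refined2d"])
        assert len(stages["final3d"]) <= len(stages["mapped3d"])

    def test_median_distance_to_centerline(self, trained, scene):
        stack, tree, rend = scene
        out = detect(stack, trained, DetectionParams(stride=3, bandwidth=3.0))
        kdt = cKDTree(tree.positions())
        d, _ = kdt.query(np.array([[s.x, s.y, s.z] for s in out]))
        assert np.median(d) <= 2.0

    def test_deterministic(self, trained, scene):
        stack, _, _ = scene
        p = DetectionParams(stride=4, bandwidth=3.0)
        a = detect(stack, trained, p)
        b = detect(stack, trained, p)
        assert [(s.x, s.y, s.z, s.score) for s in a] == \
               [(s.x, s.y, s.z, s.score) for s in b]


def test_outputs_as_frame_and_swc(tiny_stack):
    sigs = [DetectedSignal(1.0, 2.0, 3.0, 0.8, "final3d"),
            DetectedSignal(4.0, 5.0, 6.0, 0.9, "final3d")]
    df = signals_to_frame(sigs)
    assert list(df.columns) == ["x", "y", "z", "score", "stage"]
    tree = signals_to_swc(sigs)
    assert [n.parent for n in tree.nodes] == [-1, -1]
    assert all(n.type_code == 0 for n in tree.nodes)


def test_f1_empty_detections(scene):
    _, tree, rend = scene
    out = detection_f1([], tree, rend.lit_node_ids)
    assert out["f1"] == 0.0
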