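"""Swappable patch-classification contract and the reference CNN.

Every classification stage of the toolbox (signal detection, pruning,
consistency scoring, neurite typing) consumes a :class:`PatchClassifier`:
anything exposing ``n_classes``, ``patch_size`` and ``predict_proba`` can
stand behind it, from the seeded reference CNN trained here to a trivial
intensity threshold. Training sets are built from an image stack paired
with a manual SWC reconstruction: one positive block-MIP patch per
annotation node, and an equal number of background patches sampled away
from the tree ("the same number" convention for a balanced set).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from . import nn
from .imaging import ImageStack, Patch, block_mip_patch, normalize_polarity
from .morphology import NeuronTree

__all__ = [
    "LabeledPatchSet",
    "PatchClassifier",
    "CNNClassifier",
    "ThresholdClassifier",
    "ConstantClassifier",
    "TrainConfig",
    "build_detection_training_set",
    "build_type_training_set",
    "train",
    "save_model",
    "load_model",
]

DETECTION_CLASSES = ("background", "foreground")
TYPE_CLASSES = ("background", "axon", "dendrite")


@dataclass
class LabeledPatchSet:
    patches: list[Patch]
    labels: np.ndarray
    class_names: tuple[str, ...]

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.patches) != len(self.labels):
            raise ValueError("patches and labels must have equal length")
        if len(self.labels) and (
            self.labels.min() < 0 or self.labels.max() >= len(self.class_names)
        ):
            raise ValueError("labels out of range for class_names")

    def __len__(self):
        return len(self.patches)

    def as_array(self) -> np.ndarray:
        """(N, 1, k, k) float array for the network."""
        if not self.patches:
            return np.zeros((0, 1, 1, 1))
        return np.stack([p.pixels for p in self.patches])[:, None, :, :]


def patches_to_array(patches: list[Patch]) -> np.ndarray:
    if not patches:
        return np.zeros((0, 1, 1, 1))
    k = patches[0].size
    for p in patches:
        if p.size != k:
            raise ValueError("patches must share one size")
    return np.stack([p.pixels for p in patches])[:, None, :, :]


class PatchClassifier:
    """Contract: per-class probabilities for a batch of patches."""

    n_classes: int
    patch_size: int
    class_names: tuple[str, ...]

    def predict_proba(self, patches: list[Patch]) -> np.ndarray:
        raise NotImplementedError

    def _check(self, patches: list[Patch]) -> None:
        for p in patches:
            if p.size != self.patch_size:
                raise ValueError(
                    f"patch size {p.size} does not match model k={self.patch_size}"
                )


class CNNClassifier(PatchClassifier):
    """The seeded reference CNN behind the classifier contract."""

    def __init__(self, net: nn.Network, patch_size: int,
                 class_names: tuple[str, ...], seed: int,
                 val_accuracy: float | None = None, meta: dict | None = None):
        self.net = net
        self.patch_size = patch_size
        self.class_names = tuple(class_names)
        self.n_classes = len(self.class_names)
        self.seed = seed
        self.val_accuracy = val_accuracy
        self.meta = dict(meta or {})

    def predict_proba(self, patches: list[Patch]) -> np.ndarray:
        self._check(patches)
        if not patches:
            return np.zeros((0, self.n_classes))
        logits = self.net.predict_batched(patches_to_array(patches))
        return nn.softmax(logits)


class ThresholdClassifier(PatchClassifier):
    """Mean-intensity threshold stub — the minimal model satisfying the
    contract; also useful to cross-check backend swappability."""

    def __init__(self, patch_size: int, threshold: float = 0.5, sharpness: float = 50.0):
        self.patch_size = patch_size
        self.threshold = threshold
        self.sharpness = sharpness
        self.class_names = DETECTION_CLASSES
        self.n_classes = 2

    def predict_proba(self, patches):
        self._check(patches)
        if not patches:
            return np.zeros((0, 2))
        means = np.array([p.pixels.mean() for p in patches])
        p_fg = 1.0 / (1.0 + np.exp(-self.sharpness * (means - self.threshold)))
        return np.column_stack([1.0 - p_fg, p_fg])


class ConstantClassifier(PatchClassifier):
    """Always predicts one fixed probability row (test stub)."""

    def __init__(self, patch_size: int, probs, class_names=DETECTION_CLASSES):
        self.patch_size = patch_size
        self.probs = np.asarray(probs, dtype=float)
        self.class_names = tuple(class_names)
        self.n_classes = len(self.probs)

    def predict_proba(self, patches):
        self._check(patches)
        return np.tile(self.probs, (len(patches), 1))


@dataclass
class TrainConfig:
    epochs: int = 8
    batch_size: int = 64
    lr: float = 1e-3
    val_frac: float = 0.2
    channels: tuple[int, ...] = (8, 16)
    hidden: int = 32
    extra: dict = field(default_factory=dict)


def _sample_background_centers(stack: ImageStack, tree: NeuronTree, n: int,
                               min_bg_dist: float, rng: np.random.Generator):
    """Uniform centers ≥ min_bg_dist voxels from every tree node."""
    Z, Y, X = stack.voxels.shape
    kdt = cKDTree(tree.positions())
    centers = []
    attempts = 0
    max_attempts = max(2000, 1000 * n)
    while len(centers) < n:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"could not sample {n} background centers >= {min_bg_dist} "
                "voxels from the reconstruction (stack too small or too full)"
            )
        m = min(4 * (n - len(centers)) + 16, 4096)
        attempts += m
        cand = np.column_stack([
            rng.uniform(0, X - 1, m),
            rng.uniform(0, Y - 1, m),
            rng.uniform(0, Z - 1, m),
        ])
        d, _ = kdt.query(cand)
        for c in cand[d >= min_bg_dist]:
            centers.append(tuple(c))
            if len(centers) == n:
                break
    return centers


def build_detection_training_set(stack: ImageStack, tree: NeuronTree, k: int = 61,
                                 neg_ratio: float = 1.0, min_bg_dist: float = 10.0,
                                 seed: int = 0) -> LabeledPatchSet:
    """Balanced foreground/background patch set from one stack + SWC.

    Positives are block-MIP patches centered on every annotation node;
    negatives are patches at uniform background centers at least
    ``min_bg_dist`` voxels from any node, ``neg_ratio`` per positive.
    """
    if len(tree) == 0:
        raise ValueError("empty reconstruction: no positives to balance against")
    stack = normalize_polarity(stack)
    rng = np.random.default_rng(seed)
    patches = [block_mip_patch(stack, (n.x, n.y, n.z), k) for n in tree.nodes]
    labels = [1] * len(patches)
    n_neg = int(round(neg_ratio * len(patches)))
    for c in _sample_background_centers(stack, tree, n_neg, min_bg_dist, rng):
        patches.append(block_mip_patch(stack, c, k))
        labels.append(0)
    return LabeledPatchSet(patches, np.array(labels), DETECTION_CLASSES)


def build_type_training_set(stack: ImageStack, tree: NeuronTree, k: int = 61,
                            min_bg_dist: float = 10.0, seed: int = 0) -> LabeledPatchSet:
    """Three-class (background / axon / dendrite) patch set.

    Axon patches come from type-2 nodes, dendrite patches from types 3–4;
    background patches are sampled as in the detection set, one per
    neurite patch (balanced background).
    """
    stack = normalize_polarity(stack)
    rng = np.random.default_rng(seed)
    axon = [n for n in tree.nodes if n.type_code == 2]
    dend = [n for n in tree.nodes if n.type_code in (3, 4)]
    missing = [name for name, group in (("axon", axon), ("dendrite", dend)) if not group]
    if missing:
        raise ValueError(f"no nodes for class(es): {', '.join(missing)}")
    patches, labels = [], []
    for n in axon:
        patches.append(block_mip_patch(stack, (n.x, n.y, n.z), k))
        labels.append(1)
    for n in dend:
        patches.append(block_mip_patch(stack, (n.x, n.y, n.z), k))
        labels.append(2)
    n_bg = len(axon) + len(dend)
    for c in _sample_background_centers(stack, tree, n_bg, min_bg_dist, rng):
        patches.append(block_mip_patch(stack, c, k))
        labels.append(0)
    return LabeledPatchSet(patches, np.array(labels), TYPE_CLASSES)


def augment_rotations(pset: LabeledPatchSet) -> LabeledPatchSet:
    """Expand a patch set with the four 90° rotations of every patch.

    Neurite orientation within a patch is arbitrary, so rotations are
    label-preserving; the extra views stabilize texture-based
    distinctions (beaded axon vs continuous dendrite) against the
    orientation sampling of a small corpus.
    """
    patches, labels = [], []
    for p, lab in zip(pset.patches, pset.labels):
        for rot in range(4):
            patches.append(Patch(np.rot90(p.pixels, rot).copy(), p.center, p.size))
            labels.append(lab)
    return LabeledPatchSet(patches, np.array(labels), pset.class_names)


def merge_sets(sets: list[LabeledPatchSet]) -> LabeledPatchSet:
    if not sets:
        raise ValueError("no sets to merge")
    names = sets[0].class_names
    for s in sets:
        if s.class_names != names:
            raise ValueError("cannot merge sets with different classes")
    patches = [p for s in sets for p in s.patches]
    labels = np.concatenate([s.labels for s in sets])
    return LabeledPatchSet(patches, labels, names)


def train(pset: LabeledPatchSet, config: TrainConfig | None = None,
          seed: int = 0) -> CNNClassifier:
    """Train the reference CNN on a labeled patch set.

    Seeded end to end; an internal held-out split provides
    ``val_accuracy``. Raises on single-class input.
    """
    config = config or TrainConfig()
    classes = np.unique(pset.labels)
    if len(classes) < 2:
        raise ValueError("training requires at least 2 classes present")
    k = pset.patches[0].size
    X = pset.as_array()
    y = pset.labels
    rng = np.random.default_rng(seed)
    net = nn.build_cnn(k, len(pset.class_names), rng,
                       channels=config.channels, hidden=config.hidden)

    order = rng.permutation(len(X))
    n_val = max(1, int(round(config.val_frac * len(X)))) if len(X) > 4 else 0
    val_idx, tr_idx = order[:n_val], order[n_val:]
    if len(np.unique(y[tr_idx])) < 2:  # tiny degenerate splits: train on all
        tr_idx = order
    opt = nn.Adam(net.params(), lr=config.lr)
    for _ in range(config.epochs):
        perm = rng.permutation(len(tr_idx))
        for i in range(0, len(perm), config.batch_size):
            idx = tr_idx[perm[i : i + config.batch_size]]
            logits = net.forward(X[idx])
            _, g = nn.cross_entropy_grad(logits, y[idx])
            net.backward(g)
            opt.step(net.grads())

    val_acc = None
    if n_val:
        pred = net.predict_batched(X[val_idx]).argmax(axis=1)
        val_acc = float((pred == y[val_idx]).mean())
    return CNNClassifier(net, k, pset.class_names, seed, val_accuracy=val_acc,
                         meta={"epochs": config.epochs, "lr": config.lr,
                               "batch_size": config.batch_size,
                               "channels": list(config.channels),
                               "hidden": config.hidden})


def save_model(model: CNNClassifier, path) -> None:
    """Serialize to a single pickled-dict ``.npy`` plus a JSON sidecar."""
    state = {
        "kind": "classifier",
        "patch_size": model.patch_size,
        "class_names": list(model.class_names),
        "seed": model.seed,
        "val_accuracy": model.val_accuracy,
        "meta": model.meta,
        "params": model.net.get_state(),
    }
    with open(path, "wb") as fh:  # file handle: np.save must not append .npy
        np.save(fh, np.array(state, dtype=object), allow_pickle=True)
    sidecar = {k: v for k, v in state.items() if k != "params"}
    with open(str(path) + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_model(path) -> CNNClassifier:
    state = np.load(path, allow_pickle=True).item()
    if state.get("kind") != "classifier":
        raise ValueError(f"{path} is not a classifier model file")
    meta = state["meta"]
    rng = np.random.default_rng(0)  # shapes only; weights overwritten below
    net = nn.build_cnn(state["patch_size"], len(state["class_names"]), rng,
                       channels=tuple(meta.get("channels", (8, 16))),
                       hidden=meta.get("hidden", 32))
    net.set_state(state["params"])
    return CNNClassifier(net, state["patch_size"], tuple(state["class_names"]),
                         state["seed"], val_accuracy=state["val_accuracy"],
                         meta=meta)
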