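"""Neurite connection: contrastive patch embeddings and the DMST.

Detected signals are linked into trees by a minimum spanning forest over
a k-nearest-neighbor graph whose edge weight is the Euclidean distance
between two detections multiplied by a learned dissimilarity of their
local appearance. The dissimilarity is the Euclidean distance between
length-M embeddings (M = 200 by default) produced by a Siamese network —
two identical convolutional arms with shared parameters trained with a
contrastive loss on pairs of patches from consecutive (positive) versus
spatially separated (negative) annotation nodes. With unit dissimilarity
the construction reduces to the classical distance-weighted Euclidean
MST baseline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from . import nn
from .detection import DetectedSignal
from .imaging import ImageStack, Patch, block_mip_patch, normalize_polarity
from .morphology import NeuronNode, NeuronTree
from .patch_classifier import patches_to_array

__all__ = ["PairSet", "SiameseModel", "SiameseConfig", "UnitDissimilarity",
           "CallableDissimilarity", "build_pair_training_set", "train_siamese",
           "dissimilarity", "build_dmst", "save_siamese", "load_siamese",
           "minimum_spanning_forest"]


@dataclass
class PairSet:
    patches_a: list[Patch]
    patches_b: list[Patch]
    labels: np.ndarray  # 1 = positive (connected), 0 = negative

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        if not (len(self.patches_a) == len(self.patches_b) == len(self.labels)):
            raise ValueError("pair set components must have equal length")

    def __len__(self):
        return len(self.labels)


@dataclass
class SiameseConfig:
    m: int = 200  # embedding width
    margin: float = 1.0
    epochs: int = 10
    batch_size: int = 64
    lr: float = 1e-3
    val_frac: float = 0.2
    channels: tuple[int, ...] = (8, 16)
    hidden: int = 64


class SiameseModel:
    """One shared embedding arm; dissimilarity = L2 between embeddings."""

    def __init__(self, net: nn.Network, patch_size: int, m: int, margin: float,
                 seed: int, val_stats: dict | None = None, meta: dict | None = None):
        self.net = net
        self.patch_size = patch_size
        self.m = m
        self.margin = margin
        self.seed = seed
        self.val_stats = dict(val_stats or {})
        self.meta = dict(meta or {})

    def embed(self, patches: list[Patch]) -> np.ndarray:
        for p in patches:
            if p.size != self.patch_size:
                raise ValueError(
                    f"patch size {p.size} does not match model k={self.patch_size}"
                )
        if not patches:
            return np.zeros((0, self.m))
        return self.net.predict_batched(patches_to_array(patches))

    def dissimilarity(self, p: Patch, q: Patch) -> float:
        e = self.embed([p, q])
        return float(np.linalg.norm(e[0] - e[1]))


class UnitDissimilarity:
    """Stub: dissimilarity 1 everywhere — reduces the DMST to the
    classical Euclidean MST baseline."""

    def dissimilarity(self, p: Patch, q: Patch) -> float:
        return 1.0


class CallableDissimilarity:
    """Stub wrapping an arbitrary function of the two patches."""

    def __init__(self, fn):
        self.fn = fn

    def dissimilarity(self, p: Patch, q: Patch) -> float:
        return float(self.fn(p, q))


def dissimilarity(model, p: Patch, q: Patch) -> float:
    """Euclidean distance between the two patches' embeddings (or the
    stub's notion thereof); symmetric, zero for identical patches."""
    return model.dissimilarity(p, q)


def build_pair_training_set(stack: ImageStack, tree: NeuronTree, k: int = 61,
                            neg_min_separation: float = 40.0,
                            seed: int = 0) -> PairSet:
    """Positives: block-MIP patches of every (child, parent) node pair.
    Negatives: an equal number of node pairs separated by at least
    ``neg_min_separation`` voxels, sampled with the seed."""
    stack = normalize_polarity(stack)
    rng = np.random.default_rng(seed)
    index = tree._index()
    pos_pairs = [(n.id, n.parent) for n in tree.nodes if n.parent != -1]
    if not pos_pairs:
        raise ValueError("no connected node pair in the reconstruction")
    pos = tree.positions()
    ids = tree.node_ids
    n_neg = len(pos_pairs)
    neg_pairs: list[tuple[int, int]] = []
    attempts = 0
    max_attempts = 1000 * n_neg
    while len(neg_pairs) < n_neg:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"could not sample node pairs separated by >= "
                f"{neg_min_separation} voxels (tree too compact)"
            )
        m = min(4 * (n_neg - len(neg_pairs)) + 16, 4096)
        attempts += m
        ii = rng.integers(0, len(ids), m)
        jj = rng.integers(0, len(ids), m)
        d = np.linalg.norm(pos[ii] - pos[jj], axis=1)
        for a, b in zip(ii[d >= neg_min_separation], jj[d >= neg_min_separation]):
            neg_pairs.append((ids[int(a)], ids[int(b)]))
            if len(neg_pairs) == n_neg:
                break

    def patch_of(nid):
        n = index[nid]
        return block_mip_patch(stack, (n.x, n.y, n.z), k)

    pa = [patch_of(a) for a, _ in pos_pairs] + [patch_of(a) for a, _ in neg_pairs]
    pb = [patch_of(b) for _, b in pos_pairs] + [patch_of(b) for _, b in neg_pairs]
    labels = np.array([1] * len(pos_pairs) + [0] * len(neg_pairs))
    return PairSet(pa, pb, labels)


def merge_pair_sets(sets: list[PairSet]) -> PairSet:
    return PairSet(
        [p for s in sets for p in s.patches_a],
        [p for s in sets for p in s.patches_b],
        np.concatenate([s.labels for s in sets]),
    )


def _contrastive_grad(ea: np.ndarray, eb: np.ndarray, y: np.ndarray, margin: float):
    """Contrastive loss L = y d² + (1−y) max(0, margin − d)² and its
    gradients w.r.t. the two embeddings (mean over the batch)."""
    diff = ea - eb
    d = np.linalg.norm(diff, axis=1)
    hinge = np.maximum(0.0, margin - d)
    loss = float((y * d**2 + (1 - y) * hinge**2).mean())
    n = len(y)
    safe_d = np.where(d > 1e-12, d, 1.0)
    coef = 2.0 * y - 2.0 * (1 - y) * hinge / safe_d
    ga = (coef[:, None] * diff) / n
    return loss, ga, -ga


def train_siamese(pairs: PairSet, config: SiameseConfig | None = None,
                  seed: int = 0) -> SiameseModel:
    """Train the shared arm with contrastive loss; ``val_stats`` holds the
    held-out separation (median pos/neg dissimilarity and AUC)."""
    config = config or SiameseConfig()
    if len(np.unique(pairs.labels)) < 2:
        raise ValueError("training requires both positive and negative pairs")
    k = pairs.patches_a[0].size
    Xa = patches_to_array(pairs.patches_a)
    Xb = patches_to_array(pairs.patches_b)
    y = pairs.labels.astype(float)
    rng = np.random.default_rng(seed)
    net = nn.build_cnn(k, config.m, rng, channels=config.channels,
                       hidden=config.hidden)
    order = rng.permutation(len(y))
    n_val = max(1, int(round(config.val_frac * len(y)))) if len(y) > 4 else 0
    val_idx, tr_idx = order[:n_val], order[n_val:]
    if len(np.unique(y[tr_idx])) < 2:
        tr_idx = order
    opt = nn.Adam(net.params(), lr=config.lr)
    for _ in range(config.epochs):
        perm = rng.permutation(len(tr_idx))
        for i in range(0, len(perm), config.batch_size):
            idx = tr_idx[perm[i : i + config.batch_size]]
            b = len(idx)
            # both arms share parameters: run as one concatenated batch so
            # a single backward pass accumulates both gradient paths
            e = net.forward(np.concatenate([Xa[idx], Xb[idx]]))
            _, ga, gb = _contrastive_grad(e[:b], e[b:], y[idx], config.margin)
            net.backward(np.concatenate([ga, gb]))
            opt.step(net.grads())

    val_stats: dict = {}
    if n_val:
        e = net.predict_batched(np.concatenate([Xa[val_idx], Xb[val_idx]]))
        b = len(val_idx)
        d = np.linalg.norm(e[:b] - e[b:], axis=1)
        yv = y[val_idx]
        val_stats["median_pos"] = float(np.median(d[yv == 1])) if (yv == 1).any() else None
        val_stats["median_neg"] = float(np.median(d[yv == 0])) if (yv == 0).any() else None
        if (yv == 1).any() and (yv == 0).any():
            from sklearn.metrics import roc_auc_score

            # dissimilarity is low for positives: AUC of -d predicting y
            val_stats["auc"] = float(roc_auc_score(yv, -d))
    return SiameseModel(net, k, config.m, config.margin, seed,
                        val_stats=val_stats,
                        meta={"epochs": config.epochs, "lr": config.lr,
                              "batch_size": config.batch_size,
                              "channels": list(config.channels),
                              "hidden": config.hidden})


class _DSU:
    def __init__(self, n):
        self.p = list(range(n))

    def find(self, a):
        while self.p[a] != a:
            self.p[a] = self.p[self.p[a]]
            a = self.p[a]
        return a

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.p[rb] = ra
        return True


def minimum_spanning_forest(n: int, edges: list[tuple[float, int, int]]):
    """Kruskal with deterministic tie-breaking by (weight, min, max).

    ``edges`` are (weight, i, j); returns the chosen (i, j) pairs.
    """
    dsu = _DSU(n)
    chosen = []
    for w, i, j in sorted(edges, key=lambda e: (e[0], min(e[1], e[2]), max(e[1], e[2]))):
        if dsu.union(i, j):
            chosen.append((i, j))
    return chosen


def build_dmst(signals: list[DetectedSignal], stack: ImageStack | None = None,
               model=None, knn: int = 6, max_edge_len: float = 100.0,
               k: int | None = None, complete: bool = False,
               units: str = "voxel") -> NeuronTree:
    """Link detections into a spanning forest with weight
    distance × dissimilarity.

    The candidate graph is the union of each signal's ``knn`` nearest
    neighbors, keeping edges no longer than ``max_edge_len`` (or the
    complete graph when ``complete``). ``model`` provides per-pair
    dissimilarities from the detections' block-MIP patches; ``None``
    means unit dissimilarity (pure-distance MST). One root per connected
    component: the lowest signal index.
    """
    if not signals:
        return NeuronTree([], name="dmst")
    if units not in ("voxel", "um"):
        raise ValueError("units must be 'voxel' or 'um'")
    pts = np.array([[s.x, s.y, s.z] for s in signals], dtype=float)
    metric_pts = pts.copy()
    if units == "um":
        if stack is None:
            raise ValueError("physical units require the stack's voxel size")
        metric_pts *= np.asarray(stack.voxel_size, dtype=float)

    n = len(signals)
    pair_set: set[tuple[int, int]] = set()
    if complete or n <= knn + 1:
        pair_set = {(i, j) for i in range(n) for j in range(i + 1, n)}
    else:
        kdt = cKDTree(metric_pts)
        _, idx = kdt.query(metric_pts, k=min(knn + 1, n))
        for i in range(n):
            for j in idx[i]:
                j = int(j)
                if j != i:
                    pair_set.add((min(i, j), max(i, j)))
    dists = {
        (i, j): float(np.linalg.norm(metric_pts[i] - metric_pts[j]))
        for i, j in pair_set
    }
    if not complete:
        dists = {e: d for e, d in dists.items() if d <= max_edge_len}

    patches: list[Patch | None] = [None] * n
    embeddings = None
    if model is not None and stack is not None:
        nstack = normalize_polarity(stack)
        kk = k or getattr(model, "patch_size", None)
        if kk is None:
            raise ValueError("patch size k required for this model")
        patches = [block_mip_patch(nstack, (s.x, s.y, s.z), kk) for s in signals]
        if hasattr(model, "embed"):
            embeddings = model.embed(patches)

    edges = []
    for (i, j), d in dists.items():
        if model is None:
            dis = 1.0
        elif embeddings is not None:
            dis = float(np.linalg.norm(embeddings[i] - embeddings[j]))
        else:
            dis = model.dissimilarity(patches[i], patches[j])
        edges.append((d * dis, i, j))

    chosen = minimum_spanning_forest(n, edges)
    adj: dict[int, list[int]] = {i: [] for i in range(n)}
    for i, j in chosen:
        adj[i].append(j)
        adj[j].append(i)

    parent = [-2] * n  # -2 unassigned, -1 root
    order: list[int] = []
    for root in range(n):
        if parent[root] != -2:
            continue
        parent[root] = -1
        queue = [root]
        while queue:
            cur = queue.pop(0)
            order.append(cur)
            for nb in sorted(adj[cur]):
                if parent[nb] == -2:
                    parent[nb] = cur
                    queue.append(nb)

    id_of = {sig_idx: rank + 1 for rank, sig_idx in enumerate(order)}
    nodes = [
        NeuronNode(id_of[i], 0, signals[i].x, signals[i].y, signals[i].z, 1.0,
                   -1 if parent[i] == -1 else id_of[parent[i]])
        for i in order
    ]
    tree = NeuronTree(nodes, name="dmst")
    tree.validate()
    return tree


def save_siamese(model: SiameseModel, path) -> None:
    state = {
        "kind": "siamese",
        "patch_size": model.patch_size,
        "m": model.m,
        "margin": model.margin,
        "seed": model.seed,
        "val_stats": model.val_stats,
        "meta": model.meta,
        "params": model.net.get_state(),
    }
    with open(path, "wb") as fh:
        np.save(fh, np.array(state, dtype=object), allow_pickle=True)
    sidecar = {k: v for k, v in state.items() if k != "params"}
    with open(str(path) + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_siamese(path) -> SiameseModel:
    state = np.load(path, allow_pickle=True).item()
    if state.get("kind") != "siamese":
        raise ValueError(f"{path} is not a siamese model file")
    meta = state["meta"]
    rng = np.random.default_rng(0)
    net = nn.build_cnn(state["patch_size"], state["m"], rng,
                       channels=tuple(meta.get("channels", (8, 16))),
                       hidden=meta.get("hidden", 64))
    net.set_state(state["params"])
    return SiameseModel(net, state["patch_size"], state["m"], state["margin"],
                        state["seed"], val_stats=state["val_stats"], meta=meta)
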