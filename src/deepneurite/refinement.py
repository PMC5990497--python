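"""Smart pruning of over-traced reconstructions and consensus fusion.

Automated tracers run with a permissive foreground threshold over-trace:
they emit spurious segments in background. Here every node of an input
reconstruction is scored by a trained foreground/background classifier
on its local block-MIP patch, and whole segments are removed when too
few of their nodes look like signal. Multiple (pruned) reconstructions
of the same stack can then be fused into a consensus by spatial voting
followed by MST re-linking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .connection import build_dmst
from .detection import DetectedSignal
from .imaging import ImageStack, block_mip_patch, normalize_polarity
from .morphology import NeuronTree, decompose_segments
from .patch_classifier import PatchClassifier

__all__ = ["PruneReport", "prune", "consensus"]


@dataclass
class PruneReport:
    kept_nodes: int
    removed_nodes: int
    removed_segment_ids: list[int]  # indices into decompose_segments(tree)
    node_scores: dict[int, float]  # node id -> foreground probability


def _score_nodes(tree: NeuronTree, stack: ImageStack, model: PatchClassifier,
                 k: int | None) -> dict[int, float]:
    k = k or model.patch_size
    fg = 1
    names = [c.lower() for c in model.class_names]
    if "foreground" in names:
        fg = names.index("foreground")
    stack = normalize_polarity(stack)
    patches = [block_mip_patch(stack, (n.x, n.y, n.z), k) for n in tree.nodes]
    proba = model.predict_proba(patches)
    return {n.id: float(p[fg]) for n, p in zip(tree.nodes, proba)}


def prune(tree: NeuronTree, stack: ImageStack, model: PatchClassifier,
          k: int | None = None, threshold: float = 0.5,
          seg_keep_frac: float = 0.5) -> tuple[NeuronTree, PruneReport]:
    """Remove segments whose fraction of foreground-classified nodes is
    below ``seg_keep_frac``; surviving children of removed segments are
    re-rooted. Segment-level removal keeps isolated misclassified nodes
    from fragmenting true neurites."""
    if model.n_classes != 2:
        raise ValueError("pruning requires a binary model")
    scores = _score_nodes(tree, stack, model, k)
    segments = decompose_segments(tree)
    keep_ids: set[int] = set()
    removed_segments: list[int] = []
    for si, seg in enumerate(segments):
        frac = np.mean([scores[i] >= threshold for i in seg.node_ids])
        if frac >= seg_keep_frac:
            keep_ids.update(seg.node_ids)
        else:
            removed_segments.append(si)
    pruned = tree.subtree_nodes(keep_ids)
    report = PruneReport(
        kept_nodes=len(keep_ids),
        removed_nodes=len(tree) - len(keep_ids),
        removed_segment_ids=removed_segments,
        node_scores=scores,
    )
    return pruned, report


def consensus(trees: list[NeuronTree], stack: ImageStack, model: PatchClassifier,
              support_radius: float = 3.0, min_support: int | None = None,
              k: int | None = None, threshold: float = 0.5,
              seg_keep_frac: float = 0.5, link_model=None,
              max_edge_len: float = 100.0) -> NeuronTree:
    """Fuse ≥ 2 reconstructions of one stack.

    Each input is pruned, then every node is matched to the nearest node
    of each other reconstruction within ``support_radius``. A node is
    kept when it and its matches come from at least ``min_support``
    distinct inputs (default ⌈n/2⌉); its position becomes the centroid
    of the matched set (cross-reconstruction averaging). Kept positions
    are then deduplicated at sub-node-spacing radius and re-linked by
    the spanning-forest construction (pure-distance MST unless a Siamese
    ``link_model`` is given). Deterministic and invariant to input order.
    """
    if len(trees) < 2:
        raise ValueError("consensus requires at least 2 reconstructions")
    if min_support is None:
        min_support = int(np.ceil(len(trees) / 2))
    pruned_pos = []
    for t in trees:
        p, _ = prune(t, stack, model, k, threshold, seg_keep_frac)
        pruned_pos.append(p.positions())
    kdts = [cKDTree(p) if len(p) else None for p in pruned_pos]

    averaged = []
    for ti, pos in enumerate(pruned_pos):
        for x in pos:
            members = [x]
            support = 1
            for ui, kdt in enumerate(kdts):
                if ui == ti or kdt is None:
                    continue
                d, j = kdt.query(x)
                if d <= support_radius:
                    support += 1
                    members.append(pruned_pos[ui][j])
            if support >= min_support:
                averaged.append(np.mean(members, axis=0))
    if not averaged:
        return NeuronTree([], name="consensus")
    averaged = np.array(averaged)
    order = np.lexsort((averaged[:, 2], averaged[:, 1], averaged[:, 0]))
    averaged = averaged[order]

    # dedup: leader clustering in lexicographic order, radius below the
    # unit node spacing so a neurite never chains into one cluster
    dedup_radius = 0.5
    kdt = cKDTree(averaged)
    taken = np.zeros(len(averaged), dtype=bool)
    centroids = []
    for i in range(len(averaged)):
        if taken[i]:
            continue
        members = [j for j in kdt.query_ball_point(averaged[i], dedup_radius)
                   if not taken[j]]
        for j in members:
            taken[j] = True
        centroids.append(averaged[members].mean(axis=0))
    centroids = np.array(centroids)
    order = np.lexsort((centroids[:, 2], centroids[:, 1], centroids[:, 0]))
    signals = [DetectedSignal(float(c[0]), float(c[1]), float(c[2]), 1.0, "final3d")
               for c in centroids[order]]
    out = build_dmst(signals, stack, model=link_model, k=k,
                     max_edge_len=max_edge_len)
    out.name = "consensus"
    return out
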