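"""Consistency scoring of manual reconstructions.

A classifier trained on other annotators' data labels every node of a
manual reconstruction foreground or background; foreground runs form an
initial prediction, short gaps between collinear fragments are
reinstated (tips closer than 30 voxels whose orientations continue each
other within 30 degrees — both strict), and the consistency score is

    c = (nodes in the refined prediction) / (nodes in the manual
        reconstruction) x 100%

reported overall and per neurite type (axon = type 2, dendrite =
types 3-4). Because gap reinstatement only relabels existing manual
nodes, c is a retention fraction bounded by 100%.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .imaging import ImageStack, block_mip_patch, normalize_polarity
from .morphology import NeuronTree, decompose_segments, segment_orientation
from .patch_classifier import (PatchClassifier, TrainConfig,
                               build_detection_training_set, merge_sets, train)

__all__ = ["ConsistencyReport", "classify_nodes", "connect_gaps",
           "consistency_score", "cross_validated_consistency"]

FOREGROUND = "foreground"
BACKGROUND = "background"


@dataclass
class ConsistencyReport:
    c_overall: float
    c_axon: float | None
    c_dendrite: float | None
    n_manual: int
    n_initial: int
    n_refined: int
    connected_gap_count: int
    labels: dict[int, str] = field(default_factory=dict, repr=False)

    def as_dict(self) -> dict:
        return {"c_overall": self.c_overall, "c_axon": self.c_axon,
                "c_dendrite": self.c_dendrite, "n_manual": self.n_manual,
                "n_initial": self.n_initial, "n_refined": self.n_refined,
                "connected_gap_count": self.connected_gap_count}


def classify_nodes(tree: NeuronTree, stack: ImageStack, model: PatchClassifier,
                   k: int | None = None, threshold: float = 0.5
                   ) -> tuple[dict[int, str], dict[int, float]]:
    """Label every node foreground/background from its block-MIP patch.

    Returns (labels, foreground scores), both keyed by node id.
    """
    if model.n_classes != 2:
        raise ValueError("node classification requires a binary model")
    names = [c.lower() for c in model.class_names]
    fg = names.index("foreground") if "foreground" in names else 1
    stack = normalize_polarity(stack)
    k = k or model.patch_size
    patches = [block_mip_patch(stack, (n.x, n.y, n.z), k) for n in tree.nodes]
    proba = model.predict_proba(patches)
    labels = {}
    scores = {}
    for n, p in zip(tree.nodes, proba):
        scores[n.id] = float(p[fg])
        labels[n.id] = FOREGROUND if p[fg] >= threshold else BACKGROUND
    return labels, scores


def _fragments(tree: NeuronTree, labels: dict[int, str]):
    """Foreground runs within each segment, as ordered node-id lists."""
    frags = []
    for seg in decompose_segments(tree):
        run: list[int] = []
        for nid in seg.node_ids:
            if labels[nid] == FOREGROUND:
                run.append(nid)
            elif run:
                frags.append(run)
                run = []
        if run:
            frags.append(run)
    return frags


def connect_gaps(tree: NeuronTree, labels: dict[int, str],
                 angle_max: float = 30.0, dist_max: float = 30.0,
                 depth: int = 5) -> tuple[dict[int, str], int]:
    """Reinstate background nodes between collinear foreground fragments.

    Candidate pairs are fragment tips, taken nearest-first with each tip
    used at most once; a pair connects when the tip distance is smaller
    than ``dist_max`` voxels and the tips' outward orientations continue
    each other within ``angle_max`` degrees (angle between one vector and
    the negation of the other) — both inequalities strict. The
    background-labeled manual nodes on the tree path between the two
    tips are relabeled foreground; no nodes are created.

    Returns (refined labels, number of gaps connected).
    """
    labels = dict(labels)
    if angle_max <= 0 or dist_max <= 0:
        return labels, 0
    index = tree._index()
    frags = [f for f in _fragments(tree, labels) if len(f) >= 2]
    if len(frags) < 2:
        return labels, 0

    tips = []  # (frag_idx, node_id, orientation)
    for fi, f in enumerate(frags):
        pts = np.array([[index[i].x, index[i].y, index[i].z] for i in f])
        tips.append((fi, f[0], segment_orientation(pts, at_end=False, depth=depth)))
        tips.append((fi, f[-1], segment_orientation(pts, at_end=True, depth=depth)))

    g = nx.Graph()
    g.add_nodes_from(index)
    for n in tree.nodes:
        if n.parent != -1:
            g.add_edge(n.id, n.parent)

    candidates = []
    for a in range(len(tips)):
        for b in range(a + 1, len(tips)):
            fa, na, va = tips[a]
            fb, nb, vb = tips[b]
            if fa == fb:
                continue
            pa = index[na].position
            pb = index[nb].position
            d = float(np.linalg.norm(pa - pb))
            if d >= dist_max or d == 0.0:
                continue
            cosang = float(np.clip(np.dot(va, -vb), -1.0, 1.0))
            ang = np.degrees(np.arccos(cosang))
            # strict "< angle_max" with a guard for arccos round-off so a
            # geometrically exact boundary angle is excluded
            if ang >= angle_max - 1e-9:
                continue
            # tips must face each other: each outward orientation points
            # toward the other tip, else the "gap" spans a whole fragment
            chord = (pb - pa) / d
            if np.dot(va, chord) <= 0.0 or np.dot(vb, -chord) <= 0.0:
                continue
            candidates.append((d, a, b, na, nb))

    used: set[int] = set()
    n_connected = 0
    for d, a, b, na, nb in sorted(candidates):
        if a in used or b in used:
            continue
        try:
            path = nx.shortest_path(g, na, nb)
        except nx.NetworkXNoPath:
            continue
        used.update((a, b))
        n_connected += 1
        for nid in path[1:-1]:
            if labels[nid] == BACKGROUND:
                labels[nid] = FOREGROUND
    return labels, n_connected


def _retention(nodes, labels) -> float | None:
    ids = [n.id for n in nodes]
    if not ids:
        return None
    return 100.0 * float(np.mean([labels[i] == FOREGROUND for i in ids]))


def consistency_score(manual: NeuronTree, refined_labels: dict[int, str],
                      initial_labels: dict[int, str] | None = None,
                      connected_gap_count: int = 0) -> ConsistencyReport:
    """Consistency score c = refined foreground / manual nodes × 100%,
    overall and per type (axon = 2, dendrite = 3–4)."""
    if len(manual) == 0:
        raise ValueError("consistency score undefined for an empty reconstruction")
    missing = [n.id for n in manual.nodes if n.id not in refined_labels]
    if missing:
        raise ValueError(f"labels missing for nodes: {missing[:5]}...")
    n_manual = len(manual)
    n_refined = sum(refined_labels[n.id] == FOREGROUND for n in manual.nodes)
    n_initial = (
        sum(initial_labels[n.id] == FOREGROUND for n in manual.nodes)
        if initial_labels is not None
        else n_refined
    )
    return ConsistencyReport(
        c_overall=100.0 * n_refined / n_manual,
        c_axon=_retention([n for n in manual.nodes if n.type_code == 2],
                          refined_labels),
        c_dendrite=_retention([n for n in manual.nodes if n.type_code in (3, 4)],
                              refined_labels),
        n_manual=n_manual,
        n_initial=n_initial,
        n_refined=n_refined,
        connected_gap_count=connected_gap_count,
        labels=dict(refined_labels),
    )


def evaluate_reconstruction(tree: NeuronTree, stack: ImageStack,
                            model: PatchClassifier, k: int | None = None,
                            threshold: float = 0.5, angle_max: float = 30.0,
                            dist_max: float = 30.0) -> ConsistencyReport:
    """classify → connect gaps → score, for one (stack, tree) pair."""
    initial, _ = classify_nodes(tree, stack, model, k, threshold)
    refined, n_gaps = connect_gaps(tree, initial, angle_max, dist_max)
    return consistency_score(tree, refined, initial_labels=initial,
                             connected_gap_count=n_gaps)


def cross_validated_consistency(datasets, n_folds: int = 5,
                                train_config: TrainConfig | None = None,
                                seed: int = 0, k: int = 61,
                                threshold: float = 0.5,
                                angle_max: float = 30.0, dist_max: float = 30.0,
                                neg_ratio: float = 1.0,
                                min_bg_dist: float = 10.0) -> list[dict]:
    """k-fold consistency evaluation over a list of (stack, tree) pairs.

    Folds are contiguous equal-size blocks of the dataset order. For each
    fold, a detector is trained on all other folds' patch sets and every
    held-out reconstruction is scored.
    """
    if n_folds < 2:
        raise ValueError("need n_folds >= 2")
    if len(datasets) < n_folds:
        raise ValueError("fewer datasets than folds")
    idx = np.arange(len(datasets))
    folds = np.array_split(idx, n_folds)
    results = []
    for fi, hold in enumerate(folds):
        hold_set = set(int(i) for i in hold)
        train_sets = [
            build_detection_training_set(stack, tree, k=k, neg_ratio=neg_ratio,
                                         min_bg_dist=min_bg_dist,
                                         seed=seed * 1009 + di)
            for di, (stack, tree) in enumerate(datasets)
            if di not in hold_set
        ]
        model = train(merge_sets(train_sets), train_config, seed=seed + fi)
        reports = [
            evaluate_reconstruction(datasets[i][1], datasets[i][0], model, k,
                                    threshold, angle_max, dist_max)
            for i in sorted(hold_set)
        ]
        results.append({
            "fold": fi,
            "held_out": sorted(hold_set),
            "reports": reports,
            "mean_c": float(np.mean([r.c_overall for r in reports])),
            "val_accuracy": model.val_accuracy,
        })
    return results
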