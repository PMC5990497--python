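"""Axon/dendrite typing of annotated segments.

Dendrites present continuous tube-like signal, axons punctate beaded
signal; a three-class (background/axon/dendrite) patch classifier scores
every node of a segment on its block-MIP patch, and the segment label is
the majority vote over nodes whose argmax is not background (all
background → unknown). Ties between axon and dendrite resolve to axon
(the lower SWC type code).
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .imaging import ImageStack, block_mip_patch, normalize_polarity
from .morphology import NeuronTree, decompose_segments
from .patch_classifier import PatchClassifier

__all__ = ["classify_segment", "annotate_tree_types"]

AXON = "axon"
DENDRITE = "dendrite"
UNKNOWN = "unknown"


def _class_indices(model: PatchClassifier):
    names = [c.lower() for c in model.class_names]
    try:
        return names.index("background"), names.index("axon"), names.index("dendrite")
    except ValueError:
        return 0, 1, 2


def classify_segment(segment_nodes, stack: ImageStack, model3: PatchClassifier,
                     k: int | None = None) -> tuple[str, np.ndarray]:
    """Label an ordered run of 3D points axon/dendrite/unknown.

    Returns (label, per-node posteriors of shape (n, 3)).
    """
    if model3.n_classes != 3:
        raise ValueError("segment typing requires a 3-class model")
    pts = np.atleast_2d(np.asarray(segment_nodes, dtype=float))
    if pts.shape[0] < 1:
        raise ValueError("segment must contain at least one node")
    k = k or model3.patch_size
    stack = normalize_polarity(stack)
    patches = [block_mip_patch(stack, tuple(p[:3]), k) for p in pts]
    proba = model3.predict_proba(patches)
    bg_i, ax_i, de_i = _class_indices(model3)
    votes = proba.argmax(axis=1)
    n_axon = int((votes == ax_i).sum())
    n_dend = int((votes == de_i).sum())
    if n_axon == 0 and n_dend == 0:
        return UNKNOWN, proba
    return (AXON if n_axon >= n_dend else DENDRITE), proba


def annotate_tree_types(tree: NeuronTree, stack: ImageStack,
                        model3: PatchClassifier, k: int | None = None) -> NeuronTree:
    """Assign SWC type codes per segment: axon → 2, dendrite → 3,
    unknown → 0; soma nodes (type 1) are untouched."""
    index = tree._index()
    new_type: dict[int, int] = {}
    for seg in decompose_segments(tree):
        nodes = [index[i] for i in seg.node_ids]
        if nodes[0].type_code == 1:  # soma segment: leave as is
            continue
        pts = [(n.x, n.y, n.z) for n in nodes]
        label, _ = classify_segment(pts, stack, model3, k)
        code = {AXON: 2, DENDRITE: 3, UNKNOWN: 0}[label]
        for n in nodes:
            new_type[n.id] = code
    out = NeuronTree(
        [replace(n, type_code=new_type.get(n.id, n.type_code)) for n in tree.nodes],
        name=tree.name,
        comments=list(tree.comments),
    )
    out.validate()
    return out
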