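"""Neurite signal detection in 3D stacks via 2D MIP patch classification.

The pipeline classifies sliding-window patches on the XY maximum-intensity
projection, refines detected positions by mean shift toward local
intensity mass, maps each 2D detection to 3D by the local intensity
maximum along the Z column, and re-classifies the mapped points on their
local 3D block MIPs to discard projection artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.ndimage import correlate1d

from .imaging import (ImageStack, block_mip_patch, image_patch, mip_xy,
                      normalize_polarity, sliding_centers)
from .morphology import NeuronNode, NeuronTree
from .patch_classifier import PatchClassifier

__all__ = ["DetectedSignal", "DetectionParams", "detect_2d", "mean_shift_refine",
           "map_to_3d", "refine_3d", "detect", "signals_to_frame",
           "signals_to_swc", "detection_f1"]

STAGE_2D = "2d"
STAGE_REFINED = "refined2d"
STAGE_MAPPED = "mapped3d"
STAGE_FINAL = "final3d"


@dataclass(frozen=True)
class DetectedSignal:
    x: float
    y: float
    z: float
    score: float
    stage: str


@dataclass
class DetectionParams:
    stride: int = 4
    threshold: float = 0.5  # 2D stage foreground probability cut
    threshold_3d: float = 0.5
    bandwidth: float = 15.0  # mean-shift flat-disk radius, px
    tol: float = 0.5
    max_iter: int = 50


def _foreground_index(model: PatchClassifier) -> int:
    if model.n_classes != 2:
        raise ValueError("detection requires a binary model")
    names = [c.lower() for c in model.class_names]
    return names.index("foreground") if "foreground" in names else 1


def detect_2d(mip: np.ndarray, model: PatchClassifier, stride: int = 4,
              k: int | None = None, threshold: float = 0.5) -> list[DetectedSignal]:
    """Classify sliding-window patches of the MIP; keep grid centers whose
    foreground probability reaches the threshold."""
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must be in (0, 1)")
    k = k or model.patch_size
    fg = _foreground_index(model)
    centers = sliding_centers(mip.shape, stride, k)
    patches = [image_patch(mip, c, k) for c in centers]
    proba = model.predict_proba(patches)
    return [
        DetectedSignal(float(c[0]), float(c[1]), 0.0, float(p[fg]), STAGE_2D)
        for c, p in zip(centers, proba)
        if p[fg] >= threshold
    ]


def mean_shift_refine(signals: list[DetectedSignal], image: np.ndarray,
                      bandwidth: float = 15.0, max_iter: int = 50,
                      tol: float = 0.5) -> list[DetectedSignal]:
    """Shift each detection to the intensity-weighted centroid of the flat
    disk of radius ``bandwidth`` around it, iterating to convergence;
    detections converging within ``bandwidth/2`` of each other are merged,
    keeping the highest score.

    Weights are background-subtracted intensities (image median, clipped
    at zero): with a raw additive offset the centroid of any window is
    just its geometric center and the shift would stall."""
    if bandwidth <= 0:
        raise ValueError("bandwidth must be > 0")
    H, W = image.shape
    img = np.asarray(image, dtype=float)
    img = np.clip(img - np.median(img), 0.0, None)
    r = int(np.ceil(bandwidth))
    refined = []
    for s in signals:
        x, y = s.x, s.y
        for _ in range(max_iter):
            x0, x1 = max(0, int(np.floor(x - r))), min(W, int(np.ceil(x + r)) + 1)
            y0, y1 = max(0, int(np.floor(y - r))), min(H, int(np.ceil(y + r)) + 1)
            xs = np.arange(x0, x1)
            ys = np.arange(y0, y1)
            yy, xx = np.meshgrid(ys, xs, indexing="ij")
            inside = (xx - x) ** 2 + (yy - y) ** 2 <= bandwidth**2
            w = img[y0:y1, x0:x1] * inside
            tot = w.sum()
            if tot <= 0:
                break  # zero-intensity window: leave in place
            nx = float((w * xx).sum() / tot)
            ny = float((w * yy).sum() / tot)
            shift = np.hypot(nx - x, ny - y)
            x, y = nx, ny
            if shift < tol:
                break
        refined.append(replace(s, x=x, y=y, stage=STAGE_REFINED))

    # merge: greedy suppression, highest score first (ties: lower y then x)
    order = sorted(range(len(refined)),
                   key=lambda i: (-refined[i].score, refined[i].y, refined[i].x))
    merged: list[DetectedSignal] = []
    merge_r2 = (bandwidth / 2.0) ** 2
    for i in order:
        s = refined[i]
        if any((s.x - m.x) ** 2 + (s.y - m.y) ** 2 <= merge_r2 for m in merged):
            continue
        merged.append(s)
    return merged


def map_to_3d(signals: list[DetectedSignal], stack: ImageStack) -> list[DetectedSignal]:
    """Assign z by the argmax of the 3-sample smoothed intensity profile
    along each detection's Z column; ties break toward smaller z.

    The smoothing kernel is the center-weighted [1, 2, 1]/4 tap (edges
    replicated): it suppresses single-voxel noise like a moving mean but
    keeps an isolated bright voxel at its own z instead of spreading it
    into a three-sample plateau whose tie-break would shift it up."""
    stack = normalize_polarity(stack)
    Z, Y, X = stack.voxels.shape
    out = []
    for s in signals:
        cx = min(max(int(np.floor(s.x + 0.5)), 0), X - 1)
        cy = min(max(int(np.floor(s.y + 0.5)), 0), Y - 1)
        profile = stack.voxels[:, cy, cx].astype(float)
        smooth = correlate1d(profile, [0.25, 0.5, 0.25], mode="nearest")
        z = int(np.argmax(smooth))  # argmax: first (smallest z) on ties
        out.append(replace(s, z=float(z), stage=STAGE_MAPPED))
    return out


def refine_3d(signals: list[DetectedSignal], stack: ImageStack,
              model: PatchClassifier, k: int | None = None,
              threshold: float = 0.5) -> list[DetectedSignal]:
    """Re-classify each mapped detection on the MIP of its local 3D block;
    keep those scoring at or above the threshold, with updated scores."""
    k = k or model.patch_size
    fg = _foreground_index(model)
    stack = normalize_polarity(stack)
    if not signals:
        return []
    patches = [block_mip_patch(stack, (s.x, s.y, s.z), k) for s in signals]
    proba = model.predict_proba(patches)
    return [
        replace(s, score=float(p[fg]), stage=STAGE_FINAL)
        for s, p in zip(signals, proba)
        if p[fg] >= threshold
    ]


def detect(stack: ImageStack, model: PatchClassifier,
           params: DetectionParams | None = None,
           return_stages: bool = False):
    """Full detection pipeline: polarity normalization → XY MIP → 2D
    sliding-window classification → mean-shift refinement → Z mapping →
    3D re-classification."""
    params = params or DetectionParams()
    stack = normalize_polarity(stack)
    mip = mip_xy(stack)
    s2d = detect_2d(mip, model, params.stride, model.patch_size, params.threshold)
    ref = mean_shift_refine(s2d, mip, params.bandwidth, params.max_iter, params.tol)
    mapped = map_to_3d(ref, stack)
    final = refine_3d(mapped, stack, model, model.patch_size, params.threshold_3d)
    if return_stages:
        return final, {STAGE_2D: s2d, STAGE_REFINED: ref, STAGE_MAPPED: mapped,
                       STAGE_FINAL: final}
    return final


def signals_to_frame(signals: list[DetectedSignal]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"x": s.x, "y": s.y, "z": s.z, "score": s.score, "stage": s.stage}
         for s in signals],
        columns=["x", "y", "z", "score", "stage"],
    )


def signals_to_swc(signals: list[DetectedSignal]) -> NeuronTree:
    """Detections as an SWC dot cloud (isolated type-0 nodes)."""
    nodes = [NeuronNode(i + 1, 0, s.x, s.y, s.z, 1.0, -1)
             for i, s in enumerate(signals)]
    return NeuronTree(nodes, name="detections")


def detection_f1(signals: list[DetectedSignal], tree: NeuronTree,
                 lit_node_ids: list[int] | None = None,
                 tol: float = 2.0) -> dict:
    """Precision/recall/F1 of detections against a ground-truth centerline.

    Precision counts a detection correct when it lies within ``tol``
    voxels of any centerline node. Recall is measured over the nodes the
    renderer actually lit (``lit_node_ids``; defaults to all nodes): a
    node is recovered when some detection lies within ``tol`` of it.
    """
    from scipy.spatial import cKDTree

    if not signals:
        return {"precision": 0.0, "recall": 0.0, "f1": 0.0,
                "n_detections": 0, "n_lit": len(lit_node_ids or tree.node_ids)}
    pts = np.array([[s.x, s.y, s.z] for s in signals])
    all_pos = tree.positions()
    kdt_nodes = cKDTree(all_pos)
    d_det, _ = kdt_nodes.query(pts)
    precision = float((d_det <= tol).mean())
    lit_ids = lit_node_ids if lit_node_ids is not None else tree.node_ids
    index = tree._index()
    lit_pos = np.array([[index[i].x, index[i].y, index[i].z] for i in lit_ids])
    kdt_det = cKDTree(pts)
    d_lit, _ = kdt_det.query(lit_pos)
    recall = float((d_lit <= tol).mean())
    f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    return {"precision": precision, "recall": recall, "f1": f1,
            "n_detections": len(signals), "n_lit": len(lit_ids)}
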