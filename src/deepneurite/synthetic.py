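"""Synthetic neurons and image stacks emulating light-microscopy data.

The generator grows a ground-truth tree — a soma, branching dendrite
trunks and one long tortuous axon — and renders it into a 3D stack with
the appearance properties that make tracing hard in practice: dendrites
as continuous Gaussian-profile tubes, axons as bright beads whose thin
inter-bead runs are stochastically omitted (the punctate, gappy axonal
signal), a smooth multiplicative bias field (uneven illumination),
additive Gaussian noise calibrated to an SNR target, and either
fluorescence (bright signal) or bright-field (dark signal) polarity.

SNR here is (mean foreground − mean background) / background σ, measured
over the structure mask; the signal amplitude is calibrated so the
rendered stack hits the requested target in expectation.

Everything is a pure function of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .imaging import BRIGHT, DARK, ImageStack
from .morphology import NeuronNode, NeuronTree, decompose_segments

__all__ = ["SyntheticSpec", "RenderResult", "simulate_neuron", "render_stack",
           "make_corpus", "measure_snr", "add_spurious_segments"]


@dataclass
class SyntheticSpec:
    """Generation parameters; defaults are the study conditions used
    throughout the test corpus."""

    dims: tuple[int, int, int] = (128, 128, 32)  # (X, Y, Z) voxels
    voxel_size: tuple[float, float, float] = (0.3, 0.3, 1.0)  # um
    n_dendrite_trunks: int = 3
    dendrite_radius: tuple[float, float] = (1.2, 2.0)  # voxels
    dendrite_length: tuple[int, int] = (30, 60)  # steps per trunk
    axon_length: int = 150
    axon_radius: float = 1.0
    axon_bead_spacing: int = 3  # beads at every m-th axon node
    axon_arbor_branches: int = 2
    p_gap: float = 0.3  # prob. an inter-bead run is omitted
    tortuosity_deg: float = 10.0  # direction jitter per unit step
    branch_prob: float = 0.04
    background_level: float = 100.0
    bias_amplitude: float = 0.2  # relative low-frequency illumination drift
    noise_sigma: float = 4.0  # additive Gaussian, intensity units
    snr: float = 4.0
    polarity: str = BRIGHT

    def __post_init__(self):
        if any(d < 32 for d in self.dims):
            raise ValueError("each volume dim must be >= 32 voxels")
        if not (0.0 <= self.p_gap < 1.0):
            raise ValueError("p_gap must be in [0, 1)")
        if self.snr <= 0:
            raise ValueError("SNR target must be > 0")
        if self.polarity not in (BRIGHT, DARK):
            raise ValueError(f"unknown polarity {self.polarity!r}")


@dataclass
class RenderResult:
    stack: ImageStack
    mask: np.ndarray  # bool (z, y, x): voxels within any node's radius
    lit_node_ids: list[int]  # nodes whose signal was actually drawn


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 0 else np.array([1.0, 0.0, 0.0])


def _step_direction(d: np.ndarray, rng, sigma_rad: float) -> np.ndarray:
    # jitter mostly in-plane: z wander damped so shallow stacks stay filled
    j = rng.normal(0.0, sigma_rad, 3)
    j[2] *= 0.3
    return _unit(d + j)


class _Grower:
    def __init__(self, spec: SyntheticSpec, rng: np.random.Generator):
        self.spec = spec
        self.rng = rng
        self.nodes: list[NeuronNode] = []
        self.lo = np.array([2.0, 2.0, 1.0])
        self.hi = np.array(spec.dims, dtype=float) - 1 - self.lo

    def add(self, type_code, pos, radius, parent) -> int:
        nid = len(self.nodes) + 1
        self.nodes.append(NeuronNode(nid, type_code, float(pos[0]), float(pos[1]),
                                     float(pos[2]), float(radius), parent))
        return nid

    def walk(self, parent_id: int, pos, direction, n_steps: int, type_code: int,
             radius: float, branch_prob: float, depth: int = 0) -> None:
        sigma = np.deg2rad(self.spec.tortuosity_deg)
        d = _unit(np.asarray(direction, dtype=float))
        pos = np.asarray(pos, dtype=float)
        pid = parent_id
        for _ in range(n_steps):
            d = _step_direction(d, self.rng, sigma)
            nxt = pos + d
            for ax in range(3):  # reflect off the volume walls
                if nxt[ax] < self.lo[ax] or nxt[ax] > self.hi[ax]:
                    d[ax] = -d[ax]
                    nxt = pos + d
            pos = np.clip(nxt, self.lo, self.hi)
            pid = self.add(type_code, pos, radius, pid)
            if depth < 2 and branch_prob > 0 and self.rng.random() < branch_prob:
                bd = _unit(d + self.rng.normal(0.0, 0.7, 3) * np.array([1, 1, 0.3]))
                self.walk(pid, pos, bd, max(4, n_steps // 3), type_code,
                          radius * 0.8, branch_prob * 0.5, depth + 1)


def simulate_neuron(spec: SyntheticSpec, seed: int = 0) -> NeuronTree:
    """Grow a ground-truth tree: soma near the volume center, branching
    dendrite trunks (type 3) and one long tortuous axon (type 2) with
    optional distal arborization. Unit inter-node spacing."""
    rng = np.random.default_rng(seed)
    g = _Grower(spec, rng)
    center = np.array(spec.dims, dtype=float) / 2.0
    soma_pos = center + rng.normal(0.0, 2.0, 3) * np.array([1, 1, 0.5])
    soma_pos = np.clip(soma_pos, g.lo, g.hi)
    soma = g.add(1, soma_pos, 3.0, -1)

    for i in range(spec.n_dendrite_trunks):
        phi = 2 * np.pi * (i + rng.uniform(-0.2, 0.2)) / max(spec.n_dendrite_trunks, 1)
        d0 = np.array([np.cos(phi), np.sin(phi), rng.uniform(-0.2, 0.2)])
        length = int(rng.integers(spec.dendrite_length[0], spec.dendrite_length[1] + 1))
        radius = rng.uniform(*spec.dendrite_radius)
        g.walk(soma, soma_pos, d0, length, 3, radius, spec.branch_prob)

    if spec.axon_length > 0:
        phi = rng.uniform(0, 2 * np.pi)
        d0 = np.array([np.cos(phi), np.sin(phi), rng.uniform(-0.1, 0.1)])
        g.walk(soma, soma_pos, d0, spec.axon_length, 2, spec.axon_radius, 0.0)
        if spec.axon_arbor_branches > 0:
            tip = g.nodes[-1]
            tip_pos = tip.position
            for _ in range(spec.axon_arbor_branches):
                bd = _unit(rng.normal(0.0, 1.0, 3) * np.array([1, 1, 0.3]))
                g.walk(tip.id, tip_pos, bd, max(8, spec.axon_length // 6), 2,
                       spec.axon_radius, 0.0)

    tree = NeuronTree(g.nodes, name=f"synthetic-{seed}")
    tree.validate()
    return tree


def _draw_blob(canvas: np.ndarray, pos, sigmas, amplitude: float) -> None:
    x, y, z = pos
    sz, sy, sx = sigmas[2], sigmas[1], sigmas[0]
    rz, ry, rx = (int(np.ceil(3 * s)) for s in (sz, sy, sx))
    Z, Y, X = canvas.shape
    cz, cy, cx = int(round(z)), int(round(y)), int(round(x))
    z0, z1 = max(0, cz - rz), min(Z, cz + rz + 1)
    y0, y1 = max(0, cy - ry), min(Y, cy + ry + 1)
    x0, x1 = max(0, cx - rx), min(X, cx + rx + 1)
    if z0 >= z1 or y0 >= y1 or x0 >= x1:
        return
    zz, yy, xx = np.meshgrid(np.arange(z0, z1), np.arange(y0, y1),
                             np.arange(x0, x1), indexing="ij")
    blob = amplitude * np.exp(
        -(((zz - z) / sz) ** 2 + ((yy - y) / sy) ** 2 + ((xx - x) / sx) ** 2) / 2.0
    )
    np.maximum(canvas[z0:z1, y0:y1, x0:x1], blob,
               out=canvas[z0:z1, y0:y1, x0:x1])


def _draw_ball(mask: np.ndarray, pos, radius: float) -> None:
    x, y, z = pos
    r = max(radius, 1.0)
    Z, Y, X = mask.shape
    z0, z1 = max(0, int(np.floor(z - r))), min(Z, int(np.ceil(z + r)) + 1)
    y0, y1 = max(0, int(np.floor(y - r))), min(Y, int(np.ceil(y + r)) + 1)
    x0, x1 = max(0, int(np.floor(x - r))), min(X, int(np.ceil(x + r)) + 1)
    zz, yy, xx = np.meshgrid(np.arange(z0, z1), np.arange(y0, y1),
                             np.arange(x0, x1), indexing="ij")
    mask[z0:z1, y0:y1, x0:x1] |= (
        (zz - z) ** 2 + (yy - y) ** 2 + (xx - x) ** 2 <= r * r
    )


def _sigmas(radius: float, voxel_size) -> tuple[float, float, float]:
    # Gaussian footprint scaled per axis by voxel anisotropy (radius is in
    # xy-voxels). The axial floor of 1 voxel models the optical PSF, which
    # is 2-3x wider axially than laterally: structures always span at
    # least a couple of z planes, whatever their physical radius.
    sx, sy, sz = voxel_size
    base = 0.8 * radius
    return (max(base, 0.6), max(base * sx / sy, 0.6), max(base * sx / sz, 1.0))


def _bias_field(shape, amplitude: float, rng) -> np.ndarray:
    """Smooth multiplicative field 1 + amplitude * f, f in [-1, 1]: a sum
    of three random low-frequency cosines. Illumination and staining
    unevenness drift mostly laterally, so the axial frequency is kept
    well below one cycle per stack depth."""
    if amplitude == 0:
        return np.ones(shape)
    Z, Y, X = shape
    zz, yy, xx = np.meshgrid(np.linspace(0, 1, Z), np.linspace(0, 1, Y),
                             np.linspace(0, 1, X), indexing="ij")
    f = np.zeros(shape)
    total = 0.0
    for _ in range(3):
        a = rng.uniform(0.5, 1.0)
        kx, ky = rng.uniform(0.5, 1.5, 2)
        kz = rng.uniform(0.1, 0.4)
        phase = rng.uniform(0, 2 * np.pi)
        f += a * np.cos(2 * np.pi * (kx * xx + ky * yy + kz * zz) + phase)
        total += a
    return 1.0 + amplitude * f / total


def render_stack(tree: NeuronTree, spec: SyntheticSpec, seed: int = 0) -> RenderResult:
    """Render a tree into an image stack plus ground-truth mask.

    Dendrites and soma are continuous tubes of overlapping Gaussian
    blobs. Axon segments get a bright bead at every ``m``-th node; the
    thinner run of nodes between two consecutive beads is omitted with
    probability ``p_gap``, producing the beaded, gappy axonal signal.
    The mask marks voxels within each node's radius (all nodes, drawn or
    not); ``lit_node_ids`` lists the nodes whose signal was drawn.
    """
    rng = np.random.default_rng(seed)
    X, Y, Z = spec.dims
    shape = (Z, Y, X)
    signal = np.zeros(shape)
    mask = np.zeros(shape, dtype=bool)
    lit: list[int] = []
    index = tree._index()

    for n in tree.nodes:
        _draw_ball(mask, (n.x, n.y, n.z), n.radius)

    for seg in decompose_segments(tree):
        nodes = [index[i] for i in seg.node_ids]
        tc = nodes[0].type_code
        if tc != 2:  # soma + dendrites: continuous tubes
            for n in nodes:
                _draw_blob(signal, (n.x, n.y, n.z),
                           _sigmas(n.radius, spec.voxel_size), 1.0)
                lit.append(n.id)
            continue
        m = max(1, spec.axon_bead_spacing)
        bead_idx = list(range(0, len(nodes), m))
        if bead_idx[-1] != len(nodes) - 1:
            bead_idx.append(len(nodes) - 1)
        for bi in bead_idx:
            n = nodes[bi]
            _draw_blob(signal, (n.x, n.y, n.z),
                       _sigmas(n.radius * 1.3, spec.voxel_size), 1.0)
            lit.append(n.id)
        for a, b in zip(bead_idx[:-1], bead_idx[1:]):
            if rng.random() < spec.p_gap:
                continue  # omitted inter-bead run: a true signal gap
            for n in nodes[a + 1 : b]:
                _draw_blob(signal, (n.x, n.y, n.z),
                           _sigmas(n.radius * 0.7, spec.voxel_size), 0.85)
                lit.append(n.id)

    bias = _bias_field(shape, spec.bias_amplitude, rng)
    b0 = spec.background_level
    bg = ~mask
    var_bias = float((b0 * bias)[bg].var()) if bg.any() else 0.0
    sigma_bg = float(np.sqrt(var_bias + spec.noise_sigma**2))
    if sigma_bg < 1e-9:
        sigma_bg = 0.05 * b0
    sb = signal * bias
    denom = float(sb[mask].sum())
    amp = spec.snr * sigma_bg * int(mask.sum()) / denom if denom > 0 else 0.0
    noiseless = b0 * bias + amp * sb
    if spec.polarity == DARK:
        noiseless = noiseless.max() - noiseless
    img = noiseless
    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, shape)
    img = np.clip(img, 0.0, None).astype(np.float32)
    stack = ImageStack(img, spec.voxel_size, spec.polarity)
    return RenderResult(stack, mask, sorted(set(lit)))


def measure_snr(result: RenderResult) -> float:
    """(mean foreground − mean background) / background σ, on the
    polarity-normalized intensities."""
    from .imaging import normalize_polarity

    v = normalize_polarity(result.stack).voxels.astype(float)
    fg = v[result.mask]
    bg = v[~result.mask]
    return float((fg.mean() - bg.mean()) / bg.std())


def make_corpus(n_neurons: int, spec: SyntheticSpec, seed: int = 0,
                out_dir=None) -> list[tuple[ImageStack, NeuronTree, RenderResult]]:
    """n independent (stack, tree, render) triples with per-item seeds
    derived from the master seed; optionally written to disk with a
    manifest CSV."""
    if n_neurons < 1:
        raise ValueError("need n >= 1")
    ss = np.random.SeedSequence(seed)
    states = ss.generate_state(2 * n_neurons) % (2**31)
    out = []
    rows = []
    for i in range(n_neurons):
        tree = simulate_neuron(spec, int(states[2 * i]))
        render = render_stack(tree, spec, int(states[2 * i + 1]))
        out.append((render.stack, tree, render))
        if out_dir is not None:
            import os

            from .imaging import to_uint16, write_stack
            from .morphology import write_swc

            os.makedirs(out_dir, exist_ok=True)
            tif = os.path.join(out_dir, f"neuron_{i:03d}.tif")
            swc = os.path.join(out_dir, f"neuron_{i:03d}.swc")
            msk = os.path.join(out_dir, f"neuron_{i:03d}_mask.tif")
            write_stack(to_uint16(render.stack), tif)
            write_swc(tree, swc)
            import tifffile

            tifffile.imwrite(msk, render.mask.astype(np.uint8))
            rows.append({"stack": tif, "swc": swc, "mask": msk,
                         "tree_seed": int(states[2 * i]),
                         "render_seed": int(states[2 * i + 1]),
                         "snr_target": spec.snr, "polarity": spec.polarity})
    if out_dir is not None:
        import os

        pd.DataFrame(rows).to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    return out


def add_spurious_segments(tree: NeuronTree, spec: SyntheticSpec, frac: float = 0.3,
                          seed: int = 0, length: int = 10,
                          min_dist: float = 12.0) -> tuple[NeuronTree, list[int], list[int]]:
    """Over-traced input for pruning tests: append ``frac`` × (true
    segment count) short background walks as extra roots, placed at
    least ``min_dist`` voxels from every true node.

    Returns (over-traced tree, true node ids, spurious node ids).
    """
    from scipy.spatial import cKDTree

    rng = np.random.default_rng(seed)
    true_ids = [n.id for n in tree.nodes]
    n_spur = max(1, int(round(frac * len(decompose_segments(tree)))))
    kdt = cKDTree(tree.positions())
    lo = np.array([2.0, 2.0, 1.0])
    hi = np.array(spec.dims, dtype=float) - 1 - lo
    nodes = list(tree.nodes)
    next_id = max(true_ids) + 1
    spurious_ids: list[int] = []
    for _ in range(n_spur):
        for _attempt in range(200):
            start = rng.uniform(lo, hi)
            if kdt.query(start)[0] >= min_dist:
                break
        else:
            raise RuntimeError("could not place spurious segment in background")
        d = _unit(rng.normal(0.0, 1.0, 3) * np.array([1, 1, 0.3]))
        pos = start
        parent = -1
        for _ in range(length):
            nodes.append(NeuronNode(next_id, 0, float(pos[0]), float(pos[1]),
                                    float(pos[2]), 1.0, parent))
            spurious_ids.append(next_id)
            parent = next_id
            next_id += 1
            d = _step_direction(d, rng, np.deg2rad(spec.tortuosity_deg))
            pos = np.clip(pos + d, lo, hi)
    out = NeuronTree(nodes, name=tree.name + "+spurious")
    out.validate()
    return out, true_ids, spurious_ids
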