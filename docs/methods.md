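# Methods

This note documents the models, algorithms and design choices behind
`deepneurite`, and what the synthetic test corpus does and does not show
about real microscopy data.

## Data model

A reconstruction is a 7-column SWC forest (id, type, x, y, z, radius,
parent; Vaa3D dialect: 1-based ids, parent −1 for roots, `#` comments,
multiple roots allowed). Coordinates are voxel units of the companion
stack; physical units enter only through the stack's voxel size (default
0.3 × 0.3 × 1 µm, a typical whole-brain fluorescence resolution).
Stacks are `(z, y, x)` arrays with a polarity flag; bright-field images
(dark stain on bright background) are inverted once by
`normalize_polarity` (idempotent), after which every stage assumes
signal-positive intensities.

Segments are maximal unbranched runs of one type code: they break at
roots, at branch points, and at type changes. The extra break at type
changes lets axon and dendrite statistics be computed per segment. Tip
orientation is the unit chord from the node `min(depth, available)`
steps inward to the tip (depth 5 by default) — cheap, deterministic, and
within ~10° of a least-squares line fit on segments with sub-voxel
jitter.

## Patches and the classifier contract

Every classification stage consumes the same representation: the
maximum-intensity projection of the local k³ block, min–max normalized
to [0, 1] per patch (constant blocks map to zeros). Per-patch
normalization makes the classifier insensitive to the slow illumination
drift that plagues these images; its cost is that absolute brightness is
not a feature. Out-of-bounds voxels are padded with the stack minimum
(background after polarity normalization) so borders do not invent
structure. Non-integer centers round half-up. The canonical block size
is k = 61; the test corpus uses k = 15–25 so that training fits in
seconds at 128³-scale volumes (see "Problem sizes").

A classifier is anything exposing `n_classes`, `patch_size` and
`predict_proba` (rows summing to 1, deterministic at inference). The
reference implementation is a compact NumPy CNN — conv(3×3)/ReLU/
max-pool blocks (two by default), then two dense layers — trained with
Adam on a seeded generator; initialisation, shuffling and the train/
validation split all derive from one integer seed, so training is
exactly reproducible. Gradients are verified against finite differences
in the test suite. Heavier architectures can be swapped in behind the
same contract.

Detection training sets are balanced by construction: one positive
patch per annotation node, an equal number (`neg_ratio` = 1) of
background patches at uniform centers at least `min_bg_dist` = 10 voxels
from every node. The three-class set adds axon (type 2) and dendrite
(types 3–4) patches with one background patch per neurite patch.

## Detection pipeline

1. **2D stage** — sliding-window grid (stride 4 by default) over the XY
   MIP; keep centers whose foreground probability ≥ 0.5.
2. **Mean shift** — flat-disk kernel (default bandwidth 15 px ≈ k/4 for
   k = 61; the tests use ~k/5 at k = 15); each detection moves to the
   intensity-weighted centroid of its disk until the shift is < 0.5 px
   or 50 iterations. Weights are background-subtracted intensities
   (image median, clipped at zero): with the raw additive offset the
   centroid of any window is essentially its own center and the shift
   stalls. Zero-weight windows leave the detection in place. Detections
   converging within bandwidth/2 merge, keeping the highest score (ties:
   lower y, then x).
3. **Z-mapping** — z = argmax of the column profile smoothed with the
   center-weighted 3-tap [1, 2, 1]/4 (edges replicated); ties break
   toward smaller z. The center-weighted tap suppresses single-voxel
   noise like a moving mean but keeps an isolated bright voxel at its
   own plane instead of spreading it into a plateau.
4. **3D re-classification** — score the block MIP at each mapped
   location; keep those ≥ 0.5. This removes 2D detections that were
   projection artifacts over empty columns.

Detection quality on synthetic stacks is summarized as precision
(detections within 2 voxels of the true centerline), and recall over the
*rendered* centerline nodes only — axon gap regions contain no signal by
construction, so no detector can recall them; including them would
measure the renderer, not the detector.

## Connection (DMST)

The Siamese model is one convolutional embedding arm applied to both
patches (shared weights), trained with the contrastive loss
`y·d² + (1−y)·max(0, margin−d)²` (margin 1.0) on positive pairs from
consecutive annotation nodes and an equal number of negative pairs
sampled at ≥ 40 voxels separation. The embedding width is M = 200. The
dissimilarity of two patches is the L2 distance of their embeddings;
separation is reported as held-out median positive/negative
dissimilarity and the AUC of −d.

The graph over detections is the union of each node's 6 nearest
neighbors, capped at `max_edge_len` = 100 voxels (complete-graph mode
exists for testing); distances are voxel-space by default with an
optional physical-unit mode that scales axes by voxel size. Edge weight
is distance × dissimilarity. The spanning forest is Kruskal with ties
broken by (weight, min index, max index) — fully deterministic; each
connected component is rooted at its lowest signal index. Zero-distance
(duplicate) edges have weight 0 and join first. With unit dissimilarity
the output equals the classical Euclidean MST; the tests verify this
against scipy's implementation and verify the weighted case against an
exhaustive Prüfer-sequence enumeration of all labeled spanning trees.

## Pruning and consensus

Pruning is segment-level: a segment is removed when the fraction of its
nodes classified foreground is < `seg_keep_frac` = 0.5. Node-level
removal would let isolated misclassifications fragment true neurites.
Children of removed segments are re-rooted, so the output is always a
valid forest. Pruning a pruned tree changes nothing.

Consensus fuses ≥ 2 pruned reconstructions of one stack. Every node is
matched to the nearest node of each other reconstruction within
`support_radius` = 3 voxels; a node survives when its matched set spans
≥ `min_support` (default ⌈n/2⌉) distinct inputs, and its position
becomes the centroid of that set (cross-reconstruction averaging).
Survivors are deduplicated by leader clustering at 0.5 voxel — below the
unit node spacing, so a neurite can never chain into a single cluster
(single-linkage at the support radius would do exactly that) — and
re-linked by the spanning-forest construction. The procedure is
deterministic and invariant to input order; with identical inputs it
reproduces the input node set up to centroid rounding, and with
independently jittered inputs the averaging pulls the consensus closer
to the true centerline than any single input.

## Consistency scoring

Nodes of a manual reconstruction are classified foreground/background
by a model trained on *other* reconstructions (contiguous equal-size
folds; k-fold cross-validation). Foreground runs within each segment
form fragments; fragment tips are paired greedily nearest-first (each
tip used once) and a pair connects when (a) tip distance < 30 voxels,
(b) the angle between one tip's outward orientation and the negation of
the other's is < 30° (both strict, with a 10⁻⁹-degree guard for arccos
round-off so exact boundary geometries are excluded), and (c) the tips
face each other (each orientation has positive component along the
chord to the other tip — without this, the far ends of two collinear
fragments also pass the anti-alignment test). Connecting a pair
relabels the background manual nodes on the tree path between the tips;
no nodes are created, so

    c = n_refined / n_manual × 100 %

is a retention fraction bounded by 100 %, reported overall and over
axon (type 2) and dendrite (types 3–4) nodes separately.

## Axon/dendrite typing

A three-class model scores every node of a segment; the segment label is
the majority of non-background argmax votes (all-background → unknown;
axon/dendrite ties → axon, the lower SWC type code). Soma segments are
untouched; labels write SWC type codes 2/3. In the synthetic corpus the
discriminant is texture — beaded, gappy axonal signal vs continuous
tubes — and the hardest cases are thin distal dendrite branches whose
caliber approaches the axon's, the same regime that is hardest in real
images. The reference configuration for this task uses larger patches
(k = 25) and a wider net than the detection model, and expands the
training set with the four 90° rotations of every patch
(`augment_rotations`): neurite orientation within a patch is arbitrary,
and the extra views stabilize the texture boundary between thin
dendrites and axons against the orientation sampling of a small corpus.

## Synthetic data generator

`simulate_neuron` grows a soma near the volume center, 2–4 dendrite
trunks as branching random walks (unit step, direction jitter
σ = 10°/step with axial wander damped ×0.3, branch probability
0.04/step, radius uniform in 1.2–2 voxels tapering ×0.8 per branch
order), and one long axon (150 steps, radius 1) with a small distal
arbor. Walks reflect off the volume walls.

`render_stack` draws soma and dendrites as overlapping Gaussian blobs —
a continuous tube — and axons as bright beads at every 3rd node with the
thinner inter-bead run omitted with probability `p_gap` = 0.3: the
beaded, broken axonal appearance. Blob footprints scale per axis with
voxel anisotropy, with an axial floor of 1 voxel modelling the optical
PSF (axially 2–3× wider than lateral; structures always span ≥ ~2
planes). A multiplicative bias field (three random low-frequency
cosines, amplitude 0.2, axial frequency < 0.4 cycles per stack since
illumination drift is lateral) models uneven background; additive
Gaussian noise (σ = 4 on a background of 100) is added last. The signal
amplitude is calibrated so that the measured SNR —
(mean foreground − mean background)/background σ over the structure
mask — hits the target (default 4) in expectation; renders land within
a few percent. Dark-signal renders are `max − bright` before noise. The
ground-truth mask marks voxels within each node's radius (drawn or
not); the renderer also reports which nodes were actually lit.

What the generator does *not* emulate: real PSF side-lobes and
anisotropic blur beyond a Gaussian, staining chemistry, autofluorescence
textures, imaging artifacts (stripes, tiling seams), densely packed
neighboring neurons, and annotation error in the "manual" trees (they
are exact). Passing tests therefore demonstrate algorithmic correctness
and end-to-end behavior under controlled difficulty (SNR, gaps, bias),
not performance on any real dataset.

## Problem sizes

The test corpus runs at desk scale so the full suite finishes in a few
minutes on one CPU: 128 × 128 × 32 volumes, patch sizes 15–25, corpora
of 3–12 stacks (10³–10⁴ patches), ~10 training epochs. These are the
package's own defaults for its synthetic studies; the library itself
has no size assumptions beyond memory.

## Numerical and degenerate-input conventions

Probability rows sum to 1 within 1e−6; empty batches return empty
arrays. Empty trees round-trip as comment-only SWC files. An isolated
node has no orientation (error). Constant blocks normalize to zeros.
Constant z-columns map to z = 0 (smaller-z tie rule). Zero-intensity
mean-shift windows leave detections in place. Model files are a single
pickled-dict `.npy` plus a JSON metadata sidecar (patch size, classes,
seed, training hyperparameters); the format contains no timestamps, so
identical runs produce byte-identical files.

## Known limitations

- The 2D-MIP detection path inherits projection ambiguity: where two
  structures overlap in XY, the Z-mapping keeps the brighter one.
- The consensus procedure is a documented stand-in for published
  multi-tracer fusion methods, not a reproduction of any of them.
- Axon/dendrite typing degrades when dendrite caliber approaches the
  axon's; segment votes on short thin branches are the dominant error
  mode.
- No tiling/stitching for volumes that do not fit in memory; crop
  upstream.
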