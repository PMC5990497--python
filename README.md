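# deepneurite

A neuron-tracing toolbox for 3D light-microscopy stacks. Reconstructing a
neuron means finding its dendritic and axonal signal in a noisy volume and
connecting it into a tree (SWC). Dendrites are usually continuous and easy;
axons appear as dim, beaded, *broken* signal that defeats rule-based
tracers. `deepneurite` casts the hard steps as patch classification and
learned pair similarity, and packages five cooperating modules:

1. **Neurite signal detection** — classify sliding-window patches of the
   XY maximum-intensity projection (MIP) as foreground/background with a
   small CNN, refine detections by mean shift, map each to 3D via the local
   intensity maximum along Z, and re-classify on the local 3D block MIP.
   Training patches are MIPs of k³ blocks (k = 61 by default) centered on
   manual annotation nodes, balanced 1:1 with background patches.
2. **Neurite connection (DMST)** — link detections with a minimum spanning
   forest whose edge weight is `distance × dissimilarity`, where the
   dissimilarity is the Euclidean distance `‖f(p) − f(q)‖₂` between
   length-M embeddings (M = 200) from a Siamese network — two identical
   convolutional arms with shared weights trained with a contrastive loss
   on pairs of patches from consecutive (positive) vs spatially separated
   (negative) annotation nodes. With unit dissimilarity this reduces to the
   classical distance-only MST baseline.
3. **Smart pruning** — score every node of an over-traced reconstruction
   with the foreground classifier and drop segments whose foreground
   fraction falls below a threshold; optionally fuse several tracings of
   one stack into a consensus by cross-reconstruction voting and MST
   re-linking.
4. **Manual reconstruction evaluation** — the consistency score
   `c = (nodes in the refined prediction) / (nodes in the manual
   reconstruction) × 100 %`, where the refined prediction is the
   classifier's foreground set after reconnecting fragment tips that are
   closer than 30 voxels and whose orientations continue each other within
   30° (both strict), evaluated by k-fold cross-validation across
   reconstructions.
5. **Axon/dendrite classification** — a three-class
   (background/axon/dendrite) model types each segment by majority vote of
   its nodes' non-background posteriors.

All classifiers sit behind a swappable contract (`predict_proba` over
patches), so the bundled seeded NumPy reference CNN can be replaced by any
heavier backend. A synthetic-data module simulates ground-truth neurons
(soma, branching dendrite trunks, one long tortuous axon) and renders them
with the appearance properties that matter: continuous Gaussian-profile
dendrite tubes, beaded axons with stochastic signal gaps, smooth uneven
background, additive noise calibrated to an SNR target, and both
fluorescence (bright-signal) and bright-field (dark-signal) polarity — so
every stage trains and tests at desk scale without external data.

## Worked example

```bash
python examples/02_detect_signal.py
```

```
detector: patch size 15, held-out accuracy 0.995
128 detections on the held-out stack
precision 0.930  recall 0.814  F1 0.868
```

The detector reaches ~99 % held-out patch accuracy on the balanced
training set; on a held-out stack (SNR 4, 30 % axon gap probability),
93 % of detections fall within 2 voxels of the true centerline and
81 % of the rendered centerline nodes are recovered. The other scripts
in `examples/` walk through simulation, DMST linking, pruning/consensus,
consistency scoring, and axon/dendrite typing the same way — each builds
its own small synthetic input, runs one capability, and prints what the
numbers mean.

The same pipelines are exposed as a CLI for shell use
(`deepneurite simulate | train-detector | train-siamese | train-types |
detect | connect | trace | prune | consensus | evaluate |
classify-types`); every subcommand takes `--seed` and writes a
`.params.json` sidecar, so reruns are byte-identical.

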