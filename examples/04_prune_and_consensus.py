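"""Clean up an over-traced reconstruction and fuse multiple tracings.

Takes a ground-truth tree plus 30% spurious background segments (what a
permissive tracer produces), prunes segments whose nodes do not look
like signal to the trained classifier, then fuses three jittered
tracings into a consensus.
"""

from dataclasses import replace

import numpy as np

from deepneurite.morphology import NeuronTree
from deepneurite.patch_classifier import (TrainConfig,
                                          build_detection_training_set,
                                          merge_sets, train)
from deepneurite.refinement import consensus, prune
from deepneurite.synthetic import (SyntheticSpec, add_spurious_segments,
                                   make_corpus)

K = 15
spec = SyntheticSpec()

corpus = make_corpus(4, spec, seed=10)
sets = [build_detection_training_set(stack, tree, k=K, seed=i)
        for i, (stack, tree, _) in enumerate(corpus)]
model = train(merge_sets(sets), TrainConfig(epochs=6), seed=0)

stack, tree, _ = make_corpus(1, spec, seed=77)[0]
over, true_ids, spur_ids = add_spurious_segments(tree, spec, frac=0.3, seed=5)
pruned, report = prune(over, stack, model, k=K)
kept = set(pruned.node_ids)
print(f"over-traced input: {len(over)} nodes ({len(spur_ids)} spurious)")
print(f"pruned: kept {report.kept_nodes}, removed {report.removed_nodes}")
print(f"  spurious nodes surviving: {len(kept & set(spur_ids))}")
print(f"  true nodes lost: {len(set(true_ids) - kept)}")


def jitter(t, seed):
    g = np.random.default_rng(seed)
    X, Y, Z = spec.dims
    return NeuronTree([
        replace(n,
                x=float(np.clip(n.x + g.normal(0, 1), 0, X - 1)),
                y=float(np.clip(n.y + g.normal(0, 1), 0, Y - 1)),
                z=float(np.clip(n.z + g.normal(0, 1), 0, Z - 1)))
        for n in t.nodes])


tracings = [jitter(tree, s) for s in (1, 2, 3)]
fused = consensus(tracings, stack, model, k=K)
from scipy.spatial import cKDTree

kdt = cKDTree(tree.positions())
for name, t in [("input 1", tracings[0]), ("consensus", fused)]:
    d, _ = kdt.query(t.positions())
    print(f"{name}: {len(t)} nodes, mean distance to truth {d.mean():.2f} voxels")
# The consensus averages out the per-tracing jitter, so its mean distance
# to the true centerline drops below any single input's.
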