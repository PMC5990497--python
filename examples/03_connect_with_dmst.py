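"""Link detected signals into a tree with the dissimilarity-weighted MST.

Trains the Siamese dissimilarity model on patch pairs from consecutive
vs spatially separated annotation nodes, then connects a dot cloud of
detections. Edge weight = Euclidean distance x embedding dissimilarity,
so the spanning forest prefers jumps between patches that look like the
same neurite.
"""

from deepneurite.connection import (SiameseConfig, build_dmst,
                                    build_pair_training_set, merge_pair_sets,
                                    train_siamese)
from deepneurite.detection import DetectedSignal
from deepneurite.synthetic import SyntheticSpec, make_corpus

K = 15
spec = SyntheticSpec()

corpus = make_corpus(3, spec, seed=40)
sets = [build_pair_training_set(stack, tree, k=K, neg_min_separation=40, seed=i)
        for i, (stack, tree, _) in enumerate(corpus)]
pairs = merge_pair_sets(sets)
model = train_siamese(pairs, SiameseConfig(m=200, epochs=10), seed=0)
s = model.val_stats
print(f"{len(pairs)} training pairs; held-out median dissimilarity "
      f"pos {s['median_pos']:.3f} vs neg {s['median_neg']:.3f}, AUC {s['auc']:.3f}")
# Positive (connected) pairs should score well below negatives.

stack, tree, _ = make_corpus(1, spec, seed=99)[0]
dots = [DetectedSignal(n.x, n.y, n.z, 1.0, "final3d")
        for i, n in enumerate(tree.nodes) if i % 3 == 0]
linked = build_dmst(dots, stack, model=model, knn=6, max_edge_len=30, k=K)
roots = sum(n.parent == -1 for n in linked.nodes)
print(f"linked {len(dots)} dots into a forest of {roots} component(s), "
      f"{len(linked)} nodes")
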