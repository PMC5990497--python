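"""Automatically label segments of a reconstruction as axon or dendrite.

Trains the three-class (background / axon / dendrite) reference CNN and
types every segment of a held-out tree by majority vote of its nodes'
posteriors. Dendrites render as continuous tubes, axons as beaded,
gappy signal — the texture the classifier learns to separate.
"""

from deepneurite.morphology import decompose_segments
from deepneurite.neurite_type import annotate_tree_types
from deepneurite.patch_classifier import (TrainConfig,
                                          build_type_training_set, merge_sets,
                                          train)
from deepneurite.synthetic import SyntheticSpec, make_corpus

K3 = 25
spec = SyntheticSpec()

corpus = make_corpus(6, spec, seed=200)
sets = [build_type_training_set(stack, tree, k=K3, seed=i)
        for i, (stack, tree, _) in enumerate(corpus)]
model3 = train(merge_sets(sets),
               TrainConfig(epochs=12, channels=(12, 24), hidden=48), seed=0)
print(f"3-class model: held-out patch accuracy {model3.val_accuracy:.3f}")

stack, tree, _ = make_corpus(1, spec, seed=300)[0]
blind = decompose_segments(tree)
typed = annotate_tree_types(tree, stack, model3, k=K3)
index = tree._index()
typed_index = typed._index()
correct = total = 0
for seg in blind:
    true_tc = index[seg.node_ids[0]].type_code
    if true_tc not in (2, 3):
        continue
    pred_tc = typed_index[seg.node_ids[0]].type_code
    total += 1
    correct += pred_tc == true_tc
print(f"segment typing: {correct}/{total} correct "
      f"({100.0 * correct / total:.1f}%)")
# Type codes follow SWC: 2 = axon, 3 = dendrite; soma (1) is untouched.
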