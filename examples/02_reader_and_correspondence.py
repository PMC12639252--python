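"""Simulate a fragmenting, false-positive-prone reader and match it.

A phantom's ground truth is run through the simulated reader (which here
always splits detected lesions in two), and the merge-based one-to-one
correspondence is established and classified at the 0.5 score threshold.
"""

from petlesion import (
    LesionSpec,
    PhantomSpec,
    ReaderSpec,
    classify_detections,
    generate_phantom,
    merge_to_one_to_one,
    simulate_model_output,
)

spec = PhantomSpec(
    lesions=(
        LesionSpec(center=(20, 20, 20), radius_mm=9.0, suv_max=9.0, site="liver"),
        LesionSpec(center=(44, 40, 40), radius_mm=7.0, suv_max=6.0, site="bone"),
    ),
    seed=2,
)
phantom = generate_phantom(spec)
truth = phantom.expert_lesion_set()

reader = ReaderSpec(detection_prob=1.0, split_prob=1.0, n_fragments=2, fp_rate=2.0, seed=3)
model = simulate_model_output(truth, phantom.site_map, reader, phantom.volume)
print(f"expert lesions: {len(truth)}, raw model lesions: {len(model)}")

result = merge_to_one_to_one(truth, model)
print(f"after merging: {len(result.merged_model)} model lesions, "
      f"{len(result.pairs)} one-to-one pairs")
for ev in result.merge_log:
    print(f"  merged {ev.side} lesions {ev.absorbed} into {ev.survivor}")

counts = classify_detections(result, score_threshold=0.5)
print(f"TP={counts.tp} FP={counts.fp} FN={counts.fn}")
print(
    "\nEach true lesion was emitted as two fragments; merging coalesces the"
    "\nfragments back into one lesion per expert lesion, so detection counts"
    "\nreflect lesions, not fragments.  Unmatched model lesions are the"
    "\nreader's injected false positives."
)
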