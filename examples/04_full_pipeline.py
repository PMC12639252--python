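"""One-call evaluation run: simulate -> read -> match -> evaluate -> report.

Runs the full pipeline on a small synthetic cohort with the default
(imperfect) reader and prints the detection table and agreement rows.
"""

from petlesion import RunConfig, run_pipeline

config = RunConfig(n_patients=6, seed=5, phantom_shape=(40, 40, 40))
report = run_pipeline(config)

print("detection at score threshold 0.5:")
for row in report["detection"]:
    p = "  -  " if row["precision"] is None else f"{row['precision']:5.1f}"
    r = "  -  " if row["recall"] is None else f"{row['recall']:5.1f}"
    print(f"  {row['site']:10s} recall={r} %  precision={p} %  "
          f"(tp={row['tp']} fp={row['fp']} fn={row['fn']})")

print("\nagreement (model - expert):")
for axis, rep in report["agreement"].items():
    icc = "n/a" if rep["icc"] is None else f"{rep['icc']:.2f}"
    print(f"  {axis:12s} median diff={rep['median_diff']:+.2f}  MAD={rep['mad']:.2f}  "
          f"ICC={icc}  (n={rep['n']})")

over = report["cohort_overestimation"]
print(f"\ncohort lesion-count overestimation: {over['lesion_count_pct']:+.1f} %")
print(f"cohort tumor-burden overestimation: {over['tumor_burden_pct']:+.1f} %")
print(
    "\nA dashed precision means no model lesion was assigned to that site."
    "\nRe-running with the same seed reproduces these numbers exactly."
)
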