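"""Run the full biomarker-discovery pipeline on all four comparisons.

Each comparison chains: univariate screen -> PCA -> SOM -> PLS-DA
backward elimination with repeated CV; the overlap table at the end
counts proteins shared between the selected panels (the numbers a Venn
diagram of early/late/long/general maturation biomarkers would show).
Reduced problem sizes keep the demo quick; raise n_repeats to 1000 for
the full validation protocol.
"""

from pathlib import Path

import chemomark as cm

spec = cm.SyntheticSpec(
    n_animals=16, n_tech_reps=1, n_proteins=40, n_discriminant=6,
    planted_fc=1.6, biological_cv=0.4, technical_cv=0.12,
    discarded_samples=(), seed=1,
)
dataset, truth = cm.synthesize(spec)
config = cm.PipelineConfig(seed=0, n_repeats=50, max_lv=3)

reports = cm.run_all(dataset, config)
for name, report in reports.items():
    s = report.summary()
    print(f"{name:8s} n={s['n_samples']:3d}  univariate panel={s['univariate_panel_size']:3d}  "
          f"selected panel={s['multivariate_panel_size']:3d}  "
          f"CV accuracy={s['cv_accuracy_pct']:.2f}%")

print("\npanel overlaps across comparisons:")
table = cm.overlap_summary(reports)
print(table[table["order"] >= 2][["designs", "overlap"]].to_string(index=False))

out = Path("example_output")
for name, report in reports.items():
    report.write(out / name)
print(f"\nper-comparison artifacts written under {out}/<design>/")
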