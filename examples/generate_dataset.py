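"""Generate a synthetic label-free proteomics dataset with known truth.

Builds the default emulated layout — 8 animals (4 heifers, 4 bulls)
sampled at 3 maturation timepoints, 3 technical replicates each, one
female t12 biological sample discarded — over 137 proteins with 20
planted timepoint-discriminant proteins, and writes the matrix,
metadata and ground-truth fold changes as TSV.
"""

from pathlib import Path

import chemomark as cm

out = Path("example_output")
out.mkdir(exist_ok=True)

spec = cm.SyntheticSpec(seed=42)
dataset, truth = cm.synthesize(spec)

counts = dataset.timepoints.value_counts()
print(f"samples: {dataset.n_samples} "
      f"(t0={counts['t0']}, t12={counts['t12']}, t26={counts['t26']})")
print(f"proteins: {dataset.n_proteins}, planted discriminant: {spec.n_discriminant}")
print("true fold changes of the first planted proteins (t0 -> t12):")
planted = sorted(truth.discriminant["t0_vs_t12"])[:5]
print(truth.true_fc("t0_vs_t12").loc[planted].round(3).to_string())

cm.write_dataset(dataset, out / "abundance.tsv", out / "metadata.tsv")
truth.write_tsv(out / "ground_truth_logfc.tsv")
print(f"written under {out}/ — the 24/21/24 split mirrors a real"
      " longitudinal design with one biological sample lost.")
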