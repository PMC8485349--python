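"""Correlate protein abundances with phenotypes (tenderness, shear force).

Phenotypes are generated per biological sample with chosen target
correlations to specific proteins; the correlation matrix should
recover those links as significant and leave unlinked proteins near
r = 0.  A shear-force ANOVA demo follows, with the per-animal DWBS
(difference of mean shear force between late and early aging).
"""

import numpy as np

import chemomark as cm
from chemomark.univariate import WBSRecord

spec = cm.SyntheticSpec(
    phenotype_links=[("tenderness", 4, 0.85), ("shear_force", 9, -0.8)],
    seed=17,
)
dataset, truth = cm.synthesize(spec)
phenotypes = cm.synthesize_phenotypes(dataset, spec)

# correlate at the biological-sample level (replicate log means)
bio = (
    np.log(dataset.to_frame())
    .groupby([dataset.metadata["animal_id"], dataset.metadata["timepoint"]], sort=True)
    .mean()
)
bio.index = ["_".join(k) for k in bio.index]
result = cm.correlate_with_phenotypes(bio, phenotypes)

for phen, (protein, target) in truth.phenotype_r.items():
    r = result["r"].loc[protein, phen]
    print(f"{phen:12s} ~ {protein}: r = {r:+.2f} (target {target:+.2f}), "
          f"significant: {bool(result['significant'].loc[protein, phen])}")
n_sig = int(result["significant"].to_numpy().sum())
print(f"significant protein-phenotype correlations at p<0.05: {n_sig} "
      f"of {result['r'].size} (two are planted, the rest are chance)")

# shear-force ANOVA on replicate-level measurements
rng = np.random.default_rng(0)
records = [
    WBSRecord(f"An{a}", "F" if a < 4 else "M", day, rep,
              38.0 + rng.normal(0, 2) + (-11.0 if day == 26 else 0.0) + a * 0.5)
    for a in range(8) for day in (12, 26) for rep in range(5)
]
res = cm.wbs_anova(records)
print(f"\naverage DWBS: {res.average_dwbs:.2f} N "
      "(negative = meat got more tender with aging)")
print(res.anova.round(4).to_string())
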