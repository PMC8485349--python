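"""Train a toroidal hexagonal SOM and inspect its top map.

The map groups similar samples onto the same or adjacent neurons.  Two
things are worth reading off: how well the two maturation stages
separate into distinct neuron regions, and whether technical
replicates of one biological sample co-locate (they should — the
instrumental variability is smaller than the biological one).
"""

import chemomark as cm
from chemomark.som import SOMConfig

dataset, _ = cm.synthesize(cm.SyntheticSpec(seed=5))
design = next(d for d in cm.DEFAULT_DESIGNS if d.name == "early")
sub, labels = cm.subset_for_design(dataset, design)
scaled = cm.autoscale(sub.values, sub.protein_ids)

model = cm.som_fit(scaled.values, SOMConfig(rows=8, cols=8, epochs=200, seed=0))
occupancy = cm.top_map(model, labels)

occupied = occupancy[~occupancy["empty"]]
purity = occupied[["n_0", "n_1"]].max(axis=1) / occupied["total"]
print(f"occupied neurons: {len(occupied)}/64, mean class purity: {purity.mean():.2f}")
print(f"final quantization error: {model.qe_trace[-1]:.3f} "
      "(mean distance of a sample to its winning neuron)")

D = model.grid.distance_matrix()
close = total = 0
for idx in sub.metadata.groupby(["animal_id", "timepoint"]).indices.values():
    a = model.assignments[idx]
    for i in range(len(a)):
        for j in range(i + 1, len(a)):
            total += 1
            close += D[a[i], a[j]] <= 1
print(f"replicate pairs on same/adjacent neurons: {100 * close / total:.1f}%")

# PCA of the neuron weights explains WHICH proteins organize the map
weights_pca, neuron_class = cm.pca_on_som_weights(model, n_components=2, labels=labels)
print(f"weight-space PCA: PC1 {weights_pca.explained_variance_pct[0]:.1f}%, "
      f"PC2 {weights_pca.explained_variance_pct[1]:.1f}% of neuron variance; "
      f"{(neuron_class == 'empty').sum()} empty neurons")
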