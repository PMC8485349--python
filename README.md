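# chemomark

Chemometric biomarker discovery for label-free proteomics abundance
matrices.

`chemomark` is aimed at proteomics and metabolomics practitioners who
have a complete samples × proteins quantification matrix (e.g. from
SWATH-type data-independent acquisition) for a small longitudinal
animal study and want to find which proteins discriminate between
conditions.  Its reference use case is meat-maturation proteomics — a
cohort of animals sampled at successive aging timepoints, each
biological sample measured in technical replicates — but nothing in the
code is specific to muscle.

The pipeline combines four classical chemometric stages:

1. **Univariate screening** — per-protein two-sample Student's t-test
   with a dual rule: a protein is dysregulated when *p* < 0.05 **and**
   its fold change FC = mean(class b)/mean(class a) is > 1.3 or
   < 0.769 (≈ 1/1.3).  No multiplicity correction is applied.
2. **PCA** after autoscaling (per-column mean 0, sample sd 1), for
   exploration and for interpreting SOM neuron weights.
3. **Kohonen self-organizing maps** — batch-trained on a hexagonal
   grid with toroidal boundary, learning rate decreasing linearly from
   0.5 to 0.01, Gaussian neighbourhood shrinking to winner-only.
   Similar samples land on the same or adjacent neurons; technical
   replicates co-locating on the map is the visual check that
   instrumental variability is below biological variability.
4. **PLS-DA with VIP-driven backward elimination** — a two-class PLS1
   model of the centered −1/+1 class indicator; at each step the
   variable with the lowest VIP score,

   VIP_j = √( p · Σ_a SSY_a w_ja² / Σ_a SSY_a ),  SSY_a = q_a² tᵀ_a t_a,

   is removed, and every candidate panel is validated by repeated
   leave-more-out cross-validation (5 random cancellation groups of
   20% of the samples, repeated up to 1000 times), reporting
   accuracy %, non-error rate %, sensitivity, specificity and
   precision.  The panel with the best cross-validated accuracy is the
   biomarker signature.

A synthetic-data generator (`chemomark.synthetic`) produces abundance
matrices with the same statistical structure — log-normal abundances,
animal/timepoint/gender effects, biological > technical variance,
planted fold changes, phenotype variables with chosen correlations —
plus the exact ground truth, so recovery of planted biomarkers is
testable end to end.

## Worked example

```bash
python examples/plsda_selection.py
```

```
selected 7 of 40 proteins with 1 latent variable(s)
planted proteins recovered: 5/5
cross-validated accuracy 84.69%  non-error rate 84.69%
fitting accuracy 90.62%

last elimination steps (CV accuracy per panel size):
 n_vars  n_lv  cv_accuracy_pct removed
      6     1         81.87500    P013
      5     1         81.96875    P016
      4     1         76.90625    P035
      3     1         76.62500    P007
      2     2         78.09375    P030
      1     1         77.25000    None
```

The run plants 5 discriminant proteins (fold change 1.6) among 40 in a
32-sample two-timepoint design.  Backward elimination keeps a 7-protein
panel containing all 5 planted ones; the cross-validated accuracy
(84.7%) is honestly below the fitting accuracy (90.6%) because every
fold re-autoscales and refits without the held-out samples.  The other
scripts in `examples/` demonstrate the generator, the univariate
screen, the SOM top map, phenotype correlation + shear-force ANOVA, and
the full four-comparison pipeline with Venn-style overlap counts.

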