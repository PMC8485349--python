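# Methods

This note records the statistical model behind each stage, the default
parameters and why they were chosen, what the synthetic generator does
and does not emulate, and the numerical conventions that make runs
reproducible.

## Synthetic abundance model

Abundances are log-normal: effects are additive on the natural-log
scale and exponentiated,

    x[s,p] = exp( base_p + animal_a + timepoint_{p,t} + gender_{p,g}
                  + bio_{b,p} + tech_{s,p} )

* `base_p ~ N(9.0, 1.2²)` gives each protein a baseline intensity with
  a realistic dynamic range of a few orders of magnitude (arbitrary
  intensity units; only ratios matter downstream).
* Noise standard deviations on the log scale derive from the requested
  coefficients of variation through the log-normal identity
  `σ = sqrt(log(1+CV²))`, so the natural-scale CV is exact.
* Defaults: biological CV 0.30, technical CV 0.10, animal CV 0.10 —
  label-free quantification typically shows technical CVs near or
  below 10% and animal-to-animal biological spread several-fold
  larger; the generator enforces technical < biological.
* Planted effects are monotone across timepoints: a planted protein's
  biological mean is multiplied by `planted_fc` (or divided, for the
  alternating down-regulated half) at each successive timepoint, so
  every pairwise contrast carries a controlled fold change and the
  ground truth can state the exact log fold change per contrast.
  Fold changes act on biological means; technical replicates resample
  only technical noise around their biological sample.
* The default layout mirrors the emulated study: 8 animals (4 heifers,
  4 bulls) × 3 timepoints (t0, t12, t26) × 3 technical replicates with
  one female t12 biological sample discarded → 69 rows (24/21/24) over
  137 proteins.  Discarding is applied after all noise is drawn, so
  changing the discard list does not reshuffle the surviving samples.
* Phenotypes are built per biological sample as
  `r·z + sqrt(1−r²)·ε` with `z` the standardized biological mean log
  abundance of the linked protein and `ε` standardized noise
  orthogonalized against `z`; the achieved correlation is exact in
  expectation and attenuates only when correlating against
  replicate-level data.

What the generator does **not** emulate: missing values (the emulated
matrices are complete), peptide-level roll-up, identification FDR,
heteroscedastic technical noise, and protein–protein correlation
beyond what the shared animal/timepoint effects induce.  Passing tests
therefore show the pipeline recovers planted structure of this kind;
they do not certify behaviour under missingness or strong unmodelled
correlation.

## Univariate stage

The screen uses the pooled-variance Student's t-test (Welch available
via `equal_var=False`) on raw abundances at technical-replicate level,
with FC computed from raw class means.  Both FC thresholds (1.3, 0.769)
are independent strict inequalities; 0.769 ≈ 1/1.3 but the two are kept
as separate parameters.  No multiple-testing correction is applied —
the screen is deliberately a simple dual filter, and the null
calibration test verifies its per-protein type-I rate.  FC is defined
as later/earlier class so that "up" means more abundant with aging.

Phenotype correlation uses Pearson r with the exact two-sided p from
`t = r√(n−2)/√(1−r²)`.  The shear-force summary runs a two-way
fixed-effects ANOVA (animal, aging day, interaction) on replicate-level
values via statsmodels OLS/anova_lm; when an effect is significant,
standard Tukey HSD comparisons are reported (the sequential "Tukey b"
variant is not available in mainstream libraries; HSD is the documented
substitution).  Per-animal DWBS is mean(late) − mean(early) with the
two-group pooled standard deviation.

## PCA

SVD on the (centered) matrix; components ordered by decreasing
variance; each component's sign is fixed so its largest-magnitude
loading is positive, making results deterministic.  For SOM weights
the neurons × variables matrix is centered but not re-autoscaled —
the weights already live in autoscaled data space, and rescaling them
would distort the relative importance the training assigned to each
protein.

## Self-organizing map

Hexagonal toroidal lattice in odd-row offset coordinates; both grid
dimensions must be even, otherwise the hexagonal adjacency cannot wrap
consistently.  Grid distances are computed from cube coordinates under
minimal-image wrap-around (minimum over the 3×3 shifted images); the
test suite checks them against BFS shortest paths over the wrapped
adjacency graph.

Training is the batch algorithm blended with a learning rate: each
epoch assigns all samples to their nearest neuron (ties → lowest
index), computes each neuron's kernel-weighted mean target with
Gaussian kernel `h = exp(−d²/2σ²)` in grid distance from the winner,
and updates `w ← (1−α)w + α·target`.  The classical batch SOM has no
learning rate; the linear 0.5 → 0.01 schedule is honoured as this
convex blend.  σ decreases linearly from `neighborhood_start` (default
half the larger grid dimension) to 0, so the final epochs are
winner-only; with radius 0 and α = 1 one epoch is exactly one k-means
Lloyd step, which the tests exploit as an oracle.  Neurons with zero
kernel mass keep their weights for that epoch.  Weights initialize
uniformly within each variable's data range from the seeded generator.
Presets: 10×10 / 300 epochs for the pooled (three-timepoint)
comparison, 8×8 / 200 for pairwise ones.

## PLS-DA and VIP

PLS1 NIPALS on autoscaled X against the centered −1/+1 class
indicator; classes are coded symmetrically so a positive coefficient
reads as "more abundant in the later class".  Prediction threshold is
0; an exact tie is assigned to class a and flagged.  Coefficients are
reconstructed as `b = W(PᵀW)⁻¹q`, which the tests verify against OLS
at full rank and against scikit-learn's PLS at reduced rank.  VIP uses
the standard Wold formulation with `SSY_a` the class-membership
variance explained per latent variable; the mean of squared VIPs is
exactly 1.  Explained-variance percentages for the response are
computed on the **centered** indicator (the uncentered alternative
would change only the reported %, not selection).

## Cross-validation and backward elimination

Leave-more-out: each repeat partitions samples into 5 random disjoint
groups of ~20% (remainder spread one per group), each group held out
once.  Autoscaling and indicator centering are recomputed on each
training fold only — the defensible no-leakage default, flagged
because legacy toolboxes sometimes scale once globally.  Constant
columns inside a training fold are left unscaled (sd set to 1): they
carry no information and must not abort a fold.  Per repeat the folds'
held-out predictions cover every sample exactly once and are pooled;
metrics are then averaged over repeats.  A repeat whose training folds
would be single-class is redrawn (error after 100 failures).  The
default repeat count is 1000; tests and examples run 20–100 repeats,
which widens the Monte-Carlo error of the reported accuracy by a known
√(1000/n) factor and changes nothing structurally.

Technical replicates are treated as independent samples by default,
matching the replicate-level sample counts used throughout; a
group-aware mode (`groups=` / `replicate_aware_cv`) keeps all
replicates of a biological sample in one cancellation group and is
recommended whenever honest generalization to new biological samples
is the question — replicate-level CV is optimistic because sibling
replicates of a held-out sample remain in training.

`select_n_lv` evaluates all LV counts 1..max in a single CV pass
(PLS components are nested, so per-count predictions come from one
fit); ties prefer fewer LVs.  Backward elimination at each step
re-selects the LV count by CV, logs the panel's CV metrics, ranks
variables by VIP from a full-data fit (cheaper than CV-averaged VIP
and faithful to the single-removal-per-iteration description), and
removes the single lowest-VIP variable (ties → first index), running
to exhaustion (one variable) rather than stopping at the first error
increase — the full trace lets users apply any stopping rule
afterwards.  CV groups are re-randomized each step from a per-step
seed derived from the scheme seed, so any step — including the final
selected panel — replays bitwise.  The selected panel is the step with
the highest mean CV accuracy, ties → fewest variables.

Two behaviours of this protocol are worth knowing:

* **Replicate-level CV saturates.**  With technical replicates split
  randomly, strong planted effects drive many panels to exactly 100%
  CV accuracy; the fewest-variables tie rule then returns a minimal
  panel that need not contain every truly discriminant protein.  The
  recovery tests therefore use independent biological samples (24 per
  class, biological CV 0.4), the regime where no single planted
  protein separates the classes and selection is informative.
* **CV on null data is slightly pessimistic.**  The fold intercept
  follows the training majority while the held-out group is enriched
  the other way, so permuted-label accuracy sits a little below 50%
  at small n; the calibration test averages fresh permutations and
  checks the 50% ± 5 band.
* **Parsimony in LV count emerges only when the first weight vector is
  clean.**  The first PLS weight vector picks up noise covariances at
  rate √((p−1)/n), so with a single informative variable among many
  noise variables extra LVs genuinely help in CV; the 1-LV-preferred
  test uses p = 3, n = 100 where that contamination is negligible.

## Pipeline

`run_comparison` chains subset → univariate screen → autoscale → PCA →
SOM (+ weight PCA with per-neuron class annotation, empty neurons
flagged) → backward elimination.  A master seed fans out to per-stage
seeds via `SeedSequence(entropy=seed, spawn_key=(crc32(design), stage))`,
so each stage is independently re-runnable.  All artifacts serialize
to TSV/JSON under one run directory.  Problem sizes in the examples
and the acceptance script (40–137 proteins, 20–100 CV repeats, 10–20
recovery seeds) are chosen so a full run completes in minutes on one
core; raising `n_repeats` to 1000 reproduces the full validation
protocol unchanged.

## Known limitations

* The univariate screen's uncorrected p-values are a screening device,
  not inference; with 137 proteins ~7 false positives are expected per
  null comparison by construction.
* SOM results are seed- and kernel-dependent; only topological
  properties (cluster separation, replicate co-location) are stable
  across seeds, not individual neuron placements.
* Backward elimination run to exhaustion costs O(p) CV passes; for
  thousands of variables a pre-screen or batched removal would be
  needed.
* Two-class designs only; the multi-timepoint comparison is handled as
  first-vs-rest, not multiclass PLS2.
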