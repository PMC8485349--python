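"""Tests of the synthetic abundance generator and its ground truth."""

import numpy as np
import pandas as pd
import pytest

import chemomark as cm
from chemomark.synthetic import SyntheticSpec, synthesize, synthesize_phenotypes


class TestSpecValidation:
    @pytest.mark.parametrize(
        "kwargs, match",
        [
            ({"n_proteins": 0}, "n_proteins"),
            ({"n_discriminant": 200, "n_proteins": 10}, "n_discriminant"),
            ({"planted_fc": -2.0}, "planted_fc"),
            ({"technical_cv": 0.5, "biological_cv": 0.2}, "technical_cv"),
            ({"gender_affected": {999: 1.5}}, "gender_affected"),
            ({"phenotype_links": [("t", 999, 0.5)]}, "phenotype_links"),
            ({"phenotype_links": [("t", 0, 1.5)]}, "phenotype_links"),
            ({"genders": ("F", "M")}, "genders"),
        ],
    )
    def test_invalid_fields_name_the_field(self, kwargs, match):
        with pytest.raises(ValueError, match=match):
            SyntheticSpec(**kwargs)


class TestSynthesize:
    def test_default_design_row_counts(self, default_dataset):
        """8 animals x 3 timepoints x 3 reps minus one discarded t12
        biological sample -> 69 rows split 24/21/24."""
        _, dataset, _ = default_dataset
        assert dataset.n_samples == 69
        counts = dataset.timepoints.value_counts()
        assert counts["t0"] == 24 and counts["t12"] == 21 and counts["t26"] == 24
        assert dataset.n_proteins == 137

    def test_reproducible_bitwise(self):
        a, _ = synthesize(SyntheticSpec(seed=3))
        b, _ = synthesize(SyntheticSpec(seed=3))
        assert a.sample_ids == b.sample_ids
        assert np.array_equal(a.values, b.values)
        c, _ = synthesize(SyntheticSpec(seed=4))
        assert not np.array_equal(a.values, c.values)

    def test_no_effects_no_noise_gives_constant_columns(self):
        spec = SyntheticSpec(
            n_discriminant=0, biological_cv=0.0, technical_cv=0.0, animal_cv=0.0
        )
        dataset, _ = synthesize(spec)
        assert np.all(dataset.values.std(axis=0) < 1e-12 * dataset.values.mean(axis=0))

    def test_planted_fold_change_recovered_at_large_n(self):
        """Monte-Carlo check of the generator against its own model:
        with planted_fc=2.0 the empirical ratio of class means is
        within 10% of 2.0 at n_animals=200."""
        spec = SyntheticSpec(
            n_animals=200,
            timepoints=("t0", "t12"),
            n_proteins=10,
            n_discriminant=2,
            planted_fc=2.0,
            discarded_samples=(),
            seed=11,
        )
        dataset, truth = synthesize(spec)
        up = [p for p in truth.discriminant["t0_vs_t12"] if truth.log_fc.loc[p, "t0_vs_t12"] > 0]
        frame = dataset.to_frame()
        tp = dataset.timepoints
        for p in up:
            ratio = frame.loc[tp == "t12", p].mean() / frame.loc[tp == "t0", p].mean()
            assert ratio == pytest.approx(2.0, rel=0.10)

    def test_ground_truth_discriminant_matches_nonzero_logfc(self):
        spec = SyntheticSpec(n_discriminant=10, seed=5)
        _, truth = synthesize(spec)
        for contrast in truth.log_fc.columns:
            nonzero = set(truth.log_fc.index[truth.log_fc[contrast].abs() > 0])
            assert truth.discriminant[contrast] == nonzero
            assert len(nonzero) == 10

    def test_positive_abundances(self, default_dataset):
        _, dataset, _ = default_dataset
        assert np.all(dataset.values > 0)

    def test_technical_spread_below_biological(self, default_dataset):
        """Per-protein variance among technical replicates of one
        biological sample stays below the variance among biological
        samples, in aggregate."""
        _, dataset, _ = default_dataset
        log = np.log(dataset.to_frame())
        keys = [dataset.metadata["animal_id"], dataset.metadata["timepoint"]]
        tech_var = log.groupby(keys).var(ddof=1).mean().mean()
        bio_var = log.groupby(keys).mean().var(ddof=1).mean()
        assert tech_var < bio_var


class TestPhenotypes:
    def test_perfect_link_is_affine(self):
        """Target r = 1 with no noise: the phenotype is an affine
        transform of the linked protein's biological log abundance."""
        spec = SyntheticSpec(
            n_proteins=5, n_discriminant=0, phenotype_links=[("tenderness", 0, 1.0)], seed=2
        )
        dataset, _ = synthesize(spec)
        phen = synthesize_phenotypes(dataset, spec)
        bio = (
            np.log(dataset.to_frame())
            .groupby([dataset.metadata["animal_id"], dataset.metadata["timepoint"]], sort=True)
            .mean()
        )
        x = bio.iloc[:, 0].to_numpy()
        y = phen["tenderness"].to_numpy()
        r = np.corrcoef(x, y)[0, 1]
        assert r == pytest.approx(1.0, abs=1e-10)

    def test_target_r_achieved(self):
        spec = SyntheticSpec(
            n_animals=40,
            phenotype_links=[("shear", 3, -0.8)],
            discarded_samples=(),
            seed=8,
        )
        dataset, _ = synthesize(spec)
        phen = synthesize_phenotypes(dataset, spec)
        bio = (
            np.log(dataset.to_frame())
            .groupby([dataset.metadata["animal_id"], dataset.metadata["timepoint"]], sort=True)
            .mean()
        )
        r = np.corrcoef(bio.iloc[:, 3], phen["shear"])[0, 1]
        assert r == pytest.approx(-0.8, abs=0.05)

    def test_zero_link_gives_near_zero_correlation(self):
        """r = 0 links stay uncorrelated: |achieved r| < 0.2 at n = 24
        in at least 95% of seeds."""
        ok = 0
        n_runs = 60
        for seed in range(n_runs):
            spec = SyntheticSpec(
                n_animals=8,
                phenotype_links=[("null", 1, 0.0)],
                discarded_samples=(),
                seed=seed,
            )
            dataset, _ = synthesize(spec)
            phen = synthesize_phenotypes(dataset, spec)
            bio = (
                np.log(dataset.to_frame())
                .groupby(
                    [dataset.metadata["animal_id"], dataset.metadata["timepoint"]],
                    sort=True,
                )
                .mean()
            )
            r = np.corrcoef(bio.iloc[:, 1], phen["null"])[0, 1]
            ok += abs(r) < 0.2
        assert ok / n_runs >= 0.95

    def test_disjoint_links_block_diagonal(self):
        """Phenotypes linked to disjoint proteins correlate with their
        own protein but not (beyond noise) with the other's."""
        spec = SyntheticSpec(
            n_animals=60,
            phenotype_links=[("a", 0, 0.9), ("b", 5, 0.9)],
            discarded_samples=(),
            seed=13,
        )
        dataset, _ = synthesize(spec)
        phen = synthesize_phenotypes(dataset, spec)
        bio = (
            np.log(dataset.to_frame())
            .groupby([dataset.metadata["animal_id"], dataset.metadata["timepoint"]], sort=True)
            .mean()
        )
        r_own_a = np.corrcoef(bio.iloc[:, 0], phen["a"])[0, 1]
        r_own_b = np.corrcoef(bio.iloc[:, 5], phen["b"])[0, 1]
        r_cross = np.corrcoef(bio.iloc[:, 5], phen["a"])[0, 1]
        assert r_own_a > 0.8 and r_own_b > 0.8
        assert abs(r_cross) < 0.3

    def test_unknown_protein_link_raises(self):
        spec = SyntheticSpec(n_proteins=5, n_discriminant=0, phenotype_links=[("t", 2, 0.5)], seed=1)
        dataset, _ = synthesize(spec)
        dataset.protein_ids[2] = "renamed"
        with pytest.raises(ValueError, match="unknown protein"):
            synthesize_phenotypes(dataset, spec)

    def test_spec_roundtrips_through_json(self):
        spec = SyntheticSpec(phenotype_links=(("t", 2, 0.5),), gender_affected={1: 1.4})
        again = SyntheticSpec.from_json(spec.to_json())
        assert again == spec
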