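"""Tests of classification metrics, repeated leave-more-out CV,
LV-count selection and backward elimination."""

import numpy as np
import pytest

import chemomark as cm
from chemomark.selection import (
    CVScheme,
    backward_eliminate,
    classification_metrics,
    repeated_cv,
    select_n_lv,
    _partition,
)


def _balanced_null_data():
    """48 balanced samples over 30 uninformative variables."""
    rng = np.random.default_rng(1)
    X = rng.normal(size=(48, 30))
    y = np.array([0, 1] * 24)
    return X, y


class TestMetrics:
    def test_perfect_prediction(self):
        y = np.array([0, 0, 1, 1, 1])
        m = classification_metrics(y, y)
        assert m.accuracy_pct == 100.0 and m.ner_pct == 100.0
        assert m.sensitivity == {0: 1.0, 1: 1.0}
        assert m.precision == {0: 1.0, 1: 1.0}

    def test_counts_from_confusion_table(self):
        """Confusion table [[10, 0], [2, 8]] (rows true 0/1): accuracy
        90%, class-1 sensitivity 0.8, specificity 1.0, precision 1.0."""
        true = np.array([0] * 10 + [1] * 10)
        pred = np.array([0] * 10 + [0, 0] + [1] * 8)
        m = classification_metrics(true, pred)
        assert m.accuracy_pct == pytest.approx(90.0)
        assert m.sensitivity[1] == pytest.approx(0.8)
        assert m.specificity[1] == pytest.approx(1.0)
        assert m.precision[1] == pytest.approx(1.0)

    def test_majority_vote_on_imbalanced_split(self):
        """Always-predict-majority on a 60/40 split: accuracy 60%, NER 50%."""
        true = np.array([0] * 60 + [1] * 40)
        pred = np.zeros(100, dtype=int)
        m = classification_metrics(true, pred)
        assert m.accuracy_pct == pytest.approx(60.0)
        assert m.ner_pct == pytest.approx(50.0)

    def test_absent_class_flagged_nan(self):
        m = classification_metrics(np.zeros(5, dtype=int), np.zeros(5, dtype=int))
        assert np.isnan(m.sensitivity[1])

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="equal length"):
            classification_metrics([0, 1], [0])


class TestScheme:
    def test_partition_covers_disjointly(self):
        rng = np.random.default_rng(0)
        for n in (45, 48, 69, 7):
            folds = _partition(rng, n, 5)
            allidx = np.concatenate(folds)
            assert len(allidx) == n and len(set(allidx.tolist())) == n
            sizes = sorted(len(f) for f in folds)
            assert max(sizes) - min(sizes) <= 1

    def test_invalid_scheme(self):
        with pytest.raises(ValueError, match="partition"):
            CVScheme(n_groups=5, test_fraction=0.25)


class TestRepeatedCV:
    def test_separable_classes_near_perfect(self, two_cluster_matrix):
        X, y = two_cluster_matrix
        s = repeated_cv(X, y, 1, CVScheme(n_repeats=50, seed=0))
        assert s.metrics.accuracy_pct >= 99.0

    def test_deterministic_given_seed(self, two_cluster_matrix):
        X, y = two_cluster_matrix
        a = repeated_cv(X, y, 2, CVScheme(n_repeats=20, seed=5))
        b = repeated_cv(X, y, 2, CVScheme(n_repeats=20, seed=5))
        assert np.array_equal(a.per_repeat_accuracy_pct, b.per_repeat_accuracy_pct)
        assert a.metrics.accuracy_pct == b.metrics.accuracy_pct

    def test_permuted_labels_near_chance(self):
        """Freshly permuted balanced labels: mean CV accuracy 50% +/- 5%
        over many shuffles (CV on null data is slightly pessimistic
        because the fold intercept follows the training majority)."""
        X, y = _balanced_null_data()
        rng = np.random.default_rng(9)
        accs = [
            repeated_cv(X, rng.permutation(y), 2, CVScheme(n_repeats=5, seed=s)).metrics.accuracy_pct
            for s in range(100)
        ]
        assert np.mean(accs) == pytest.approx(50.0, abs=5.0)

    def test_group_aware_split_keeps_replicates_together(self):
        rng = np.random.default_rng(3)
        n_bio = 15
        groups = np.repeat(np.arange(n_bio), 3)
        X = rng.normal(size=(n_bio * 3, 4))
        y = np.repeat(np.array([0, 1] * 8)[:n_bio], 3)
        X[y == 1] += 3.0
        s = repeated_cv(X, y, 1, CVScheme(n_repeats=10, seed=4), groups=groups)
        assert s.metrics.accuracy_pct >= 99.0  # still separable at group level


class TestSelectNLV:
    def test_single_informative_variable_prefers_one_lv(self):
        """One strongly informative variable plus pure noise: the 1-LV
        model wins in >= 90% of seeds.  The first weight vector picks up
        noise covariances at rate sqrt((p-1)/n), so parsimony emerges
        once that contamination is negligible; extra LVs then tie and
        the fewest-LV rule applies."""
        hits, n_runs = 0, 30
        for seed in range(n_runs):
            rng = np.random.default_rng(1000 + seed)
            y = np.array([0] * 50 + [1] * 50)
            X = rng.normal(size=(100, 3))
            X[:, 0] += np.where(y == 1, 5.0, -5.0)
            best = select_n_lv(X, y, CVScheme(n_repeats=20, seed=seed), max_lv=3)
            hits += best == 1
        assert hits / n_runs >= 0.9

    def test_max_lv_one(self, two_cluster_matrix):
        X, y = two_cluster_matrix
        assert select_n_lv(X, y, CVScheme(n_repeats=10, seed=0), max_lv=1) == 1

    def test_cap_by_sample_count(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(4, 10))
        y = np.array([0, 0, 1, 1])
        best = select_n_lv(X, y, CVScheme(n_groups=2, test_fraction=0.5, n_repeats=5, seed=0), max_lv=9)
        assert best <= 3  # bounded by n - 1


class TestBackwardElimination:
    def test_indicator_variable_selected(self):
        """Two variables, one exactly the class indicator: the panel is
        that variable alone."""
        y = np.array([0] * 10 + [1] * 10)
        rng = np.random.default_rng(6)
        X = np.column_stack([np.where(y == 1, 1.0, -1.0), rng.normal(size=20)])
        tr = backward_eliminate(
            X, y, CVScheme(n_repeats=20, seed=0), max_lv=1, variable_ids=["ind", "noise"]
        )
        assert tr.selected_set == ["ind"]
        assert tr.final_cv.metrics.accuracy_pct == 100.0

    def test_trace_bookkeeping(self, two_cluster_matrix):
        X, y = two_cluster_matrix
        tr = backward_eliminate(X, y, CVScheme(n_repeats=10, seed=1), max_lv=2)
        steps = tr.steps
        # one step per removal down to a single variable
        assert steps["n_vars"].tolist() == list(range(X.shape[1], 0, -1))
        removed = steps["removed"].dropna().tolist()
        assert len(set(removed)) == len(removed)  # never re-added
        assert set(removed) | set(tr.selected_set) >= {f"var{i}" for i in range(X.shape[1])}
        best = steps.loc[tr.best_step]
        assert best["cv_accuracy_pct"] == steps["cv_accuracy_pct"].max()

    def test_trace_replay_bitwise(self, two_cluster_matrix):
        """Re-running CV on the selected panel with the logged step seed
        reproduces the final metrics exactly."""
        X, y = two_cluster_matrix
        tr = backward_eliminate(X, y, CVScheme(n_repeats=10, seed=2), max_lv=2)
        idx = [int(v[3:]) for v in tr.selected_set]
        scheme = CVScheme(n_repeats=10, seed=tr.selected_step_seed)
        replay = repeated_cv(X[:, idx], y, tr.final_cv.n_lv, scheme)
        assert replay.metrics.accuracy_pct == tr.final_cv.metrics.accuracy_pct
        assert np.array_equal(
            replay.per_repeat_accuracy_pct, tr.final_cv.per_repeat_accuracy_pct
        )
        logged = tr.steps.loc[tr.best_step, "cv_accuracy_pct"]
        assert replay.lv_accuracy_curve[tr.final_cv.n_lv - 1] == logged

    def test_selected_beats_full_model(self):
        """On a planted-signal fixture the selected panel's CV accuracy
        is at least the all-variables model's (within one standard
        error over repeats)."""
        rng = np.random.default_rng(7)
        y = np.array([0] * 20 + [1] * 20)
        X = rng.normal(size=(40, 30))
        X[:, :3] += np.where(y == 1, 1.0, -1.0)[:, None]
        scheme = CVScheme(n_repeats=50, seed=3)
        tr = backward_eliminate(X, y, scheme, max_lv=3)
        full = repeated_cv(X, y, 3, CVScheme(n_repeats=50, seed=99))
        se = full.accuracy_sd_pct / np.sqrt(50)
        assert tr.steps.loc[tr.best_step, "cv_accuracy_pct"] >= full.metrics.accuracy_pct - se

    def test_needs_two_variables(self):
        with pytest.raises(ValueError, match="2 variables"):
            backward_eliminate(
                np.ones((10, 1)), np.array([0, 1] * 5), CVScheme(n_repeats=2, seed=0), 1
            )
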