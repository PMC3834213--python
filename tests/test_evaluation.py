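import numpy as np
import pytest
from scipy import stats

from elmcortex import (
    CohortSpec,
    ConstantClassifier,
    ELMClassifier,
    ELMConfig,
    FeatureTable,
    ValidationError,
    bayes_rule_scores,
    generate_cohort,
    loocv,
    normalize_minmax,
    paired_comparison,
    permutation_test,
    roc_curve,
    sample_size_sweep,
    theoretical_bayes_accuracy,
)
from elmcortex.schema import generic_descriptors

from conftest import random_table


class NearestCentroid:
    """Simple deterministic classifier used as a stub contract."""

    stochastic = False
    name = "centroid"

    def fit(self, X, y, seed):
        mu_pos = X[y == 1].mean(axis=0)
        mu_neg = X[y == -1].mean(axis=0)

        class _F:
            def scores(self, Xt):
                Xt = np.atleast_2d(np.asarray(Xt, float))
                return (np.linalg.norm(Xt - mu_neg, axis=1)
                        - np.linalg.norm(Xt - mu_pos, axis=1))

            def predict(self, Xt):
                return np.where(self.scores(Xt) >= 0, 1, -1)

        return _F()


class TestLOOCV:
    def test_one_fold_per_subject(self):
        t = random_table(np.random.default_rng(0), n=10, d=4)
        res = loocv(t, [1, 2], NearestCentroid())
        ev = res["centroid"]
        assert len(ev.fold_predictions) == 10
        assert len(ev.fold_scores) == 10

    def test_constant_classifier_scores_class_prevalence(self):
        t = random_table(np.random.default_rng(1), n=12, d=3)
        res = loocv(t, [1], ConstantClassifier(label=1))
        assert res["constant"].test_acc == pytest.approx(50.0)

    def test_fold_isolation_from_held_out_label(self):
        """Flipping the held-out subject's label must not change that
        fold's prediction (no leakage)."""
        t = random_table(np.random.default_rng(2), n=10, d=4)
        res = loocv(t, [1, 2, 3], NearestCentroid())
        flipped = t.with_labels(
            np.concatenate([[-t.labels[0]], t.labels[1:]]))
        res2 = loocv(flipped, [1, 2, 3], NearestCentroid())
        assert res["centroid"].fold_predictions[0] == \
            res2["centroid"].fold_predictions[0]

    def test_empty_subset_rejected(self):
        t = random_table(np.random.default_rng(3))
        with pytest.raises(ValidationError):
            loocv(t, [], NearestCentroid())

    def test_elm_folds_reseeded_but_run_reproducible(self):
        t = random_table(np.random.default_rng(4), n=14, d=5)
        clf = ELMClassifier(ELMConfig(n_hidden=10))
        a = loocv(t, [1, 2, 3], clf, seed=5)
        b = loocv(t, [1, 2, 3], clf, seed=5)
        assert np.array_equal(a["elm"].fold_scores, b["elm"].fold_scores)

    def test_elm_approaches_bayes_accuracy_on_large_cohort(self):
        """The exact likelihood-ratio rule evaluated through the LOOCV
        machinery approaches the closed-form Bayes accuracy."""
        spec = CohortSpec(n_patients=200, n_controls=200, effect_size=1.0,
                          within_region_correlation=0.3, seed=6)
        table = generate_cohort(spec)

        class BayesRule:
            stochastic = False
            name = "bayes"

            def fit(self, X, y, seed):
                outer_spec = spec

                class _F:
                    def scores(self, Xt):
                        Xt = np.atleast_2d(np.asarray(Xt, float))
                        t = FeatureTable(Xt, np.ones(len(Xt), int),
                                         [f"x{i}" for i in range(len(Xt))],
                                         table.descriptors)
                        return bayes_rule_scores(outer_spec, t)

                    def predict(self, Xt):
                        return np.where(self.scores(Xt) >= 0, 1, -1)

                return _F()

        res = loocv(table, list(range(1, 341)), BayesRule())
        expected = 100 * theoretical_bayes_accuracy(spec)
        assert abs(res["bayes"].test_acc - expected) < 3.0


class TestROC:
    def test_perfect_separation_auc_1(self):
        labels = np.array([1, 1, 1, -1, -1, -1])
        rc = roc_curve([0.9, 0.8, 0.7, 0.3, 0.2, 0.1], labels)
        assert rc.auc == pytest.approx(1.0)

    def test_auc_equals_pairwise_rank_oracle(self):
        """Trapezoid AUC equals the normalized count of correctly
        ordered (patient, control) score pairs, ties half-weighted."""
        rng = np.random.default_rng(7)
        for _ in range(25):
            n = int(rng.integers(4, 15))
            labels = np.array([1, -1] * (n // 2) + [1] * (n % 2))
            scores = rng.integers(0, 5, size=len(labels)).astype(float)  # ties
            if len(set(labels)) < 2:
                continue
            rc = roc_curve(scores, labels)
            pos = scores[labels == 1]
            neg = scores[labels == -1]
            pairs = sum((1.0 if p > q else 0.5 if p == q else 0.0)
                        for p in pos for q in neg)
            assert rc.auc == pytest.approx(pairs / (len(pos) * len(neg)))

    def test_random_scores_auc_near_half(self):
        rng = np.random.default_rng(8)
        labels = np.array([1, -1] * 1000)
        rc = roc_curve(rng.normal(size=2000), labels)
        assert abs(rc.auc - 0.5) < 0.03

    def test_endpoints_and_monotonicity(self):
        rng = np.random.default_rng(9)
        scores = rng.normal(size=30)
        labels = np.array([1, -1] * 15)
        rc = roc_curve(scores, labels)
        assert rc.fpr[0] == 0 and rc.tpr[0] == 0
        assert rc.fpr[-1] == 1 and rc.tpr[-1] == 1
        assert np.all(np.diff(rc.fpr) >= 0)
        assert np.all(np.diff(rc.tpr) >= 0)

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            roc_curve([0.1, 0.2], np.array([1, 1]))


class TestPermutationTest:
    def test_p_is_one_over_nperm_plus_one_when_observed_beats_all(self):
        spec = CohortSpec(n_patients=8, n_controls=8, effect_size=4.0,
                          informative_indices=(1, 69, 137), seed=10)
        t = normalize_minmax(generate_cohort(spec))
        res = permutation_test(t, (1, 69, 137), NearestCentroid(),
                               n_perm=19, seed=0)
        assert res.observed_rate > res.null_rates.max()
        assert res.p_value == pytest.approx(1 / 20)

    def test_p_is_one_when_observed_below_all_nulls(self):
        class WrongWay(NearestCentroid):
            name = "wrong"

            def fit(self, X, y, seed):
                inner = super().fit(X, -y, seed)
                return inner

        spec = CohortSpec(n_patients=8, n_controls=8, effect_size=4.0,
                          informative_indices=(1, 69, 137), seed=11)
        t = normalize_minmax(generate_cohort(spec))
        res = permutation_test(t, (1, 69, 137), WrongWay(), n_perm=19, seed=0)
        assert res.p_value == 1.0

    def test_p_never_zero(self):
        spec = CohortSpec(n_patients=6, n_controls=6, effect_size=5.0,
                          informative_indices=(1,), seed=12)
        t = normalize_minmax(generate_cohort(spec))
        res = permutation_test(t, (1,), NearestCentroid(), n_perm=9, seed=1)
        assert res.p_value > 0.0


class TestPairedComparison:
    def test_identical_vectors_t0_p1(self):
        assert paired_comparison([70.0, 72.0, 68.0], [70.0, 72.0, 68.0]) == \
            (0.0, 1.0)

    def test_constant_nonzero_difference_reported_as_degenerate(self):
        t, p = paired_comparison([75.0, 76.0], [70.0, 71.0])
        assert t == np.inf and p == 0.0
        t, p = paired_comparison([70.0, 71.0], [75.0, 76.0])
        assert t == -np.inf and p == 0.0

    def test_matches_textbook_formula_on_random_vectors(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            a = rng.normal(70, 5, size=12)
            b = rng.normal(68, 5, size=12)
            d = a - b
            t_expect = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
            p_expect = 2 * stats.t.sf(abs(t_expect), len(d) - 1)
            t, p = paired_comparison(a, b)
            assert t == pytest.approx(t_expect, rel=1e-10)
            assert p == pytest.approx(p_expect, rel=1e-10)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            paired_comparison([1.0, 2.0], [1.0, 2.0, 3.0])


@pytest.fixture(scope="module")
def cohort():
    spec = CohortSpec(n_patients=20, n_controls=20, effect_size=2.0,
                      informative_indices=(1, 69), seed=14)
    return normalize_minmax(generate_cohort(spec))


class TestSampleSizeSweep:

    def test_full_size_equals_plain_loocv(self, cohort):
        clf = NearestCentroid()
        df = sample_size_sweep(cohort, (1, 69), clf, sizes=(40,), seed=3)
        direct = loocv(cohort, (1, 69), clf, seed=3 + 40 + 0)
        assert df.iloc[0]["test_acc"] == direct["centroid"].test_acc

    def test_subsets_are_balanced(self, cohort):
        captured = []

        class Recorder(NearestCentroid):
            name = "rec"

            def fit(self, X, y, seed):
                captured.append(np.sum(y == 1) - np.sum(y == -1))
                return super().fit(X, y, seed)

        sample_size_sweep(cohort, (1,), Recorder(), sizes=(10, 20), seed=0)
        # within each LOOCV fold the training set misses one subject, so
        # the imbalance is exactly +/-1 for a balanced sub-cohort
        assert set(captured) <= {-1, 1}

    def test_accuracy_variability_shrinks_with_size(self, cohort):
        clf = NearestCentroid()
        df = sample_size_sweep(cohort, (1, 69), clf, sizes=(6, 30),
                               seed=5, n_repeats=12)
        sd_small = df[df["size"] == 6]["test_acc"].std()
        sd_large = df[df["size"] == 30]["test_acc"].std()
        assert sd_large < sd_small

    def test_validation_errors(self, cohort):
        clf = NearestCentroid()
        with pytest.raises(ValidationError):
            sample_size_sweep(cohort, (1,), clf, sizes=(7,))
        with pytest.raises(ValidationError):
            sample_size_sweep(cohort, (1,), clf, sizes=(60,))
        unbalanced = FeatureTable(cohort.values[:-1], cohort.labels[:-1],
                                  cohort.subject_ids[:-1],
                                  cohort.descriptors)
        with pytest.raises(ValidationError):
            sample_size_sweep(unbalanced, (1,), clf, sizes=(10,))
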