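"""Pseudopopulation construction, distance geometry, classifiers and the
subsampled leave-one-trial-out decoder."""

import numpy as np
import pandas as pd
import pytest

import odorpop as op
from odorpop.decoding import (
    GaussianClassifier,
    KnnEcocClassifier,
    PopulationMatrix,
    build_pseudopopulation,
    compare_decoding_curves,
    cross_odour_distances,
    decode_accuracy,
    posthoc_grid,
)
from conftest import make_session, simple_trials


def _cluster_population(n_units=30, n_trials=19, sep=10.0, noise=1.0, seed=0,
                        base=20.0) -> PopulationMatrix:
    """Six well-separated Gaussian-count clusters, one per odour."""
    rng = np.random.default_rng(seed)
    classes = np.arange(3, 9)
    centres = {c: base + sep * rng.standard_normal(n_units) for c in classes}
    rows, labels = [], []
    for c in classes:
        for _ in range(n_trials):
            rows.append(np.clip(centres[c] + noise * rng.standard_normal(n_units), 0, None))
            labels.append(c)
    counts = np.rint(rows).astype(int)
    return PopulationMatrix(counts=counts, labels=np.array(labels),
                            unit_ids=[f"u{i}" for i in range(n_units)])


def _null_population(n_units=25, seed=0) -> PopulationMatrix:
    """Odour-independent Poisson counts (no class information)."""
    rng = np.random.default_rng(seed)
    rates = rng.uniform(1, 8, n_units)
    labels = np.repeat(np.arange(3, 9), 19)
    counts = rng.poisson(rates, size=(labels.size, n_units))
    return PopulationMatrix(counts=counts, labels=labels,
                            unit_ids=[f"u{i}" for i in range(n_units)])


class TestBuildPseudopopulation:
    def test_two_sessions_pool_columns(self):
        s1, _ = op.generate_session(op.control_preset(n_units=3, seed=1))
        s2, _ = op.generate_session(op.control_preset(n_units=4, seed=2))
        pop = build_pseudopopulation([s1, s2])
        assert pop.counts.shape == (114, 7)
        assert (np.bincount(pop.labels)[3:9] == 19).all()

    def test_counts_match_known_spikes(self):
        trials = simple_trials([3, 3, 4, 4], [10.0, 20.0, 30.0, 40.0])
        spikes = [10.1, 10.2, 10.3, 10.4, 10.49, 30.1, 30.6]
        s = make_session({"u0": spikes}, trials, duration=45.0)
        pop = build_pseudopopulation([s], n_trials=2)
        # odour 3: 5 spikes in [10, 10.5), 0 in [20, 20.5)
        # odour 4: 1 spike in [30, 30.5) (30.6 outside), 0 in [40, 40.5)
        assert pop.counts[:, 0].tolist() == [5, 0, 1, 0]
        assert pop.labels.tolist() == [3, 3, 4, 4]

    def test_insufficient_trials_named(self):
        trials = simple_trials([3, 4], [10.0, 20.0])
        s = make_session({"u0": []}, trials, duration=30.0)
        with pytest.raises(ValueError, match="trials of odour"):
            build_pseudopopulation([s], n_trials=2)


class TestCrossOdourDistances:
    def test_three_four_five_triangle(self):
        counts = np.array([[0, 0], [0, 0], [3, 4], [3, 4]])
        pop = PopulationMatrix(counts, np.array([3, 3, 4, 4]), ["a", "b"])
        summ = cross_odour_distances(pop)
        assert np.allclose(summ.distances["cross:3-4"], 5.0)
        assert np.allclose(summ.distances["within:3"], 0.0)

    def test_identical_vectors_flagged_degenerate(self):
        counts = np.ones((4, 3), dtype=int)
        pop = PopulationMatrix(counts, np.array([3, 3, 4, 4]), list("abc"))
        summ = cross_odour_distances(pop)
        assert summ.degenerate and summ.omnibus is None

    def test_column_permutation_invariance(self):
        pop = _cluster_population(n_units=8, n_trials=4, seed=3)
        perm = np.random.default_rng(0).permutation(8)
        pop2 = PopulationMatrix(pop.counts[:, perm], pop.labels,
                                [pop.unit_ids[i] for i in perm])
        s1, s2 = cross_odour_distances(pop), cross_odour_distances(pop2)
        for key in s1.distances:
            assert np.allclose(np.sort(s1.distances[key]), np.sort(s2.distances[key]))

    def test_group_sizes(self):
        pop = _null_population(n_units=6, seed=4)
        summ = cross_odour_distances(pop)
        assert len(summ.group_labels) == 6 + 15
        assert all(summ.distances[f"within:{c}"].size == 171 for c in range(3, 9))
        assert summ.distances["cross:3-4"].size == 361

    def test_separated_clusters_distinguish_all_odours(self):
        pop = _cluster_population(seed=5)
        summ = cross_odour_distances(pop)
        assert summ.omnibus.p < 1e-10
        grid = posthoc_grid(summ, range(3, 9))
        assert (grid["p"] < 0.05).all()


class TestGaussianClassifier:
    def test_likelihood_comparison_1d(self):
        """Classes at -5 and +5 with unit variance: the point 4 belongs to
        the +5 class."""
        rng = np.random.default_rng(0)
        X = np.concatenate([rng.normal(-5, 1, 50), rng.normal(5, 1, 50)])[:, None]
        y = np.array([3] * 50 + [4] * 50)
        clf = GaussianClassifier().fit(X, y)
        assert clf.predict([[4.0]])[0] == 4
        assert clf.predict([[-4.0]])[0] == 3

    def test_query_at_class_mean_wins(self):
        rng = np.random.default_rng(1)
        X = rng.normal(0, 1, (60, 2))
        X[30:] += 6.0
        y = np.array([3] * 30 + [4] * 30)
        clf = GaussianClassifier().fit(X, y)
        assert clf.predict([X[:30].mean(axis=0)])[0] == 3

    def test_equidistant_tie_goes_to_lowest_carbon(self):
        X = np.array([[-1.0], [-2.0], [-3.0], [1.0], [2.0], [3.0]])
        y = np.array([5, 5, 5, 7, 7, 7])
        clf = GaussianClassifier().fit(X, y)
        assert clf.predict([[0.0]])[0] == 5

    def test_nearest_mean_oracle_on_spherical_classes(self):
        """With equal spherical covariances the Gaussian classifier must
        agree with nearest-class-mean assignment."""
        rng = np.random.default_rng(2)
        means = {c: rng.uniform(-10, 10, 3) for c in range(3, 9)}
        X = np.concatenate([means[c] + rng.normal(0, 1, (40, 3)) for c in means])
        y = np.repeat(list(means), 40)
        clf = GaussianClassifier().fit(X, y)
        # force the shared spherical covariance so the oracle is exact
        import scipy.stats as st

        fitted_means = {c: X[y == c].mean(axis=0) for c in means}
        clf.dists_ = [st.multivariate_normal(fitted_means[c], np.eye(3)) for c in means]
        queries = rng.uniform(-12, 12, (200, 3))
        pred = clf.predict(queries)
        centre_matrix = np.stack([fitted_means[c] for c in means])
        oracle = np.array(list(means))[
            np.argmin(((queries[:, None, :] - centre_matrix) ** 2).sum(-1), axis=1)
        ]
        assert np.array_equal(pred, oracle)

    def test_insufficient_rows_per_class(self):
        X = np.random.default_rng(3).normal(size=(8, 4))
        y = np.array([3] * 4 + [4] * 4)
        with pytest.raises(ValueError, match="training rows"):
            GaussianClassifier().fit(X, y)


class TestKnnEcoc:
    def test_coincident_training_point_wins(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(-5, 5, (60, 2))
        y = np.repeat(np.arange(3, 9), 10)
        clf = KnnEcocClassifier(k=1).fit(X, y)
        assert clf.predict([X[17]])[0] == y[17]

    def test_two_separated_clusters_perfect(self):
        rng = np.random.default_rng(1)
        X = np.concatenate([rng.normal(0, 0.5, (30, 2)), rng.normal(8, 0.5, (30, 2))])
        y = np.array([3] * 30 + [4] * 30)
        clf = KnnEcocClassifier(k=3).fit(X[::2], y[::2])
        assert np.array_equal(clf.predict(X[1::2]), y[1::2])

    def test_duplicate_training_set_identical_predictions(self):
        # k = 1: duplicating the training set cannot change the nearest
        # neighbour (for k > 1 duplicates displace the k-th neighbour)
        rng = np.random.default_rng(2)
        X = rng.normal(size=(60, 3))
        y = np.repeat(np.arange(3, 9), 10)
        q = rng.normal(size=(20, 3))
        p1 = KnnEcocClassifier(k=1).fit(X, y).predict(q)
        p2 = KnnEcocClassifier(k=1).fit(np.vstack([X, X]), np.tile(y, 2)).predict(q)
        assert np.array_equal(p1, p2)

    def test_one_vs_one_learner_count(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(60, 2))
        y = np.repeat(np.arange(3, 9), 10)
        clf = KnnEcocClassifier(k=5).fit(X, y)
        assert len(clf.learners_) == 15

    def test_invalid_k(self):
        with pytest.raises(ValueError, match="k"):
            KnnEcocClassifier(k=0)


class TestDecodeAccuracy:
    def test_seeded_determinism(self):
        pop = _cluster_population(n_units=20, seed=6)
        c1 = decode_accuracy(pop, sizes=[10, 20], iters=40, seed=9)
        c2 = decode_accuracy(pop, sizes=[10, 20], iters=40, seed=9)
        assert np.array_equal(c1.outcomes, c2.outcomes)
        assert np.array_equal(c1.accuracy, c2.accuracy)

    def test_null_population_at_chance(self):
        """Odour-independent counts decode at 1/6 within 3 binomial SE.

        A single session's leave-one-trial-out accuracy carries dataset-level
        variance beyond the binomial component (the 114 trial outcomes share
        training sets), so the check pools replicate null populations.
        """
        iters, reps = 100, 5
        outcomes = []
        for rep in range(reps):
            pop = _null_population(n_units=30, seed=70 + rep)
            curve = decode_accuracy(pop, sizes=[30], iters=iters, seed=1 + rep)
            outcomes.append(curve.outcomes[0])
        acc = np.concatenate(outcomes).mean()
        se = np.sqrt((1 / 6) * (5 / 6) / (iters * reps))
        assert abs(acc - 1 / 6) <= 3 * se + 0.03  # + dataset-level slack

    def test_permuted_labels_at_chance(self):
        pop = _cluster_population(n_units=25, seed=8)
        rng = np.random.default_rng(0)
        pop_perm = PopulationMatrix(pop.counts, rng.permutation(pop.labels),
                                    pop.unit_ids)
        iters = 300
        curve = decode_accuracy(pop_perm, sizes=[25], iters=iters, seed=2)
        se = np.sqrt((1 / 6) * (5 / 6) / iters)
        assert abs(curve.accuracy[0] - 1 / 6) <= 3 * se

    def test_separable_clusters_high_accuracy_both_classifiers(self):
        pop = _cluster_population(seed=9)
        for clf in ("gaussian", "knn_ecoc"):
            curve = decode_accuracy(pop, classifier=clf, sizes=[20], iters=100, seed=3)
            assert curve.accuracy[0] >= 0.95
            assert curve.binom_p[0] < 1e-10

    def test_size_exceeding_population_rejected(self):
        pop = _cluster_population(n_units=15, seed=10)
        with pytest.raises(ValueError, match="sizes"):
            decode_accuracy(pop, sizes=[20], iters=5)

    def test_joint_pca_flag_changes_projection_but_not_law(self):
        pop = _cluster_population(n_units=20, seed=11)
        a = decode_accuracy(pop, sizes=[20], iters=60, seed=4, joint_pca=False)
        b = decode_accuracy(pop, sizes=[20], iters=60, seed=4, joint_pca=True)
        assert a.accuracy[0] >= 0.9 and b.accuracy[0] >= 0.9


class TestCompareCurves:
    def test_identical_curves_adjusted_p_one(self):
        pop = _cluster_population(n_units=20, seed=12)
        c = decode_accuracy(pop, sizes=[10, 20], iters=40, seed=5)
        comp = compare_decoding_curves(c, c)
        assert np.allclose(comp["p_adj"], 1.0)
        assert np.allclose(comp["diff"], 0.0)

    def test_perfect_vs_chance(self):
        sizes = np.array([10])
        perfect = np.ones((1, 500), dtype=bool)
        chance = np.zeros((1, 500), dtype=bool)
        chance[0, :83] = True
        a = op.DecodingCurve("gaussian", sizes, perfect, perfect.mean(1), 1 / 6,
                             np.array([0.0]), 0)
        b = op.DecodingCurve("gaussian", sizes, chance, chance.mean(1), 1 / 6,
                             np.array([0.5]), 0)
        comp = compare_decoding_curves(a, b)
        assert comp["p_adj"].iloc[0] < 1e-6

    def test_mismatched_sizes_rejected(self):
        pop = _cluster_population(n_units=20, seed=13)
        c1 = decode_accuracy(pop, sizes=[10], iters=10, seed=6)
        c2 = decode_accuracy(pop, sizes=[20], iters=10, seed=6)
        with pytest.raises(ValueError, match="sizes"):
            compare_decoding_curves(c1, c2)
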