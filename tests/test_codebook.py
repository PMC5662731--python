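"""Exemplar ensembles, max-projection, calibration, similarity, codebook."""

import itertools

import numpy as np
import pytest
from scipy.optimize import minimize

from graspkin.codebook import (
    CalibratedClassifier,
    ExemplarEnsemble,
    build_codebook,
    calibrate,
    exemplar_objective,
    max_project,
    pairwise_similarity,
    spectral_medoid_clustering,
    train_exemplar_ensemble,
)


def qp_oracle(x_pos, x_neg, C):
    """Independent solver for the exemplar objective: slack-variable QP
    via SLSQP on the equivalent constrained problem."""
    d = len(x_pos)
    n = len(x_neg)

    def unpack(z):
        return z[:d], z[d], z[d + 1], z[d + 2 :]

    def fun(z):
        w, b, xi0, xi = unpack(z)
        return w @ w + C * xi0 + C / n * xi.sum()

    cons = [
        {"type": "ineq", "fun": lambda z: unpack(z)[2]},
        {"type": "ineq",
         "fun": lambda z: unpack(z)[2] - 1 + unpack(z)[0] @ x_pos + unpack(z)[1]},
    ]
    for j in range(n):
        cons.append({"type": "ineq", "fun": lambda z, j=j: unpack(z)[3][j]})
        cons.append(
            {"type": "ineq",
             "fun": lambda z, j=j: unpack(z)[3][j]
             - 1 - unpack(z)[0] @ x_neg[j] - unpack(z)[1]}
        )
    z0 = np.zeros(d + 2 + n)
    res = minimize(fun, z0, constraints=cons, method="SLSQP",
                   options={"maxiter": 500, "ftol": 1e-10})
    w, b, _, _ = unpack(res.x)
    return w, b, res.fun


class TestExemplarTraining:
    def test_member_objective_matches_qp_oracle(self, rng):
        for _ in range(3):
            x = rng.normal(size=(12, 3))
            ens = train_exemplar_ensemble(
                0, x, K=1, negative_set_size=10, C=0.5, seed=1, tol=1e-6
            )
            x_neg = x[ens.negative_sets[0]]
            obj_svm = exemplar_objective(
                ens.weights[0], ens.offsets[0], x[0], x_neg, C=0.5
            )
            _, _, obj_qp = qp_oracle(x[0], x_neg, C=0.5)
            assert obj_svm == pytest.approx(obj_qp, rel=1e-3, abs=1e-6)

    def test_toy_exemplar_separates_from_negatives(self, rng):
        """Exemplar at (1,0), negatives near (-1,0): every ensemble member
        scores the exemplar strictly above every negative."""
        x = np.vstack([[1.0, 0.0], rng.normal([-1, 0], 0.1, size=(20, 2))])
        ens = train_exemplar_ensemble(0, x, K=3, negative_set_size=15, C=10.0,
                                      seed=0)
        for w, b in zip(ens.weights, ens.offsets):
            pos = x[0] @ w
            neg = x[1:] @ w
            assert (pos > neg).all()

    def test_single_member_max_projection_identity(self, rng):
        x = rng.normal(size=(10, 4))
        ens = train_exemplar_ensemble(0, x, K=1, negative_set_size=6, C=0.1,
                                      seed=0)
        clf = max_project(ens)
        assert np.array_equal(clf.weights, ens.weights[0])

    def test_negative_sets_exclude_exemplar(self, rng):
        x = rng.normal(size=(15, 3))
        ens = train_exemplar_ensemble(4, x, K=5, negative_set_size=8, seed=2)
        for ns in ens.negative_sets:
            assert 4 not in ns

    def test_too_small_candidate_set_rejected(self, rng):
        x = rng.normal(size=(5, 3))
        with pytest.raises(ValueError):
            train_exemplar_ensemble(0, x, K=2, negative_set_size=5)


class TestMaxProjection:
    def test_identical_members_yield_the_member(self):
        w = np.array([[1.0, 2.0, 3.0]] * 4)
        ens = ExemplarEnsemble(0, w, np.zeros(4), [np.array([1])], 0.01)
        assert np.array_equal(max_project(ens).weights, w[0])

    def test_two_axis_members(self):
        w = np.array([[1.0, 0.0], [0.0, 1.0]])
        ens = ExemplarEnsemble(0, w, np.zeros(2), [np.array([1])], 0.01)
        assert np.array_equal(max_project(ens).weights, [1.0, 1.0])

    def test_random_members_match_elementwise_oracle(self, rng):
        w = rng.normal(size=(10, 50))
        ens = ExemplarEnsemble(0, w, np.zeros(10), [np.array([1])], 0.01)
        assert np.array_equal(max_project(ens).weights, np.max(w, axis=0))

    def test_dominance_on_non_negative_descriptors(self, rng):
        """<w_i, x> >= <w_i^k, x> for non-negative x (HOG is non-negative)."""
        w = rng.normal(size=(6, 20))
        ens = ExemplarEnsemble(0, w, np.zeros(6), [np.array([1])], 0.01)
        proj = max_project(ens).weights
        x = rng.random((30, 20))
        for k in range(6):
            assert (x @ proj >= x @ w[k] - 1e-12).all()

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ExemplarEnsemble(
                0, np.ones((2, 3)), np.zeros(3), [np.array([1])], 0.01
            )


class TestCalibration:
    def test_separated_scores_map_around_half(self):
        clf = CalibratedClassifier(np.ones(3))
        cal = calibrate(clf, [2.0, 2.5, 3.0], [-1.0, -0.5, 0.0])

        def p(s):
            return 1 / (1 + np.exp(-(cal.slope * s + cal.intercept)))

        assert all(p(s) > 0.5 for s in (2.0, 2.5, 3.0))
        assert all(p(s) < 0.5 for s in (-1.0, -0.5, 0.0))

    def test_monotone_increasing(self, rng):
        clf = CalibratedClassifier(np.ones(2))
        cal = calibrate(clf, rng.normal(1, 1, 30), rng.normal(-1, 1, 30))
        a, b = rng.normal(size=2)
        lo, hi = min(a, b), max(a, b)
        assert cal.slope > 0
        assert cal.slope * hi > cal.slope * lo

    def test_recovers_known_logistic_model(self, rng):
        """Scores from a logistic model (slope 2, intercept -1, n=500);
        the fit agrees with a fine-grid maximum-likelihood oracle."""
        s = rng.normal(0, 1.5, 500)
        p = 1 / (1 + np.exp(-(2.0 * s - 1.0)))
        y = rng.random(500) < p
        cal = calibrate(CalibratedClassifier(np.ones(1)), s[y], s[~y])

        def loglik(a, b):
            z = a * s + b
            return np.sum(y * z - np.logaddexp(0, z))

        grid_a = np.linspace(1.0, 3.0, 161)
        grid_b = np.linspace(-2.0, 0.0, 161)
        ll = np.array([[loglik(a, b) for b in grid_b] for a in grid_a])
        ia, ib = np.unravel_index(np.argmax(ll), ll.shape)
        assert cal.slope == pytest.approx(grid_a[ia], rel=0.10)
        assert cal.intercept == pytest.approx(grid_b[ib], rel=0.10)

    def test_degenerate_scores_rejected(self):
        clf = CalibratedClassifier(np.ones(1))
        with pytest.raises(ValueError, match="degenerate"):
            calibrate(clf, [1.0, 1.0], [1.0, 1.0])

    def test_uncalibrated_probability_rejected(self):
        with pytest.raises(ValueError, match="calibrated"):
            CalibratedClassifier(np.ones(2)).probability(np.ones(2))


class TestPairwiseSimilarity:
    def test_symmetric_and_matches_formula(self, rng):
        x = rng.normal(size=(8, 5))
        clfs = [CalibratedClassifier(rng.normal(size=5)) for _ in range(8)]
        s = pairwise_similarity(x, clfs)
        assert np.array_equal(s, s.T)
        for i, j in itertools.product(range(8), repeat=2):
            direct = 0.5 * (clfs[i].weights @ x[j] + clfs[j].weights @ x[i])
            assert s[i, j] == pytest.approx(direct, abs=1e-12)

    def test_missing_classifier_rejected(self, rng):
        with pytest.raises(ValueError):
            pairwise_similarity(rng.normal(size=(4, 3)),
                                [CalibratedClassifier(np.ones(3))] * 3)

    def test_within_cluster_similarity_exceeds_between(self, rng):
        """Two descriptor clusters: trained exemplar similarity is higher
        within clusters than between them."""
        a = np.abs(rng.normal([2, 0, 0, 0], 0.2, size=(12, 4)))
        b = np.abs(rng.normal([0, 0, 2, 0], 0.2, size=(12, 4)))
        x = np.vstack([a, b])
        clfs = []
        for i in range(24):
            ens = train_exemplar_ensemble(i, x, K=2, negative_set_size=12,
                                          C=1.0, seed=i)
            clfs.append(max_project(ens))
        s = pairwise_similarity(x, clfs)
        within = np.r_[s[:12, :12][np.triu_indices(12, 1)],
                       s[12:, 12:][np.triu_indices(12, 1)]]
        between = s[:12, 12:].ravel()
        assert within.mean() > between.mean()


def _ncut_objective(a, labels):
    total = 0.0
    for c in np.unique(labels):
        inside = labels == c
        cut = a[np.ix_(inside, ~inside)].sum()
        assoc = a[inside].sum()
        total += cut / assoc
    return total


class TestCodebook:
    def test_every_candidate_its_own_cluster_when_full_size(self, rng):
        n = 6
        s = rng.random((n, n))
        s = (s + s.T) / 2
        clfs = [CalibratedClassifier(rng.normal(size=3), 1.0, 0.0)
                for _ in range(n)]
        cb = build_codebook(s, clfs, n_entries=n)
        assert sorted(cb.medoid_indices) == list(range(n))
        assert len(np.unique(cb.assignments)) == n

    def test_two_block_similarity_recovers_blocks(self):
        """Exact 2-block similarity at n=10: spectral partition equals the
        blocks, verified optimal by exhaustive normalized-cut enumeration."""
        n = 10
        s = np.full((n, n), 0.05)
        s[:5, :5] = 1.0
        s[5:, 5:] = 1.0
        labels, medoids = spectral_medoid_clustering(s, 2, seed=0)
        assert len(set(labels[:5])) == 1 and len(set(labels[5:])) == 1
        assert labels[0] != labels[5]
        assert {m < 5 for m in medoids} == {True, False}
        # exhaustive oracle: the block partition minimises the normalized cut
        a = s.copy()
        np.fill_diagonal(a, 0.0)
        best = min(
            _ncut_objective(a, np.array([0] + list(bits)))
            for bits in itertools.product([0, 1], repeat=n - 1)
            if len(set([0] + list(bits))) == 2
        )
        achieved = _ncut_objective(a, labels)
        assert achieved == pytest.approx(best, rel=1e-9)

    def test_disconnected_graph_reports_components(self):
        s = np.zeros((6, 6))
        s[:2, :2] = s[2:4, 2:4] = s[4:, 4:] = 1.0
        clfs = [CalibratedClassifier(np.ones(2), 1.0, 0.0)] * 6
        with pytest.raises(ValueError, match="components"):
            build_codebook(s, clfs, n_entries=2)

    def test_partition_invariant_under_candidate_permutation(self, rng):
        """Permuting candidate order relabels clusters but does not change
        the partition (compared via co-membership)."""
        blocks = [rng.normal(m, 0.05, size=(7, 7)) for m in (3.0, 1.0, 2.0)]
        n = 21
        s = np.full((n, n), 0.01)
        for k in range(3):
            s[k * 7 : (k + 1) * 7, k * 7 : (k + 1) * 7] = blocks[k]
        s = (s + s.T) / 2
        labels, _ = spectral_medoid_clustering(s, 3, seed=0)
        perm = rng.permutation(n)
        labels_p, _ = spectral_medoid_clustering(s[np.ix_(perm, perm)], 3, seed=0)
        co = labels[:, None] == labels[None, :]
        co_p = labels_p[:, None] == labels_p[None, :]
        inv = np.empty(n, dtype=int)
        inv[perm] = np.arange(n)
        assert np.array_equal(co, co_p[np.ix_(inv, inv)])

    def test_medoids_are_set_members_and_maximise_within_similarity(self, rng):
        n = 12
        s = rng.random((n, n))
        s = (s + s.T) / 2
        labels, medoids = spectral_medoid_clustering(s, 3, seed=1)
        a = s - s.min()
        np.fill_diagonal(a, 0.0)
        for c, m in enumerate(medoids):
            idx = np.nonzero(labels == c)[0]
            assert m in idx
            within = a[np.ix_(idx, idx)].sum(axis=1)
            assert a[m, idx].sum() == pytest.approx(within.max())

    def test_codebook_save_load_round_trip(self, posture_codebook, tmp_path, rng):
        posture_codebook.save(tmp_path / "cb")
        from graspkin.codebook import Codebook

        loaded = Codebook.load(tmp_path / "cb")
        d = rng.random(posture_codebook.weight_matrix.shape[1])
        assert np.allclose(
            loaded.probabilities(d), posture_codebook.probabilities(d)
        )
        assert np.array_equal(loaded.medoid_indices,
                              posture_codebook.medoid_indices)
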