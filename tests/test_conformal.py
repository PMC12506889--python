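"""Non-conformity scores, taxonomies, p-values and prediction sets.

The p-value path is checked against an explicit brute-force implementation
(python loops over calibration scores) on random small instances.
"""

import numpy as np
import pytest

import scconformal as sc
from scconformal.conformal import (NULL_CLUSTER, NonconformityConfig,
                                   TaxonomyConfig, nonconformity_matrix)

PROBS = np.array([0.5, 0.3, 0.2])


class TestScoreArithmetic:
    def test_thr_hand_values(self):
        assert sc.score_thr(np.array([0.7, 0.2, 0.1]), 0) == pytest.approx(0.3)
        assert sc.score_thr(np.array([1.0, 0.0]), 0) == 0.0
        assert sc.score_thr(np.array([0.0, 1.0]), 0) == 1.0

    def test_aps_hand_values(self):
        assert sc.score_aps(PROBS, 1, u=0.5) == pytest.approx(0.65)
        assert sc.score_aps(PROBS, 0, u=0.0) == 0.0          # top class, u=0
        assert sc.score_aps(PROBS, 2, u=1.0) == pytest.approx(1.0)  # total mass

    def test_raps_hand_values(self):
        assert sc.score_raps(PROBS, 2, u=0.0, eta=0.01, kappa=1) == pytest.approx(0.82)
        # rank <= kappa: no penalty
        assert sc.score_raps(PROBS, 0, u=0.3, eta=0.5, kappa=1) == \
            pytest.approx(sc.score_aps(PROBS, 0, u=0.3))

    def test_raps_eta_zero_equals_aps(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            p = rng.dirichlet(np.ones(5))
            u = rng.uniform()
            k = rng.integers(5)
            assert sc.score_raps(p, k, u, eta=0.0, kappa=2) == \
                pytest.approx(sc.score_aps(p, k, u), abs=1e-12)

    def test_aps_tie_break_stable_by_class_index(self):
        p = np.array([0.4, 0.4, 0.2])
        # class 0 precedes class 1 at equal score
        assert sc.score_aps(p, 0, u=0.0) == 0.0
        assert sc.score_aps(p, 1, u=0.0) == pytest.approx(0.4)

    def test_non_simplex_rejected(self):
        with pytest.raises(ValueError, match="simplex"):
            sc.score_thr(np.array([0.9, 0.9]), 0)


def brute_force_pvalues(cal_scores_by_group, group_of_class, S):
    """O(n*K*m) literal rank count, the oracle for pvalue_matrix."""
    n, K = S.shape
    P = np.empty((n, K))
    for i in range(n):
        for k in range(K):
            cal = cal_scores_by_group[group_of_class[k]]
            count = sum(1 for s in cal if s >= S[i, k])
            P[i, k] = (1 + count) / (len(cal) + 1)
    return P


@pytest.mark.parametrize("kind", ["THR", "APS", "RAPS"])
@pytest.mark.parametrize("taxonomy", ["standard", "classwise", "cluster"])
def test_pvalues_match_brute_force(kind, taxonomy):
    """Vectorized conformal p-values equal the explicit loop, exactly."""
    rng = np.random.default_rng(42)
    for trial in range(12):
        K = int(rng.integers(2, 7))
        n_cal = int(rng.integers(K * 3, 50 + K * 3))
        labels = np.array([f"c{k}" for k in range(K)] * 3
                          + list(rng.choice([f"c{k}" for k in range(K)],
                                            size=n_cal - 3 * K)), dtype=object)
        probs_cal = rng.dirichlet(np.ones(K), size=len(labels))
        nc = NonconformityConfig(kind=kind, seed=trial)
        tax = TaxonomyConfig(kind=taxonomy, min_class_cal=3,
                             n_clusters=min(2, K), seed=trial)
        import warnings as _w
        with _w.catch_warnings():
            _w.simplefilter("ignore", UserWarning)
            calibrator = sc.calibrate(probs_cal, labels, nc, tax,
                                      label_space=[f"c{k}" for k in range(K)])
        probs_q = rng.dirichlet(np.ones(K), size=8)
        P = sc.pvalue_matrix(calibrator, probs_q, seed=trial + 100)
        # reconstruct the scores the implementation used (same u stream)
        u = np.random.default_rng(trial + 100).uniform(size=8) \
            if nc.randomized else None
        S = nonconformity_matrix(probs_q, nc, u)
        cal_by_group = {g: list(v) for g, v in calibrator.group_scores.items()}
        expected = brute_force_pvalues(cal_by_group, calibrator.group_of_class, S)
        np.testing.assert_array_equal(P, expected)
        assert np.all(P > 0) and np.all(P <= 1)


class TestCalibrate:
    def _probs_labels(self, counts, K=3, seed=0):
        rng = np.random.default_rng(seed)
        labels = np.concatenate([[f"c{k}"] * c for k, c in enumerate(counts)])
        return rng.dirichlet(np.ones(K), size=len(labels)), labels.astype(object)

    def test_standard_single_pool(self):
        probs, labels = self._probs_labels([10, 10, 10])
        cal = sc.calibrate(probs, labels, NonconformityConfig(), TaxonomyConfig())
        assert set(cal.group_of_class) == {0}
        assert len(cal.group_scores[0]) == 30

    def test_classwise_groups_by_class(self):
        probs, labels = self._probs_labels([30, 30, 30])
        cal = sc.calibrate(probs, labels, NonconformityConfig(),
                           TaxonomyConfig(kind="classwise"))
        assert sorted(cal.group_of_class) == [0, 1, 2]
        assert all(len(v) == 30 for v in cal.group_scores.values())

    def test_classwise_class_below_two_errors(self):
        probs, labels = self._probs_labels([1, 30, 30])
        with pytest.raises(ValueError, match="c0"):
            sc.calibrate(probs, labels, NonconformityConfig(),
                         TaxonomyConfig(kind="classwise"))

    def test_classwise_rare_class_warns(self):
        probs, labels = self._probs_labels([5, 30, 30])
        with pytest.warns(UserWarning, match="unstable"):
            sc.calibrate(probs, labels, NonconformityConfig(),
                         TaxonomyConfig(kind="classwise", min_class_cal=20))

    def test_single_cluster_equals_standard(self):
        probs, labels = self._probs_labels([40, 40, 40], seed=3)
        nc = NonconformityConfig(kind="THR")
        std = sc.calibrate(probs, labels, nc, TaxonomyConfig(kind="standard"))
        one = sc.calibrate(probs, labels, nc,
                           TaxonomyConfig(kind="cluster", n_clusters=1,
                                          min_class_cal=10))
        rng = np.random.default_rng(9)
        pq = rng.dirichlet(np.ones(3), size=50)
        np.testing.assert_array_equal(sc.pvalue_matrix(std, pq, seed=1),
                                      sc.pvalue_matrix(one, pq, seed=1))


class TestClusterClasses:
    def test_identical_distributions_one_cluster(self):
        s = np.linspace(0.1, 0.9, 40)
        out = sc.cluster_classes({"a": s, "b": s.copy()},
                                 TaxonomyConfig(kind="cluster", n_clusters=1,
                                                min_class_cal=10))
        assert out["a"] == out["b"]

    def test_disjoint_supports_separate_clusters(self):
        rng = np.random.default_rng(0)
        low = rng.uniform(0.0, 0.1, 50)
        high = rng.uniform(0.9, 1.0, 50)
        out = sc.cluster_classes({"low": low, "high": high},
                                 TaxonomyConfig(kind="cluster", n_clusters=2,
                                                min_class_cal=10))
        assert out["low"] != out["high"]

    def test_rare_class_goes_to_null_cluster(self):
        out = sc.cluster_classes(
            {"big": np.linspace(0, 1, 50), "tiny": np.array([0.5] * 5)},
            TaxonomyConfig(kind="cluster", n_clusters=1, min_class_cal=20))
        assert out["tiny"] == NULL_CLUSTER and out["big"] != NULL_CLUSTER

    def test_too_many_clusters_errors(self):
        with pytest.raises(ValueError, match="exceeds"):
            sc.cluster_classes({"a": np.linspace(0, 1, 50)},
                               TaxonomyConfig(kind="cluster", n_clusters=3,
                                              min_class_cal=10))


class TestPredictSets:
    @pytest.fixture(scope="class")
    def calibrator(self, small_pipeline):
        return sc.calibrate(small_pipeline["probs_cal"],
                            small_pipeline["cal"].labels,
                            NonconformityConfig(kind="APS", seed=0),
                            TaxonomyConfig(),
                            label_space=small_pipeline["model"].label_space)

    def test_alpha_zero_full_label_space(self, calibrator, small_pipeline):
        sets = sc.predict_sets(calibrator, small_pipeline["probs_query"][:50],
                               alpha=0.0, seed=5)
        assert np.all(sets.set_sizes == len(calibrator.label_space))

    def test_nested_in_alpha(self, calibrator, small_pipeline):
        pq = small_pipeline["probs_query"]
        loose = sc.predict_sets(calibrator, pq, alpha=0.05, seed=5)
        strict = sc.predict_sets(calibrator, pq, alpha=0.10, seed=5)
        assert np.all(strict.set_mask <= loose.set_mask)

    def test_alpha_one_only_pvalue_one_survives(self, calibrator, small_pipeline):
        sets = sc.predict_sets(calibrator, small_pipeline["probs_query"][:50],
                               alpha=1.0, seed=5)
        assert np.array_equal(sets.set_mask, sets.pvalues >= 1.0)

    def test_empty_sets_flagged_as_rejections(self, calibrator):
        # adversarial cell: uniform probabilities score badly everywhere
        K = len(calibrator.label_space)
        uniform = np.full((1, K), 1.0 / K)
        sets = sc.predict_sets(calibrator, uniform, alpha=0.9, seed=5)
        assert sets.empty_mask[0] == (sets.set_sizes[0] == 0)


class TestForceLabel:
    def test_singleton_returns_member(self):
        res = sc.PredictionSetResult(
            label_space=["a", "b"], pvalues=np.array([[0.9, 0.01]]),
            set_mask=np.array([[True, False]]), alpha=0.05,
            probs=np.array([[0.8, 0.2]]))
        labels, rejected = sc.force_label(res)
        assert labels[0] == "a" and not rejected[0]

    def test_pvalue_tie_broken_by_softmax_then_order(self):
        res = sc.PredictionSetResult(
            label_space=["a", "b", "c"],
            pvalues=np.array([[0.9, 0.2, 0.9]]),
            set_mask=np.array([[True, False, True]]), alpha=0.05,
            probs=np.array([[0.5, 0.1, 0.4]]))
        labels, _ = sc.force_label(res)
        assert labels[0] == "a"

    def test_empty_set_still_forced_and_flagged(self):
        res = sc.PredictionSetResult(
            label_space=["a", "b"], pvalues=np.array([[0.02, 0.04]]),
            set_mask=np.array([[False, False]]), alpha=0.05,
            probs=np.array([[0.6, 0.4]]))
        labels, rejected = sc.force_label(res)
        assert labels[0] == "b" and rejected[0]


# ---------------------------------------------------------------------------
# property tests
# ---------------------------------------------------------------------------

from hypothesis import given, settings
from hypothesis import strategies as st


@settings(max_examples=50, deadline=None, derandomize=True)
@given(weights=st.lists(st.floats(0.01, 10.0), min_size=2, max_size=8),
       u=st.floats(0.0, 1.0))
def test_score_ranges_on_arbitrary_simplex_points(weights, u):
    """THR lies in [0,1]; APS in [0,1]; RAPS exceeds APS by at most
    eta*(K-kappa); scores are finite for every class."""
    probs = np.asarray(weights) / np.sum(weights)
    K = len(probs)
    for k in range(K):
        thr = sc.score_thr(probs, k)
        aps = sc.score_aps(probs, k, u)
        raps = sc.score_raps(probs, k, u, eta=0.01, kappa=1)
        assert 0.0 <= thr <= 1.0
        assert -1e-12 <= aps <= 1.0 + 1e-12
        assert aps - 1e-12 <= raps <= aps + 0.01 * (K - 1) + 1e-12


@settings(max_examples=50, deadline=None, derandomize=True)
@given(scores=st.lists(st.floats(0.0, 100.0), min_size=1, max_size=60),
       s_a=st.floats(0.0, 100.0), s_b=st.floats(0.0, 100.0))
def test_detector_pvalue_monotone_and_bounded(scores, s_a, s_b):
    """Conformal p-values are antitone in the anomaly score and confined to
    [1/(n+1), 1]."""
    calib = sc.AnomalyCalibration(scores=np.asarray(scores))
    pa = sc.conformal_pvalue(calib, s_a)
    pb = sc.conformal_pvalue(calib, s_b)
    n = calib.n_cal
    for p in (pa, pb):
        assert 1 / (n + 1) <= p <= 1.0
    if s_a <= s_b:
        assert pa >= pb
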