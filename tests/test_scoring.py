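"""RV coefficient, keypoint scores, SMOTE and per-keypoint SVMs."""

import numpy as np
import pytest
from scipy.stats import ortho_group

from keyfusion import (
    KeypointModel,
    keypoint_score,
    rank_and_select_top_k,
    rv_coefficient,
    smote_oversample,
    train_keypoint_svm,
)


def brute_force_rv(A, B):
    """Oracle: pairwise inner-product form of the RV coefficient."""
    num = sum((A[:, j] @ B[:, k]) ** 2 for j in range(A.shape[1]) for k in range(B.shape[1]))
    da = sum((A[:, j] @ A[:, k]) ** 2 for j in range(A.shape[1]) for k in range(A.shape[1]))
    db = sum((B[:, j] @ B[:, k]) ** 2 for j in range(B.shape[1]) for k in range(B.shape[1]))
    return num / np.sqrt(da * db)


class TestRvCoefficient:
    def test_self_similarity_is_one(self):
        rng = np.random.default_rng(0)
        Q = rng.normal(size=(6, 4))
        assert rv_coefficient(Q, Q) == pytest.approx(1.0, abs=1e-12)

    def test_homothetic_transform_is_one(self):
        """RV = 1 when one matrix is a rotated, positively scaled copy."""
        rng = np.random.default_rng(1)
        Q = rng.normal(size=(8, 5))
        H = ortho_group.rvs(5, random_state=2)
        assert rv_coefficient(Q, 3.7 * Q @ H) == pytest.approx(1.0, abs=1e-8)

    def test_orthogonal_configurations_are_zero(self):
        Qp = np.array([[1.0], [0.0]])
        Qc = np.array([[0.0], [1.0]])
        assert rv_coefficient(Qp, Qc) == 0.0

    def test_symmetry_and_permutation_invariance(self):
        rng = np.random.default_rng(3)
        A, B = rng.normal(size=(7, 4)), rng.normal(size=(7, 6))
        assert rv_coefficient(A, B) == pytest.approx(rv_coefficient(B, A), rel=1e-12)
        perm = rng.permutation(4)
        assert rv_coefficient(A[:, perm], B) == pytest.approx(
            rv_coefficient(A, B), rel=1e-12
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        A = rng.normal(size=(rng.integers(2, 9), rng.integers(1, 6)))
        B = rng.normal(size=(A.shape[0], rng.integers(1, 6)))
        assert rv_coefficient(A, B) == pytest.approx(brute_force_rv(A, B), rel=1e-10)

    def test_zero_matrix_rejected(self):
        with pytest.raises(ValueError, match="zero matrix"):
            rv_coefficient(np.zeros((4, 2)), np.ones((4, 2)))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            rv_coefficient(np.ones((4, 2)), np.ones((5, 2)))


class TestKeypointScore:
    def test_identical_groups_score_zero(self):
        Q = np.random.default_rng(0).normal(size=(5, 3))
        assert keypoint_score(Q, Q) == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal_groups_score_one(self):
        assert keypoint_score(np.array([[1.0], [0.0]]), np.array([[0.0], [1.0]])) == 1.0

    def test_uniform_scoring_ignores_matrices(self):
        rng = np.random.default_rng(1)
        assert keypoint_score(rng.normal(size=(4, 2)), rng.normal(size=(4, 3)),
                              score_type="uniform") == 1.0

    def test_score_increases_with_group_shift(self):
        """1 - RV is non-decreasing in the planted shift delta."""
        rng = np.random.default_rng(7)
        mean = rng.normal(size=(20, 1))
        d = rng.normal(size=(20, 1))
        scores = []
        for delta in (0.0, 0.5, 1.0, 2.0):
            rng_i = np.random.default_rng(42)
            Qp = mean + delta * d + 0.2 * rng_i.normal(size=(20, 10))
            Qc = mean + 0.2 * rng_i.normal(size=(20, 10))
            scores.append(keypoint_score(Qp, Qc))
        assert all(b >= a - 1e-6 for a, b in zip(scores, scores[1:]))


class TestSmote:
    def test_samples_lie_on_segment(self):
        minority = np.array([[0.0, 1.0], [0.0, 1.0]])  # points (0,0), (1,1)
        out = smote_oversample(minority, 30, k=1, rng=np.random.default_rng(0))
        assert out.shape == (2, 30)
        synth = out[:, 2:]
        np.testing.assert_allclose(synth[0], synth[1], atol=1e-12)
        assert np.all((synth >= 0) & (synth <= 1))

    def test_identity_when_target_equals_count(self):
        m = np.random.default_rng(1).normal(size=(3, 5))
        np.testing.assert_array_equal(smote_oversample(m, 5, 3), m)

    @pytest.mark.parametrize("seed", range(5))
    def test_convexity_and_neighbor_membership(self, seed):
        """Each synthetic point is a convex combination of a minority point
        and one of its k nearest minority neighbours."""
        rng = np.random.default_rng(seed)
        m = rng.normal(size=(4, 7))
        k = 3
        out = smote_oversample(m, 20, k, rng=np.random.default_rng(seed + 100))
        d2 = np.sum((m[:, :, None] - m[:, None, :]) ** 2, axis=0)
        np.fill_diagonal(d2, np.inf)
        nn = np.argsort(d2, axis=1)[:, :k]
        for s in out[:, 7:].T:
            ok = False
            for i in range(7):
                for j in nn[i]:
                    x, y = m[:, i], m[:, j]
                    seg = y - x
                    t = seg @ (s - x) / (seg @ seg)
                    if -1e-9 <= t <= 1 + 1e-9 and np.linalg.norm(x + t * seg - s) < 1e-9:
                        ok = True
            assert ok

    def test_single_sample_falls_back_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            out = smote_oversample(np.ones((3, 1)), 4, 5, np.random.default_rng(0))
        assert out.shape == (3, 4)
        assert "SMOTE undefined" in caplog.text

    def test_shrinking_is_rejected(self):
        with pytest.raises(ValueError):
            smote_oversample(np.ones((2, 4)), 3, 1)


class TestKeypointSvm:
    def test_separable_toy_problem(self):
        rng = np.random.default_rng(0)
        Qp = np.vstack([np.ones(10) + 0.1 * rng.normal(size=10), rng.normal(size=10)])
        Qc = np.vstack([-np.ones(10) + 0.1 * rng.normal(size=10), rng.normal(size=10)])
        w, b = train_keypoint_svm(Qp, Qc, rng=np.random.default_rng(1))
        assert w[0] > 0
        assert all(w @ Qp[:, j] + b > 0 for j in range(10))
        assert all(w @ Qc[:, j] + b < 0 for j in range(10))

    def test_label_swap_negates_decision(self):
        rng = np.random.default_rng(2)
        A, B = rng.normal(size=(5, 8)), rng.normal(size=(5, 8)) + 0.5
        w1, b1 = train_keypoint_svm(A, B, rng=np.random.default_rng(0))
        w2, b2 = train_keypoint_svm(B, A, rng=np.random.default_rng(0))
        grid = rng.normal(size=(5, 20))
        # libSVM solves to ~1e-3 tolerance; the unique solution is negated
        np.testing.assert_allclose(w1 @ grid + b1, -(w2 @ grid + b2), atol=5e-3)

    def test_smote_balancing_reduces_majority_bias(self):
        """On a symmetric test grid, balanced training predicts the minority
        class closer to half the time than raw imbalanced training."""
        from sklearn.svm import SVC

        rng = np.random.default_rng(5)
        minority = rng.normal(size=(4, 5)) + np.array([[1.5], [0], [0], [0]])
        majority = rng.normal(size=(4, 50)) - np.array([[1.5], [0], [0], [0]])
        w, b = train_keypoint_svm(minority, majority, rng=np.random.default_rng(0))
        # oracle comparator: plain SVM without balancing
        X = np.concatenate([minority, majority], axis=1).T
        y = np.concatenate([np.ones(5), -np.ones(50)])
        raw = SVC(kernel="linear", C=1.0).fit(X, y)
        grid = rng.normal(size=(4, 400)) * 1.5  # symmetric around the origin
        frac_balanced = np.mean((w @ grid + b) > 0)
        frac_raw = np.mean(raw.decision_function(grid.T) > 0)
        assert abs(frac_balanced - 0.5) <= abs(frac_raw - 0.5)

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            train_keypoint_svm(np.ones((3, 0)), np.ones((3, 4)))


class TestTopK:
    @staticmethod
    def model(i, score):
        return KeypointModel(
            template_index=i, score=score, weight=np.zeros(4), bias=0.0,
            feature_kind="hog", block_size=16,
        )

    def test_selects_by_descending_score(self):
        models = [self.model(0, 0.5), self.model(1, 0.9), self.model(2, 0.1)]
        got = rank_and_select_top_k(models, 2)
        assert [m.score for m in got] == [0.9, 0.5]

    def test_ties_broken_by_template_index(self):
        models = [self.model(5, 0.4), self.model(2, 0.4), self.model(9, 0.4)]
        assert [m.template_index for m in rank_and_select_top_k(models, 3)] == [2, 5, 9]

    def test_oversized_k_returns_all(self, caplog):
        models = [self.model(0, 0.3)]
        with caplog.at_level("WARNING"):
            assert rank_and_select_top_k(models, 10) == models
        assert "exceeds" in caplog.text
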