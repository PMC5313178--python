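"""Keypoint scoring (RV coefficient) and per-keypoint SVM training.

The group difference at a keypoint is measured by the RV coefficient
between the patient and control feature matrices,

    RV(Qp, Qc) = tr(Qp Qp' Qc Qc') / [tr((Qp Qp')^2)^1/2 tr((Qc Qc')^2)^1/2],

a matrix correlation in [0, 1]: 1 when one configuration is a homothetic
(rotation + positive scaling) transform of the other, 0 when the column
spaces are uncorrelated.  The keypoint's classification weight is
1 - RV, so keypoints whose local anatomy differs most between groups count
most.  Each effective keypoint also gets a linear soft-margin SVM on its
descriptor columns (+1 patient, -1 healthy); the minority group is first
over-sampled to the majority size with SMOTE.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.svm import SVC

from .representation import LocalFeatureMatrix

logger = logging.getLogger(__name__)


@dataclass
class KeypointModel:
    """A scored template keypoint with its trained linear decision function."""

    template_index: int
    score: float  # 1 - RV, in [0, 1]
    weight: np.ndarray  # length H
    bias: float
    feature_kind: str
    block_size: int

    def decision(self, theta: np.ndarray) -> float:
        return float(self.weight @ theta + self.bias)

    def predict_patient(self, theta: np.ndarray) -> bool:
        """Hard SVM label: patient iff the decision value is positive."""
        return self.decision(theta) > 0.0


def _as_matrix(Q) -> np.ndarray:
    if isinstance(Q, LocalFeatureMatrix):
        return Q.values
    return np.asarray(Q, dtype=np.float64)


def rv_coefficient(Qp, Qc) -> float:
    """RV coefficient between two H x n descriptor configurations.

    Computed through the cross-Gram identity
    tr(Qp Qp' Qc Qc') = ||Qp' Qc||_F^2, which avoids forming the H x H
    Gram matrices.  Raises ``ValueError`` on zero matrices, for which the
    coefficient is undefined.
    """
    A, B = _as_matrix(Qp), _as_matrix(Qc)
    if A.shape[0] != B.shape[0]:
        raise ValueError(f"feature-length mismatch: {A.shape[0]} vs {B.shape[0]}")
    if A.size == 0 or B.size == 0:
        raise ValueError("RV coefficient needs at least one column per matrix")
    den_a = np.linalg.norm(A.T @ A)
    den_b = np.linalg.norm(B.T @ B)
    if den_a < 1e-300 or den_b < 1e-300:
        raise ValueError("RV coefficient is undefined for a zero matrix")
    num = np.linalg.norm(A.T @ B) ** 2
    rv = num / (den_a * den_b)
    if rv < -1e-8 or rv > 1.0 + 1e-8:
        warnings.warn(f"RV coefficient {rv} outside [0,1] beyond round-off")
    return float(min(max(rv, 0.0), 1.0))


def keypoint_score(Qp, Qc, score_type: str = "rv") -> float:
    """Classification weight of a keypoint: 1 - RV, or 1 under uniform scoring."""
    if score_type == "uniform":
        return 1.0
    return 1.0 - rv_coefficient(Qp, Qc)


def smote_oversample(
    minority: np.ndarray,
    target_n: int,
    k: int = 5,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """SMOTE: grow an H x n minority sample to H x target_n columns.

    Synthetic columns are ``x + u * (x_nn - x)`` with ``u ~ U[0, 1]`` and
    ``x_nn`` one of x's k nearest minority neighbours (Euclidean).  With a
    single minority column SMOTE is undefined; that case falls back to
    jittered duplication (sd 1e-3) with a warning.
    """
    rng = rng or np.random.default_rng()
    minority = np.asarray(minority, dtype=np.float64)
    H, n = minority.shape
    if target_n < n:
        raise ValueError("target_n must be >= current minority size")
    if target_n == n:
        return minority.copy()
    n_new = target_n - n
    if n == 1:
        logger.warning("SMOTE undefined for a single minority sample; jittering")
        jitter = rng.normal(0.0, 1e-3, size=(H, n_new))
        synth = minority[:, [0] * n_new] + jitter
        return np.concatenate([minority, synth], axis=1)
    k_eff = min(k, n - 1)
    d2 = np.sum((minority[:, :, None] - minority[:, None, :]) ** 2, axis=0)
    np.fill_diagonal(d2, np.inf)
    nn_idx = np.argsort(d2, axis=1, kind="stable")[:, :k_eff]
    base = rng.integers(0, n, size=n_new)
    pick = rng.integers(0, k_eff, size=n_new)
    u = rng.uniform(0.0, 1.0, size=n_new)
    x = minority[:, base]
    x_nn = minority[:, nn_idx[base, pick]]
    synth = x + u[None, :] * (x_nn - x)
    return np.concatenate([minority, synth], axis=1)


def train_keypoint_svm(
    Qp,
    Qc,
    svm_c: float = 1.0,
    smote_k: int = 5,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, float]:
    """SMOTE-balanced 2-class linear SVM on one keypoint's descriptors.

    Columns of ``Qp`` are labelled +1 (patient), columns of ``Qc`` -1
    (healthy); the minority group is over-sampled to the majority size
    before fitting.  Returns ``(w, b)`` with prediction ``sign(w.theta + b)``
    (positive = patient).
    """
    P, C = _as_matrix(Qp), _as_matrix(Qc)
    if P.shape[1] == 0 or C.shape[1] == 0:
        raise ValueError("both classes must be non-empty")
    n_max = max(P.shape[1], C.shape[1])
    if P.shape[1] < n_max:
        P = smote_oversample(P, n_max, smote_k, rng)
    elif C.shape[1] < n_max:
        C = smote_oversample(C, n_max, smote_k, rng)
    X = np.concatenate([P, C], axis=1).T
    y = np.concatenate([np.ones(P.shape[1]), -np.ones(C.shape[1])])
    clf = SVC(kernel="linear", C=svm_c)
    clf.fit(X, y)
    # classes_ is sorted [-1, +1]; decision_function > 0 predicts +1 (patient)
    w = clf.coef_[0].astype(np.float64)
    b = float(clf.intercept_[0])
    return w, b


def rank_and_select_top_k(
    models: list[KeypointModel], top_k: int = 100
) -> list[KeypointModel]:
    """Top-k keypoint models by descending score, ties by template index."""
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    if top_k > len(models):
        logger.warning(
            "top_k=%d exceeds available keypoints (%d); keeping all",
            top_k, len(models),
        )
    ranked = sorted(models, key=lambda m: (-m.score, m.template_index))
    return ranked[:top_k]
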