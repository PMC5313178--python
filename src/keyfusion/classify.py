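"""Training, threshold calibration, prediction and leave-one-out evaluation.

A test subject's statistic is the signed score sum

    LS_sum = sum_i  +/- (1 - RV_i)

over the effective keypoints matched in the subject: each matched
keypoint's linear SVM votes patient (+) or healthy (-) on the local
descriptor extracted at the match, weighted by the keypoint's score.
The decision threshold eps_c is calibrated on the training subjects
(scored by resubstitution) to minimise |FN - FP|; the subject is labelled
patient iff LS_sum > eps_c strictly.  Evaluation is leave-one-out: the
whole second stage (eps_rate filtering, feature matrices, RV scores, SVMs,
top-k selection, threshold) is refit on each training remainder.  Keypoint
detection, descriptor extraction and template matching are per-subject
deterministic operations with no fitted state, so they are computed once
and shared across folds.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .config import PipelineConfig
from .correspondence import match_template_to_subject
from .io import Volume, downsample_volume, get_slice
from .keypoints import FeatureRecord, FeatureSet, extract_subject_features
from .representation import (
    BlockBoundaryError,
    extract_feature,
    map_record_to_original,
)
from .scoring import (
    KeypointModel,
    keypoint_score,
    rank_and_select_top_k,
    train_keypoint_svm,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# cohort precomputation
# ---------------------------------------------------------------------------


@dataclass
class SubjectData:
    volume: Volume  # original resolution
    features: FeatureSet  # extracted after down-sampling
    label: str  # "patient" or "control"


@dataclass
class CohortData:
    """Per-subject deterministic precomputations shared across CV folds."""

    template_volume: Volume
    template_fs: FeatureSet
    subjects: dict[str, SubjectData]
    matches: list[dict[str, FeatureRecord]]  # per template keypoint
    config: PipelineConfig
    _theta_cache: dict[tuple[str, int], list[dict[str, np.ndarray | None]]] = field(
        default_factory=dict
    )

    def labels(self) -> dict[str, str]:
        return {sid: sd.label for sid, sd in self.subjects.items()}

    def thetas(self, feature_kind: str, block_size: int):
        """Per-(keypoint, subject) representation descriptors, lazily cached.

        ``None`` marks matches whose block did not fit the slice.
        """
        key = (feature_kind, block_size)
        if key in self._theta_cache:
            return self._theta_cache[key]
        factor = self.config.downsample_factor
        out: list[dict[str, np.ndarray | None]] = []
        for i, per_subject in enumerate(self.matches):
            row: dict[str, np.ndarray | None] = {}
            for sid, rec in per_subject.items():
                mp = map_record_to_original(rec, factor)
                vol = self.subjects[sid].volume
                try:
                    s = get_slice(vol, mp.orientation, mp.order)
                    row[sid] = extract_feature(s.pixels, mp, feature_kind, block_size)
                except (BlockBoundaryError, IndexError) as exc:
                    logger.warning(
                        "keypoint %d, subject %s: block dropped (%s)", i, sid, exc
                    )
                    row[sid] = None
            out.append(row)
        self._theta_cache[key] = out
        return out


def prepare_cohort(
    template: Volume, cohort: list[Volume], cfg: PipelineConfig
) -> CohortData:
    """Extract features and template matches for every subject once."""
    t_small = downsample_volume(template, cfg.downsample_factor)
    template_fs = extract_subject_features(t_small, cfg.detector)
    logger.info("template: %d keypoints", len(template_fs))
    subjects: dict[str, SubjectData] = {}
    matches: list[dict[str, FeatureRecord]] = [
        {} for _ in range(len(template_fs.records))
    ]
    for vol in cohort:
        if vol.subject_id in subjects:
            raise ValueError(f"duplicate subject_id {vol.subject_id!r}")
        fs = extract_subject_features(
            downsample_volume(vol, cfg.downsample_factor), cfg.detector
        )
        subjects[vol.subject_id] = SubjectData(
            volume=vol, features=fs, label=vol.group
        )
        for i, m in enumerate(
            match_template_to_subject(template_fs, fs, cfg.eps_match)
        ):
            if m is not None:
                matches[i][vol.subject_id] = m
    return CohortData(
        template_volume=template,
        template_fs=template_fs,
        subjects=subjects,
        matches=matches,
        config=cfg,
    )


# ---------------------------------------------------------------------------
# trained model
# ---------------------------------------------------------------------------


@dataclass
class TrainedModel:
    """The selected keypoint models plus the calibrated decision threshold."""

    keypoint_models: list[KeypointModel]
    template_records: dict[int, FeatureRecord]
    threshold: float
    config: PipelineConfig

    def __post_init__(self) -> None:
        if not self.keypoint_models:
            raise ValueError("a trained model needs at least one keypoint model")
        if not np.isfinite(self.threshold):
            raise ValueError("threshold must be finite")

    def to_json(self) -> str:
        payload = {
            "config": self.config.to_dict(),
            "threshold": self.threshold,
            "keypoints": [
                {
                    "template_index": km.template_index,
                    "score": km.score,
                    "weight": km.weight.tolist(),
                    "bias": km.bias,
                    "feature_kind": km.feature_kind,
                    "block_size": km.block_size,
                    "template_record": {
                        "orientation": rec.orientation,
                        "order": rec.order,
                        "location": list(rec.location),
                        "dominant_orientation": rec.dominant_orientation,
                        "scale": rec.scale,
                        "descriptor": rec.descriptor.tolist(),
                    },
                }
                for km in self.keypoint_models
                for rec in [self.template_records[km.template_index]]
            ],
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, s: str) -> "TrainedModel":
        payload = json.loads(s)
        cfg = PipelineConfig.from_dict(payload["config"])
        models, records = [], {}
        for kp in payload["keypoints"]:
            models.append(
                KeypointModel(
                    template_index=kp["template_index"],
                    score=kp["score"],
                    weight=np.asarray(kp["weight"]),
                    bias=kp["bias"],
                    feature_kind=kp["feature_kind"],
                    block_size=kp["block_size"],
                )
            )
            tr = kp["template_record"]
            records[kp["template_index"]] = FeatureRecord(
                orientation=tr["orientation"],
                order=tr["order"],
                location=tuple(tr["location"]),
                dominant_orientation=tr["dominant_orientation"],
                scale=tr["scale"],
                descriptor=np.asarray(tr["descriptor"]),
            )
        return cls(
            keypoint_models=models,
            template_records=records,
            threshold=payload["threshold"],
            config=cfg,
        )


def _svm_rng(cfg: PipelineConfig, template_index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([cfg.seed, 7919, template_index])
    )


def fit_on_subjects(
    cohort: CohortData, train_sids: list[str], cfg: PipelineConfig | None = None
) -> TrainedModel:
    """Fit the second stage (filter, score, SVMs, top-k, threshold) on a subset."""
    cfg = cfg or cohort.config
    labels = cohort.labels()
    train_sids = sorted(train_sids)
    patients = [s for s in train_sids if labels[s] == "patient"]
    controls = [s for s in train_sids if labels[s] == "control"]
    if not patients or not controls:
        raise ValueError("training subjects must include both classes")
    M, N = len(patients), len(controls)
    thetas = cohort.thetas(cfg.feature_kind, cfg.block_size)

    scored: list[KeypointModel] = []
    columns: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for i, per_subject in enumerate(cohort.matches):
        n_p = sum(1 for s in patients if s in per_subject)
        n_c = sum(1 for s in controls if s in per_subject)
        if n_p < cfg.eps_rate * M or n_c < cfg.eps_rate * N:
            continue  # unrepresentative keypoint
        qp = [thetas[i][s] for s in patients if thetas[i].get(s) is not None]
        qc = [thetas[i][s] for s in controls if thetas[i].get(s) is not None]
        if not qp or not qc:
            logger.warning("keypoint %d: empty feature matrix after drops", i)
            continue
        Qp, Qc = np.stack(qp, axis=1), np.stack(qc, axis=1)
        score = keypoint_score(Qp, Qc, cfg.score_type)
        scored.append(
            KeypointModel(
                template_index=i,
                score=score,
                weight=np.zeros(Qp.shape[0]),
                bias=0.0,
                feature_kind=cfg.feature_kind,
                block_size=cfg.block_size,
            )
        )
        columns[i] = (Qp, Qc)
    if not scored:
        raise ValueError("no effective keypoints survived eps_rate filtering")
    selected = rank_and_select_top_k(scored, cfg.top_k)
    for km in selected:
        Qp, Qc = columns[km.template_index]
        w, b = train_keypoint_svm(
            Qp, Qc, cfg.svm_c, cfg.smote_k, _svm_rng(cfg, km.template_index)
        )
        km.weight, km.bias = w, b
    model = TrainedModel(
        keypoint_models=selected,
        template_records={
            km.template_index: cohort.template_fs.records[km.template_index]
            for km in selected
        },
        threshold=0.0,
        config=cfg,
    )
    train_scores = {
        sid: ls_sum_cached(cohort, model, sid) for sid in train_sids
    }
    model.threshold = calibrate_threshold(
        train_scores, {sid: labels[sid] for sid in train_sids}
    )
    return model


def ls_sum_cached(cohort: CohortData, model: TrainedModel, sid: str) -> float:
    """LS_sum of a subject using the cohort's cached matches/descriptors."""
    cfg = model.config
    thetas = cohort.thetas(cfg.feature_kind, cfg.block_size)
    total = 0.0
    for km in model.keypoint_models:
        theta = thetas[km.template_index].get(sid)
        if theta is None:
            continue
        total += km.score if km.predict_patient(theta) else -km.score
    return total


def score_test_subject(
    test_fs: FeatureSet,
    model: TrainedModel,
    test_volume: Volume,
) -> tuple[float, int]:
    """LS_sum for an unseen subject: match, describe, vote, sum.

    ``test_fs`` must come from the same detector/down-sampling settings as
    the model.  Returns ``(LS_sum, n_matched)``; with zero matches the sum
    is 0 and the decision falls to the threshold comparison.
    """
    cfg = model.config
    index = test_fs.slice_index()
    from .correspondence import match_feature

    total, n_matched = 0.0, 0
    for km in model.keypoint_models:
        tf = model.template_records[km.template_index]
        m = match_feature(tf, index.get(tf.slice_key, []), cfg.eps_match)
        if m is None:
            continue
        mp = map_record_to_original(m, cfg.downsample_factor)
        try:
            s = get_slice(test_volume, mp.orientation, mp.order)
            theta = extract_feature(s.pixels, mp, cfg.feature_kind, cfg.block_size)
        except (BlockBoundaryError, IndexError):
            continue
        n_matched += 1
        total += km.score if km.predict_patient(theta) else -km.score
    if n_matched == 0:
        logger.warning("subject %s matched no effective keypoints", test_volume.subject_id)
    return total, n_matched


# ---------------------------------------------------------------------------
# thresholding and metrics
# ---------------------------------------------------------------------------


def _confusion(scores: dict[str, float], labels: dict[str, str], t: float):
    tp = sum(1 for s in scores if labels[s] == "patient" and scores[s] > t)
    fn = sum(1 for s in scores if labels[s] == "patient" and scores[s] <= t)
    fp = sum(1 for s in scores if labels[s] == "control" and scores[s] > t)
    tn = sum(1 for s in scores if labels[s] == "control" and scores[s] <= t)
    return tp, fp, tn, fn


def _candidate_thresholds(values) -> np.ndarray:
    """Sorted-unique-score midpoints plus below-min / above-max sentinels."""
    u = np.unique(np.asarray(list(values), dtype=np.float64))
    cands = [u[0] - 1.0, u[-1] + 1.0]
    cands.extend((u[:-1] + u[1:]) / 2.0)
    return np.asarray(sorted(cands))


def _pick_threshold(
    scores: dict[str, float],
    labels: dict[str, str],
    objective,
) -> float:
    """Smallest-objective candidate; ties broken by |t| then by value."""
    best = None
    for t in _candidate_thresholds(scores.values()):
        obj = objective(*_confusion(scores, labels, t))
        key = (obj, abs(t), t)
        if best is None or key < best[0]:
            best = (key, t)
    return float(best[1])


def calibrate_threshold(
    train_scores: dict[str, float], train_labels: dict[str, str]
) -> float:
    """Decision threshold minimising |FN - FP| on training LS_sums.

    Candidates are midpoints of the sorted unique scores plus sentinels
    beyond both ends; ties prefer the candidate closest to 0 (the ideal
    threshold), then the smaller value.
    """
    present = set(train_labels.values())
    if present != {"patient", "control"}:
        raise ValueError("threshold calibration needs both classes present")
    return _pick_threshold(
        train_scores, train_labels, lambda tp, fp, tn, fn: abs(fn - fp)
    )


def predict_label(ls_sum: float, eps_c: float) -> str:
    """Patient iff LS_sum strictly exceeds the threshold."""
    return "patient" if ls_sum > eps_c else "control"


def eer_accuracy(
    per_subject_scores: dict[str, float], labels: dict[str, str]
) -> float:
    """Accuracy (%) at the threshold equalising false-positive and
    false-negative *rates* as nearly as the discrete scores allow."""
    present = set(labels.values())
    if present != {"patient", "control"}:
        raise ValueError("EER accuracy needs both classes present")

    def objective(tp, fp, tn, fn):
        fpr = fp / (fp + tn)
        fnr = fn / (fn + tp)
        return abs(fpr - fnr)

    t = _pick_threshold(per_subject_scores, labels, objective)
    tp, fp, tn, fn = _confusion(per_subject_scores, labels, t)
    return 100.0 * (tp + tn) / (tp + fp + tn + fn)


# ---------------------------------------------------------------------------
# leave-one-out evaluation
# ---------------------------------------------------------------------------


@dataclass
class EvalResult:
    """Leave-one-out confusion counts and headline metrics (percentages)."""

    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    sensitivity: float
    specificity: float
    eer_accuracy: float
    per_subject_scores: dict[str, float]
    predictions: dict[str, str]

    @classmethod
    def from_counts(
        cls,
        tp: int,
        fp: int,
        tn: int,
        fn: int,
        per_subject_scores: dict[str, float],
        labels: dict[str, str],
        predictions: dict[str, str],
    ) -> "EvalResult":
        total = tp + fp + tn + fn
        return cls(
            tp=tp,
            fp=fp,
            tn=tn,
            fn=fn,
            accuracy=100.0 * (tp + tn) / total,
            sensitivity=100.0 * tp / (tp + fn) if tp + fn else float("nan"),
            specificity=100.0 * tn / (tn + fp) if tn + fp else float("nan"),
            eer_accuracy=eer_accuracy(per_subject_scores, labels),
            per_subject_scores=per_subject_scores,
            predictions=predictions,
        )

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "eer_accuracy": self.eer_accuracy,
            "per_subject_scores": self.per_subject_scores,
            "predictions": self.predictions,
        }


def loocv_evaluate(
    cohort: list[Volume],
    template: Volume,
    cfg: PipelineConfig,
    precomputed: CohortData | None = None,
) -> EvalResult:
    """Leave-one-out cross-validation of the full pipeline.

    For every held-out subject, eps_rate filtering, RV scoring, SVM
    training, top-k selection and threshold calibration are refit on the
    remaining subjects only; the held-out subject is then matched against
    the refit model and classified.
    """
    labels = {v.subject_id: v.group for v in cohort}
    for lab in ("patient", "control"):
        if sum(1 for g in labels.values() if g == lab) < 2:
            raise ValueError(f"need at least 2 {lab} subjects for LOOCV")
    data = precomputed or prepare_cohort(template, cohort, cfg)
    sids = sorted(labels)
    scores: dict[str, float] = {}
    predictions: dict[str, str] = {}
    tp = fp = tn = fn = 0
    for held_out in sids:
        train = [s for s in sids if s != held_out]
        model = fit_on_subjects(data, train, cfg)
        ls = ls_sum_cached(data, model, held_out)
        pred = predict_label(ls, model.threshold)
        scores[held_out] = ls
        predictions[held_out] = pred
        if labels[held_out] == "patient":
            tp += pred == "patient"
            fn += pred == "control"
        else:
            tn += pred == "control"
            fp += pred == "patient"
        logger.info(
            "fold %s: LS_sum=%.4f threshold=%.4f pred=%s true=%s",
            held_out, ls, model.threshold, pred, labels[held_out],
        )
    return EvalResult.from_counts(tp, fp, tn, fn, scores, labels, predictions)
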