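"""Model/Results facade over the two-stage pipeline.

``TwoStageFusionModel`` holds the data (template + labelled cohort) and
configuration; ``fit()`` runs the correspondence and representation stages
and returns a ``TwoStageFusionResults`` carrying the trained keypoint
ensemble, its calibrated threshold, per-keypoint diagnostics, and methods
to predict new subjects, cross-validate, and print a summary table.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import (
    CohortData,
    EvalResult,
    TrainedModel,
    fit_on_subjects,
    loocv_evaluate,
    predict_label,
    prepare_cohort,
    score_test_subject,
)
from .config import PipelineConfig
from .io import Volume, downsample_volume, load_cohort, load_volume, read_manifest
from .keypoints import extract_subject_features


class TwoStageFusionModel:
    """Two-stage local-feature fusion classifier for volumetric images.

    Parameters
    ----------
    template : Volume
        The reference volume whose keypoints define the landmark set.
    subjects : list of Volume
        Training cohort; each volume's ``group`` must be "patient" or
        "control".
    config : PipelineConfig, optional
        Pipeline settings (matching/rate thresholds, block size, feature
        kind, top-k, SVM and SMOTE parameters, seed).
    """

    def __init__(
        self,
        template: Volume,
        subjects: list[Volume],
        config: PipelineConfig | None = None,
    ) -> None:
        labels = {v.group for v in subjects}
        bad = labels - {"patient", "control"}
        if bad:
            raise ValueError(f"cohort groups must be patient/control, got {bad}")
        self.template = template
        self.subjects = list(subjects)
        self.config = config or PipelineConfig()
        self._cohort_data: CohortData | None = None

    @classmethod
    def from_manifest(
        cls,
        manifest_path: str | Path,
        template_path: str | Path,
        config: PipelineConfig | None = None,
    ) -> "TwoStageFusionModel":
        manifest = read_manifest(manifest_path)
        manifest = manifest[manifest["group"].isin(["patient", "control"])]
        subjects = load_cohort(manifest)
        template = load_volume(template_path, "template", "template")
        return cls(template, subjects, config)

    @property
    def cohort_data(self) -> CohortData:
        """Per-subject features and template matches (computed once)."""
        if self._cohort_data is None:
            self._cohort_data = prepare_cohort(
                self.template, self.subjects, self.config
            )
        return self._cohort_data

    def fit(self) -> "TwoStageFusionResults":
        """Train on all subjects and return the results object."""
        trained = fit_on_subjects(
            self.cohort_data, [v.subject_id for v in self.subjects], self.config
        )
        return TwoStageFusionResults(model=self, trained=trained)

    def cross_validate(self) -> EvalResult:
        """Leave-one-out evaluation with full second-stage refitting."""
        return loocv_evaluate(
            self.subjects, self.template, self.config, precomputed=self.cohort_data
        )


@dataclass
class TwoStageFusionResults:
    """Fitted keypoint ensemble with its calibrated decision threshold."""

    model: TwoStageFusionModel | None
    trained: TrainedModel

    @property
    def threshold(self) -> float:
        return self.trained.threshold

    @property
    def keypoint_scores(self) -> pd.DataFrame:
        rows = [
            {
                "template_index": km.template_index,
                "score": km.score,
                "orientation": self.trained.template_records[km.template_index].orientation,
                "order": self.trained.template_records[km.template_index].order,
                "scale": self.trained.template_records[km.template_index].scale,
            }
            for km in self.trained.keypoint_models
        ]
        return pd.DataFrame(rows)

    def predict(self, volumes: Volume | list[Volume]) -> pd.DataFrame:
        """Score and label unseen volumes.

        Returns a DataFrame with columns subject_id, ls_sum,
        matched_keypoints, label.
        """
        if isinstance(volumes, Volume):
            volumes = [volumes]
        cfg = self.trained.config
        rows = []
        for v in volumes:
            fs = extract_subject_features(
                downsample_volume(v, cfg.downsample_factor), cfg.detector
            )
            ls, n_matched = score_test_subject(fs, self.trained, v)
            rows.append(
                {
                    "subject_id": v.subject_id,
                    "ls_sum": ls,
                    "matched_keypoints": n_matched,
                    "label": predict_label(ls, self.trained.threshold),
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable fit summary."""
        t = self.trained
        scores = np.array([km.score for km in t.keypoint_models])
        cfg = t.config
        lines = [
            "Two-stage local feature fusion classifier",
            "=" * 45,
            f"feature kind:            {cfg.feature_kind.upper()}",
            f"block size:              {cfg.block_size} x {cfg.block_size}",
            f"ratio-test eps_match:    {cfg.eps_match}",
            f"coverage eps_rate:       {cfg.eps_rate}",
            f"keypoints selected (K):  {len(t.keypoint_models)} (top_k={cfg.top_k})",
            f"score type:              {cfg.score_type} (1-RV)"
            if cfg.score_type == "rv"
            else "score type:              uniform (all 1)",
            f"keypoint score range:    [{scores.min():.4f}, {scores.max():.4f}]",
            f"mean keypoint score:     {scores.mean():.4f}",
            f"decision threshold e_c:  {t.threshold:+.4f}",
        ]
        return "\n".join(lines)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.trained.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "TwoStageFusionResults":
        return cls(model=None, trained=TrainedModel.from_json(Path(path).read_text()))
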