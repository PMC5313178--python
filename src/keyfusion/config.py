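"""Pipeline configuration.

A single frozen dataclass carries every tunable of the two-stage pipeline so
that a trained model can snapshot the exact settings it was built with and
refuse to score subjects processed differently.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Any

FEATURE_KINDS = ("hog", "gv", "glcm")


@dataclass(frozen=True)
class DetectorParams:
    """Scale-space keypoint detector settings.

    Detection runs on each 2D slice after min-max normalisation to [0, 1].
    ``min_sigma``/``max_sigma``/``num_sigma`` define the (log-spaced) scale
    grid of the scale-normalised Laplacian-of-Gaussian search;
    ``contrast_threshold`` is the minimum absolute scale-normalised response;
    (detections must stand clear of the noise floor of a few percent of the
    dynamic range that typical MR slices carry);
    ``edge_ratio`` bounds the principal-curvature ratio (Harris-style edge
    suppression); orientation-histogram peaks above ``ori_peak_ratio`` of
    the maximum spawn additional keypoints at the same location (standard
    SIFT practice, and essential for locally symmetric texture whose
    gradient histogram is bimodal); ``border_scale_factor`` discards
    keypoints closer than
    ``scale * border_scale_factor`` to the slice border so descriptor and
    block extraction always fit.
    """

    min_sigma: float = 1.6
    max_sigma: float = 6.4
    num_sigma: int = 6
    contrast_threshold: float = 0.08
    edge_ratio: float = 10.0
    border_scale_factor: float = 6.0
    ori_peak_ratio: float = 0.8  # secondary orientation peaks above this fraction
    max_orientations: int = 3  # of the histogram max spawn extra keypoints


@dataclass(frozen=True)
class PipelineConfig:
    """Settings of the full correspondence + representation pipeline.

    eps_match : Lowe ratio-test threshold (closest / second-closest descriptor
        distance must fall strictly below it).
    eps_rate : minimum fraction of subjects, in each group separately, in
        which a template keypoint must be matched to count as effective.
    block_size : side length in pixels of the square cell block from which
        the representation descriptor is extracted (4, 8 or 16).
    feature_kind : local representation around matched keypoints — "hog"
        (oriented-gradient histogram, length 128), "gv" (raw gray values,
        length block_size**2) or "glcm" (gray-level co-occurrence, length 64).
    top_k : number of highest-scoring keypoints kept for classification.
    svm_c : soft-margin constant of the per-keypoint linear SVM.
    smote_k : neighbour count of SMOTE minority over-sampling.
    downsample_factor : isotropic block-mean down-sampling applied to every
        volume before slicing/detection; representation descriptors are
        always extracted at the original resolution.
    seed : master seed; every stochastic step derives its stream from it.
    """

    eps_match: float = 0.8
    eps_rate: float = 0.5
    block_size: int = 16
    feature_kind: str = "hog"
    top_k: int = 100
    svm_c: float = 1.0
    smote_k: int = 5
    downsample_factor: int = 1
    seed: int = 0
    score_type: str = "rv"  # "rv" -> 1-RV weights; "uniform" -> all weights 1
    detector: DetectorParams = field(default_factory=DetectorParams)

    def __post_init__(self) -> None:
        if not 0.0 < self.eps_match < 1.0:
            raise ValueError(f"eps_match must be in (0, 1), got {self.eps_match}")
        if not 0.0 < self.eps_rate <= 1.0:
            raise ValueError(f"eps_rate must be in (0, 1], got {self.eps_rate}")
        if self.block_size not in (4, 8, 16):
            raise ValueError(f"block_size must be 4, 8 or 16, got {self.block_size}")
        if self.feature_kind not in FEATURE_KINDS:
            raise ValueError(f"feature_kind must be one of {FEATURE_KINDS}")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if self.downsample_factor < 1:
            raise ValueError("downsample_factor must be >= 1")
        if self.score_type not in ("rv", "uniform"):
            raise ValueError("score_type must be 'rv' or 'uniform'")

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        d = dict(d)
        det = d.pop("detector", None)
        if det is not None:
            d["detector"] = DetectorParams(**det)
        return cls(**d)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "PipelineConfig":
        return cls.from_dict(json.loads(s))
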