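"""Template-anchored keypoint correspondence.

Every template keypoint is matched independently against each subject:
candidate points are the subject's keypoints on the *same* slice
(orientation and order must agree exactly), the closest candidate in
descriptor space wins iff the Lowe ratio test passes — the ratio of the
closest to the second-closest (plain, unsquared) Euclidean distance must be
strictly below ``eps_match``.  A slice offering only one candidate never
yields a match, and equal closest/second distances (ratio 1) are rejected.
Keypoints matched in fewer than ``eps_rate`` of the subjects of either
group are discarded as unrepresentative; the survivors are the "effective"
keypoints the classifier is built on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .keypoints import FeatureRecord, FeatureSet


@dataclass
class MatchSet:
    """Matches of one template keypoint across both training groups."""

    template_index: int
    patient_matches: dict[str, FeatureRecord] = field(default_factory=dict)
    control_matches: dict[str, FeatureRecord] = field(default_factory=dict)

    @property
    def n_patient(self) -> int:
        return len(self.patient_matches)

    @property
    def n_control(self) -> int:
        return len(self.control_matches)


def retrieve_candidates(fs: FeatureSet, tf: FeatureRecord) -> list[FeatureRecord]:
    """Candidate points: the subject's records on the template keypoint's slice."""
    return fs.by_slice(tf.orientation, tf.order)


_SECOND_NEIGHBOR_RADIUS = 3.0  # px: candidates this close to the best are
# the same physical point (orientation copies, adjacent scale-space
# detections) and cannot serve as the "closest incorrect match"


def match_feature(
    tf: FeatureRecord,
    candidates: list[FeatureRecord],
    eps_match: float = 0.8,
) -> FeatureRecord | None:
    """Lowe ratio-test match of a template keypoint against candidates.

    Returns the closest candidate by descriptor Euclidean distance iff the
    ratio of its distance to that of the second-closest candidate falls
    strictly below ``eps_match``.  The second-closest is the nearest
    candidate at a *geometrically distinct* location (more than 3 px from
    the best): duplicate detections of the same point — secondary
    orientation copies in particular — are not incorrect matches and must
    not veto a correct one.  With no distinct second candidate there is no
    distance to certify the match against, so it is rejected (a lone
    candidate point is never trusted).
    """
    if len(candidates) < 2:
        return None
    desc = np.stack([c.descriptor for c in candidates])
    dists = np.linalg.norm(desc - tf.descriptor, axis=1)
    best = int(np.argmin(dists))
    d1 = dists[best]
    loc_best = np.asarray(candidates[best].location)
    distinct = [
        i
        for i, c in enumerate(candidates)
        if np.linalg.norm(np.asarray(c.location) - loc_best)
        > _SECOND_NEIGHBOR_RADIUS
    ]
    if not distinct:
        return None
    d2 = float(min(dists[i] for i in distinct))
    if d2 < 1e-300:
        return None  # both distances zero: ratio undefined, treat as ambiguous
    if d1 / d2 < eps_match:
        return candidates[best]
    return None


def match_template_to_subject(
    template_fs: FeatureSet, subject_fs: FeatureSet, eps_match: float = 0.8
) -> list[FeatureRecord | None]:
    """Match every template keypoint against one subject.

    Returns one entry per template record (None where no match), using the
    subject's slice index for candidate retrieval.
    """
    index = subject_fs.slice_index()
    out: list[FeatureRecord | None] = []
    for tf in template_fs.records:
        cands = index.get(tf.slice_key, [])
        out.append(match_feature(tf, cands, eps_match))
    return out


def build_match_sets(
    template_fs: FeatureSet,
    patient_fs_list: list[FeatureSet],
    control_fs_list: list[FeatureSet],
    cfg: PipelineConfig | None = None,
) -> list[MatchSet]:
    """One MatchSet per template keypoint, populated subject by subject."""
    cfg = cfg or PipelineConfig()
    match_sets = [MatchSet(template_index=i) for i in range(len(template_fs.records))]
    for group_list, attr in (
        (patient_fs_list, "patient_matches"),
        (control_fs_list, "control_matches"),
    ):
        for fs in group_list:
            matches = match_template_to_subject(template_fs, fs, cfg.eps_match)
            for ms, m in zip(match_sets, matches):
                if m is not None:
                    getattr(ms, attr)[fs.subject_id] = m
    return match_sets


def filter_unrepresentative(
    match_sets: list[MatchSet],
    n_patient: int,
    n_control: int,
    eps_rate: float = 0.5,
) -> list[MatchSet]:
    """Keep the effective keypoints.

    A keypoint is unrepresentative — and discarded — if its match count in
    either group falls strictly below ``eps_rate`` times that group's size.
    """
    if n_patient < 1 or n_control < 1:
        raise ValueError("both groups must be non-empty")
    return [
        ms
        for ms in match_sets
        if not (
            ms.n_patient < eps_rate * n_patient or ms.n_control < eps_rate * n_control
        )
    ]


def match_sets_to_frame(match_sets: list[MatchSet]) -> pd.DataFrame:
    """Tabular view keyed by (template_index, subject_id) for serialisation."""
    rows = []
    for ms in match_sets:
        for group, matches in (
            ("patient", ms.patient_matches),
            ("control", ms.control_matches),
        ):
            for sid, rec in sorted(matches.items()):
                rows.append(
                    {
                        "template_index": ms.template_index,
                        "subject_id": sid,
                        "group": group,
                        "orientation": rec.orientation,
                        "order": rec.order,
                        "x_row": rec.location[0],
                        "x_col": rec.location[1],
                        "orientation_angle": rec.dominant_orientation,
                        "scale": rec.scale,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "template_index", "subject_id", "group", "orientation", "order",
            "x_row", "x_col", "orientation_angle", "scale",
        ],
    )
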