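"""Shared fixtures: small deterministic inputs and the frozen study cohort."""

from __future__ import annotations

import numpy as np
import pytest

from keyfusion import PipelineConfig, SyntheticCohortSpec, generate_cohort
from keyfusion.classify import CohortData, prepare_cohort
from keyfusion.keypoints import DESCRIPTOR_LEN, FeatureRecord


def make_record(
    orientation="axial",
    order=20,
    location=(20.0, 20.0),
    dominant_orientation=0.0,
    scale=2.0,
    descriptor=None,
):
    """A FeatureRecord with a valid (unit-norm) descriptor."""
    if descriptor is None:
        descriptor = np.zeros(DESCRIPTOR_LEN)
        descriptor[0] = 1.0
    return FeatureRecord(
        orientation=orientation,
        order=order,
        location=location,
        dominant_orientation=dominant_orientation,
        scale=scale,
        descriptor=descriptor,
    )


def unit_at_distance(base: np.ndarray, d: float, direction: int) -> np.ndarray:
    """A unit vector at Euclidean distance ``d`` from unit vector ``base``.

    ``direction`` selects an axis orthogonal to ``base`` so several
    candidates can sit at controlled distances from the same template
    descriptor.  Requires 0 < d < 2.
    """
    e = np.zeros_like(base)
    e[direction] = 1.0
    e = e - (e @ base) * base
    e = e / np.linalg.norm(e)
    cos = 1.0 - d**2 / 2.0
    v = cos * base + np.sqrt(1.0 - cos**2) * e
    return v / np.linalg.norm(v)


def textured_slice(shape=(48, 48), seed=0):
    """A smooth, feature-rich test slice: blob + oriented grating + noise."""
    rng = np.random.default_rng(seed)
    r = np.arange(shape[0])[:, None]
    c = np.arange(shape[1])[None, :]
    img = 0.3 + np.exp(-((r - 24) ** 2 + (c - 24) ** 2) / (2 * 16.0))
    img = img * (1 + 0.4 * np.cos(2 * np.pi / 5.0 * (0.8 * (c - 24) + 0.6 * (r - 24))))
    img = img + rng.normal(0, 0.01, shape)
    return np.clip(img, 0, None)


# ---------------------------------------------------------------------------
# the frozen synthetic study (shared by the end-to-end acceptance checks)
# ---------------------------------------------------------------------------

STRONG_SPEC = SyntheticCohortSpec(seed=0, effect_magnitude=1.0)
STUDY_CONFIG = PipelineConfig(top_k=30)


@pytest.fixture(scope="session")
def strong_cohort():
    """Frozen strong-effect cohort: (template, subjects, landmarks)."""
    return generate_cohort(STRONG_SPEC)


@pytest.fixture(scope="session")
def strong_data(strong_cohort) -> CohortData:
    """Features and template matches of the frozen cohort (computed once)."""
    template, subjects, _ = strong_cohort
    return prepare_cohort(template, subjects, STUDY_CONFIG)
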