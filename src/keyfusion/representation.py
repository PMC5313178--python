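"""Fixed-scale local descriptors around matched keypoints.

Unlike the scale-covariant SIFT appearance used for matching, the
representation stage compares anatomy *at a common scale*: a
``block_size x block_size`` pixel block is cut from the original-resolution
slice at the matched point's own location, rotated to its dominant
orientation, and summarised by one of three descriptors:

* ``hog``  — 4x4 subregions x 8 orientation channels of accumulated
  gradient magnitude (Gaussian-weighted over the block, SIFT-style),
  length 128 for every block size;
* ``gv``   — the raw gray values of the block, length block_size**2;
* ``glcm`` — gray-level co-occurrence of the block quantised to 8 levels,
  symmetric and normalised, averaged over the four unit offsets
  (0,1), (1,0), (1,1), (1,-1); length 64.

Every descriptor is L2-normalised to unit length.  Descriptors of the
matched subjects of one group are stacked as the columns of the H x n
feature matrix Q that the scoring stage compares between groups.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from skimage.feature import graycomatrix

from ._gradhist import (
    oriented_gradient_descriptor,
    sample_rotated_patch,
    uniform_fallback,
)
from .config import PipelineConfig
from .correspondence import MatchSet
from .io import Volume, get_slice
from .keypoints import FeatureRecord

logger = logging.getLogger(__name__)

GLCM_LEVELS = 8
_GLCM_ANGLES = [0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4]


class BlockBoundaryError(ValueError):
    """The descriptor block (after rotation margin) does not fit the slice."""


def feature_length(feature_kind: str, block_size: int) -> int:
    if feature_kind == "hog":
        return 128
    if feature_kind == "gv":
        return block_size**2
    if feature_kind == "glcm":
        return GLCM_LEVELS**2
    raise ValueError(f"unknown feature kind {feature_kind!r}")


def _check_bounds(shape: tuple[int, int], loc: tuple[float, float], block_size: int):
    margin = math.ceil(block_size / 2 * math.sqrt(2.0)) + 1
    if not (
        margin <= loc[0] <= shape[0] - 1 - margin
        and margin <= loc[1] <= shape[1] - 1 - margin
    ):
        raise BlockBoundaryError(
            f"block of size {block_size} at {loc} exceeds slice bounds {shape}"
        )


def _rotated_block(pixels, mp: FeatureRecord, block_size: int, pad: int = 0):
    patch, _ = sample_rotated_patch(
        np.asarray(pixels, dtype=np.float64),
        mp.location,
        block_size + 2 * pad,
        1.0,
        mp.dominant_orientation,
    )
    return patch


def extract_hog(pixels: np.ndarray, mp: FeatureRecord, block_size: int = 16) -> np.ndarray:
    """Oriented-gradient block descriptor, length 128, unit norm."""
    _check_bounds(pixels.shape, mp.location, block_size)
    return oriented_gradient_descriptor(
        np.asarray(pixels, dtype=np.float64),
        mp.location,
        mp.dominant_orientation,
        grid_size=block_size,
        spacing=1.0,
        n_cells=4,
        n_bins=8,
        gaussian_sigma=block_size / 2.0,
    )


def extract_gv(pixels: np.ndarray, mp: FeatureRecord, block_size: int = 16) -> np.ndarray:
    """Raw gray values of the rotated block, flattened row-major, unit norm."""
    _check_bounds(pixels.shape, mp.location, block_size)
    block = _rotated_block(pixels, mp, block_size)
    vec = block.ravel().astype(np.float64)
    norm = np.linalg.norm(vec)
    if norm < 1e-12:
        return uniform_fallback(vec.size)
    return vec / norm


def extract_glcm(pixels: np.ndarray, mp: FeatureRecord, block_size: int = 16) -> np.ndarray:
    """Averaged symmetric co-occurrence matrix of the 8-level block, unit norm."""
    _check_bounds(pixels.shape, mp.location, block_size)
    block = _rotated_block(pixels, mp, block_size)
    lo, hi = block.min(), block.max()
    if hi - lo < 1e-12:
        levels = np.zeros(block.shape, dtype=np.uint8)
    else:
        levels = np.clip(
            ((block - lo) / (hi - lo) * GLCM_LEVELS).astype(int), 0, GLCM_LEVELS - 1
        ).astype(np.uint8)
    glcm = graycomatrix(
        levels,
        distances=[1],
        angles=_GLCM_ANGLES,
        levels=GLCM_LEVELS,
        symmetric=True,
        normed=True,
    )
    mat = glcm[:, :, 0, :].mean(axis=2)
    vec = mat.ravel()
    norm = np.linalg.norm(vec)
    if norm < 1e-12:
        return uniform_fallback(vec.size)
    return vec / norm


_EXTRACTORS = {"hog": extract_hog, "gv": extract_gv, "glcm": extract_glcm}


def extract_feature(
    pixels: np.ndarray, mp: FeatureRecord, feature_kind: str, block_size: int
) -> np.ndarray:
    return _EXTRACTORS[feature_kind](pixels, mp, block_size)


def map_record_to_original(mp: FeatureRecord, factor: int) -> FeatureRecord:
    """Map a record detected on a down-sampled grid back to original voxels.

    Block-mean voxel ``i`` covers original voxels ``[i*f, (i+1)*f)``, so the
    centre maps to ``i*f + (f-1)/2``.  With factor 1 this is the identity.
    """
    if factor == 1:
        return mp
    off = (factor - 1) / 2.0
    return FeatureRecord(
        orientation=mp.orientation,
        order=int(round(mp.order * factor + off)),
        location=(mp.location[0] * factor + off, mp.location[1] * factor + off),
        dominant_orientation=mp.dominant_orientation,
        scale=mp.scale * factor,
        descriptor=mp.descriptor,
    )


@dataclass
class LocalFeatureMatrix:
    """H x n matrix of unit-norm local descriptors (columns = subjects)."""

    values: np.ndarray
    feature_kind: str
    subject_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("feature matrix must be 2D (H x n)")
        if self.values.shape[1] != len(self.subject_ids):
            raise ValueError("one column per subject required")
        norms = np.linalg.norm(self.values, axis=0)
        if self.values.shape[1] and not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("every column must be unit-norm")

    @property
    def H(self) -> int:
        return self.values.shape[0]

    @property
    def n(self) -> int:
        return self.values.shape[1]


def build_feature_matrices(
    ms: MatchSet,
    volumes_by_subject: dict[str, Volume],
    cfg: PipelineConfig,
) -> tuple[LocalFeatureMatrix, LocalFeatureMatrix]:
    """Group feature matrices (Q_patient, Q_control) for one keypoint.

    Descriptors are extracted on the original-resolution slice of each
    matched subject (locations mapped back through the down-sample factor);
    columns follow sorted subject id.  Matches whose block falls outside
    the slice are dropped with a warning.  An empty group is an error —
    the eps_rate filter should have removed such keypoints.
    """
    out = []
    for group, matches in (
        ("patient", ms.patient_matches),
        ("control", ms.control_matches),
    ):
        cols, sids = [], []
        for sid in sorted(matches):
            mp = map_record_to_original(matches[sid], cfg.downsample_factor)
            vol = volumes_by_subject[sid]
            try:
                s = get_slice(vol, mp.orientation, mp.order)
                vec = extract_feature(s.pixels, mp, cfg.feature_kind, cfg.block_size)
            except (BlockBoundaryError, IndexError) as exc:
                logger.warning(
                    "dropping match (keypoint %d, subject %s): %s",
                    ms.template_index, sid, exc,
                )
                continue
            cols.append(vec)
            sids.append(sid)
        if not cols:
            raise ValueError(
                f"keypoint {ms.template_index}: no usable {group} matches "
                "(empty feature matrix)"
            )
        out.append(
            LocalFeatureMatrix(
                values=np.stack(cols, axis=1), feature_kind=cfg.feature_kind,
                subject_ids=sids,
            )
        )
    return out[0], out[1]
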