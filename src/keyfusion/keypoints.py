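"""Scale-space keypoint detection and SIFT appearance descriptors on 2D slices.

Keypoints are maxima and minima of the scale-normalised Laplacian of
Gaussian, found on each slice after min-max normalisation to [0, 1] (so the
contrast threshold is intensity-scale-free).  Bright blobs are LoG minima of
the image, dark blobs are found by running the same detector on the inverted
slice.  Edge-like responses are suppressed with a principal-curvature ratio
test on the Hessian at the detection scale, and keypoints too close to the
slice border (within ``scale * border_scale_factor``) are discarded so that
descriptor windows fit.

Each keypoint gets a dominant orientation from a 36-bin gradient-orientation
histogram (Gaussian-weighted with sigma = 1.5 * scale, circularly smoothed,
peak refined by parabolic interpolation) and a 128-long SIFT appearance
descriptor: a 4x4 spatial grid of 8-channel orientation histograms sampled
from a window of width 12 * scale rotated to the dominant orientation,
normalised / clipped at 0.2 / renormalised to unit length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from skimage.feature import blob_log

from ._gradhist import oriented_gradient_descriptor
from .config import DetectorParams
from .io import Slice2D, Volume, iter_slices

DESCRIPTOR_LEN = 128
_N_ORI_BINS = 36


@dataclass
class FeatureRecord:
    """One keypoint: where it sits, its scale/orientation, and its appearance."""

    orientation: str  # slice orientation d
    order: int  # slice order l
    location: tuple[float, float]  # (row, col) in slice pixels
    dominant_orientation: float  # radians
    scale: float  # detection sigma, pixels
    descriptor: np.ndarray  # unit-norm, length 128

    def __post_init__(self) -> None:
        self.descriptor = np.asarray(self.descriptor, dtype=np.float64)
        if self.descriptor.shape != (DESCRIPTOR_LEN,):
            raise ValueError(
                f"descriptor must have length {DESCRIPTOR_LEN}, got {self.descriptor.shape}"
            )
        if abs(np.linalg.norm(self.descriptor) - 1.0) > 1e-6:
            raise ValueError("descriptor must be unit-norm")
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    @property
    def slice_key(self) -> tuple[str, int]:
        return (self.orientation, self.order)


@dataclass
class FeatureSet:
    """All keypoints of one subject, indexed by (orientation, order)."""

    subject_id: str
    group: str
    records: list[FeatureRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def by_slice(self, orientation: str, order: int) -> list[FeatureRecord]:
        key = (orientation, order)
        return [r for r in self.records if r.slice_key == key]

    def slice_index(self) -> dict[tuple[str, int], list[FeatureRecord]]:
        idx: dict[tuple[str, int], list[FeatureRecord]] = {}
        for r in self.records:
            idx.setdefault(r.slice_key, []).append(r)
        return idx

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = {
                "subject_id": self.subject_id,
                "group": self.group,
                "orientation": r.orientation,
                "order": r.order,
                "x_row": r.location[0],
                "x_col": r.location[1],
                "orientation_angle": r.dominant_orientation,
                "scale": r.scale,
            }
            row.update({f"d{i:03d}": v for i, v in enumerate(r.descriptor)})
            rows.append(row)
        cols = [
            "subject_id", "group", "orientation", "order", "x_row", "x_col",
            "orientation_angle", "scale",
        ] + [f"d{i:03d}" for i in range(DESCRIPTOR_LEN)]
        return pd.DataFrame(rows, columns=cols)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FeatureSet":
        if len(df) == 0:
            raise ValueError("cannot rebuild a FeatureSet from an empty frame")
        dcols = [f"d{i:03d}" for i in range(DESCRIPTOR_LEN)]
        records = [
            FeatureRecord(
                orientation=row.orientation,
                order=int(row.order),
                location=(float(row.x_row), float(row.x_col)),
                dominant_orientation=float(row.orientation_angle),
                scale=float(row.scale),
                descriptor=np.asarray([getattr(row, c) for c in dcols]),
            )
            for row in df.itertuples()
        ]
        return cls(
            subject_id=str(df["subject_id"].iloc[0]),
            group=str(df["group"].iloc[0]),
            records=records,
        )


def _normalize01(pixels: np.ndarray) -> np.ndarray | None:
    lo, hi = float(pixels.min()), float(pixels.max())
    if hi - lo < 1e-12:
        return None
    return (pixels - lo) / (hi - lo)


def _passes_edge_test(
    smoothed: np.ndarray, r: int, c: int, edge_ratio: float
) -> bool:
    """Principal-curvature ratio test on the Hessian of the smoothed slice."""
    h, w = smoothed.shape
    if not (1 <= r < h - 1 and 1 <= c < w - 1):
        return False
    drr = smoothed[r + 1, c] - 2 * smoothed[r, c] + smoothed[r - 1, c]
    dcc = smoothed[r, c + 1] - 2 * smoothed[r, c] + smoothed[r, c - 1]
    drc = (
        smoothed[r + 1, c + 1]
        - smoothed[r + 1, c - 1]
        - smoothed[r - 1, c + 1]
        + smoothed[r - 1, c - 1]
    ) / 4.0
    tr = drr + dcc
    det = drr * dcc - drc * drc
    if det <= 0:
        return False  # saddle: curvatures of opposite sign
    return tr * tr / det < (edge_ratio + 1.0) ** 2 / edge_ratio


def dominant_orientations(
    pixels: np.ndarray,
    location: tuple[float, float],
    scale: float,
    peak_ratio: float = 0.8,
    max_orientations: int = 3,
) -> list[float]:
    """Peaks of the Gaussian-weighted gradient-orientation histogram.

    36 bins over [0, 2*pi), weighting sigma = 1.5*scale, window radius
    3*sigma; the histogram is circularly smoothed and each winning bin is
    refined by parabolic interpolation.  Every local peak reaching
    ``peak_ratio`` of the global maximum yields an orientation (strongest
    first, at most ``max_orientations``), so locally symmetric texture —
    whose histogram is bimodal with peaks pi apart — produces a keypoint
    for each plausible orientation instead of an arbitrary winner.
    """
    sigma = 1.5 * scale
    radius = max(2, int(round(3.0 * sigma)))
    h, w = pixels.shape
    r0, c0 = int(round(location[0])), int(round(location[1]))
    rlo, rhi = max(r0 - radius, 1), min(r0 + radius, h - 2)
    clo, chi = max(c0 - radius, 1), min(c0 + radius, w - 2)
    if rhi < rlo or chi < clo:
        return [0.0]
    win = pixels[rlo - 1 : rhi + 2, clo - 1 : chi + 2]
    g_row = (win[2:, 1:-1] - win[:-2, 1:-1]) / 2.0
    g_col = (win[1:-1, 2:] - win[1:-1, :-2]) / 2.0
    mag = np.hypot(g_row, g_col)
    ang = np.mod(np.arctan2(g_row, g_col), 2.0 * np.pi)
    rr = np.arange(rlo, rhi + 1)[:, None] - location[0]
    cc = np.arange(clo, chi + 1)[None, :] - location[1]
    weight = np.exp(-(rr**2 + cc**2) / (2.0 * sigma**2))
    hist = np.zeros(_N_ORI_BINS)
    bins = (ang / (2.0 * np.pi) * _N_ORI_BINS).astype(int) % _N_ORI_BINS
    np.add.at(hist, bins.ravel(), (mag * weight).ravel())
    if hist.sum() < 1e-12:
        return [0.0]
    # circular smoothing, twice, with a small binomial kernel
    for _ in range(2):
        hist = (np.roll(hist, 1) + 2.0 * hist + np.roll(hist, -1)) / 4.0
    peak = hist.max()
    prev, nxt = np.roll(hist, 1), np.roll(hist, -1)
    is_peak = (hist >= prev) & (hist > nxt) & (hist >= peak_ratio * peak)
    out = []
    for k in sorted(np.flatnonzero(is_peak), key=lambda k: -hist[k]):
        left, center, right = prev[k], hist[k], nxt[k]
        denom = left - 2.0 * center + right
        offset = 0.0 if abs(denom) < 1e-12 else 0.5 * (left - right) / denom
        out.append(
            float(np.mod((k + offset + 0.5) / _N_ORI_BINS * 2.0 * np.pi, 2.0 * np.pi))
        )
        if len(out) >= max_orientations:
            break
    return out


def detect_keypoints(
    s: Slice2D, det_params: DetectorParams | None = None
) -> list[tuple[tuple[float, float], float, float]]:
    """Detect scale-space blob keypoints on one slice.

    Returns a deterministic, sorted list of ``(location, scale,
    dominant_orientation)`` triples.  A constant slice yields no keypoints.
    """
    p = det_params or DetectorParams()
    if min(s.pixels.shape) < 16:
        raise ValueError("slice too small for detection (min dimension 16)")
    norm = _normalize01(np.asarray(s.pixels, dtype=np.float64))
    if norm is None:
        return []
    blobs = []
    for img in (norm, 1.0 - norm):  # bright blobs, then dark blobs
        found = blob_log(
            img,
            min_sigma=p.min_sigma,
            max_sigma=p.max_sigma,
            num_sigma=p.num_sigma,
            threshold=p.contrast_threshold,
        )
        smooth_cache: dict[float, np.ndarray] = {}
        for r, c, sigma in found:
            if sigma not in smooth_cache:
                smooth_cache[sigma] = gaussian_filter(img, sigma)
            ri, ci = int(round(r)), int(round(c))
            if not _passes_edge_test(smooth_cache[sigma], ri, ci, p.edge_ratio):
                continue
            margin = sigma * p.border_scale_factor
            h, w = img.shape
            if not (margin <= r <= h - 1 - margin and margin <= c <= w - 1 - margin):
                continue
            blobs.append((float(r), float(c), float(sigma)))
    blobs.sort()
    out = []
    for r, c, sigma in blobs:
        for ori in dominant_orientations(
            norm, (r, c), sigma, p.ori_peak_ratio, p.max_orientations
        ):
            out.append(((r, c), sigma, ori))
    return out


def compute_descriptor(
    s: Slice2D, kp: tuple[tuple[float, float], float, float]
) -> np.ndarray:
    """128-long unit-norm SIFT appearance descriptor for one keypoint.

    4x4 spatial grid x 8 orientation channels sampled on a 16x16 grid
    spanning a window of width 12*scale, rotated to the dominant
    orientation; Gaussian-weighted, clipped at 0.2 and renormalised.
    Window samples clipped by the slice border contribute zero.
    """
    (loc, scale, ori) = kp
    norm = _normalize01(np.asarray(s.pixels, dtype=np.float64))
    if norm is None:
        from ._gradhist import uniform_fallback

        return uniform_fallback(DESCRIPTOR_LEN)
    grid = 16
    spacing = 12.0 * scale / grid
    return oriented_gradient_descriptor(
        norm,
        loc,
        ori,
        grid_size=grid,
        spacing=spacing,
        n_cells=4,
        n_bins=8,
        gaussian_sigma=grid / 2.0,
        clip=0.2,
    )


def extract_slice_features(
    s: Slice2D, det_params: DetectorParams | None = None
) -> list[FeatureRecord]:
    records = []
    for kp in detect_keypoints(s, det_params):
        (loc, scale, ori) = kp
        records.append(
            FeatureRecord(
                orientation=s.orientation,
                order=s.order,
                location=loc,
                dominant_orientation=ori,
                scale=scale,
                descriptor=compute_descriptor(s, kp),
            )
        )
    return records


def extract_subject_features(
    v: Volume, det_params: DetectorParams | None = None
) -> FeatureSet:
    """Detect and describe keypoints on every slice of all three orientations."""
    fs = FeatureSet(subject_id=v.subject_id, group=v.group)
    for s in iter_slices(v):
        fs.records.extend(extract_slice_features(s, det_params))
    return fs
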