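"""Oriented-gradient histogram core shared by the SIFT-style appearance
descriptor and the fixed-scale HOG representation.

Both descriptors are the same object computed at different scales: a square
patch is resampled on a grid rotated to the keypoint's dominant orientation,
image gradients are taken on the resampled patch (so gradient angles are
already expressed in the rotated frame), and gradient magnitudes are
accumulated into an ``n_cells x n_cells`` spatial grid of 8-channel
orientation histograms, then flattened and L2-normalised.

Geometry convention: a keypoint orientation ``theta`` is the angle
``atan2(d_row, d_col)`` of its dominant gradient direction in slice (row,
col) coordinates.  The descriptor-frame x axis is aligned with that
direction: a descriptor-frame offset ``(x, y)`` maps to the slice point
``(row + y*cos(theta) + x*sin(theta), col + x*cos(theta) - y*sin(theta))``.
Samples falling outside the slice contribute zero magnitude.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import map_coordinates


def uniform_fallback(length: int) -> np.ndarray:
    """Unit-norm constant vector used when a patch carries no gradient."""
    return np.full(length, 1.0 / np.sqrt(length))


def sample_rotated_patch(
    pixels: np.ndarray,
    center: tuple[float, float],
    n_samples: int,
    spacing: float,
    angle: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Bilinearly resample a rotated square grid around ``center``.

    Returns ``(patch, inside)`` of shape (n_samples, n_samples); ``inside``
    flags sample points that fell within the slice bounds (out-of-bounds
    samples read as 0 and must not contribute gradient mass).
    """
    half = (n_samples - 1) / 2.0
    idx = (np.arange(n_samples) - half) * spacing
    x, y = np.meshgrid(idx, idx)  # y varies along rows, x along cols
    ct, st = np.cos(angle), np.sin(angle)
    rows = center[0] + y * ct + x * st
    cols = center[1] + x * ct - y * st
    patch = map_coordinates(pixels, [rows, cols], order=1, mode="constant", cval=0.0)
    h, w = pixels.shape
    inside = (rows >= 0) & (rows <= h - 1) & (cols >= 0) & (cols <= w - 1)
    return patch, inside


def patch_gradients(patch: np.ndarray, inside: np.ndarray | None = None):
    """Central-difference gradients of the interior of a sampled patch.

    ``patch`` has one sample of margin on each side; returns magnitude and
    angle arrays for the (n-2) x (n-2) interior.  Gradient angle is
    ``atan2(g_row, g_col)`` in the patch frame, wrapped to [0, 2*pi).
    """
    g_row = (patch[2:, 1:-1] - patch[:-2, 1:-1]) / 2.0
    g_col = (patch[1:-1, 2:] - patch[1:-1, :-2]) / 2.0
    mag = np.hypot(g_row, g_col)
    ang = np.mod(np.arctan2(g_row, g_col), 2.0 * np.pi)
    if inside is not None:
        # a gradient is valid only if the sample and all four neighbours are
        valid = (
            inside[1:-1, 1:-1]
            & inside[2:, 1:-1]
            & inside[:-2, 1:-1]
            & inside[1:-1, 2:]
            & inside[1:-1, :-2]
        )
        mag = np.where(valid, mag, 0.0)
    return mag, ang


def accumulate_histogram(
    mag: np.ndarray,
    ang: np.ndarray,
    n_cells: int = 4,
    n_bins: int = 8,
    gaussian_sigma: float | None = None,
) -> np.ndarray:
    """Accumulate gradient magnitudes into the cell/orientation histogram.

    Orientation mass is soft-assigned linearly between the two adjacent
    bins; spatial assignment is hard (each sample belongs to one cell).
    Returns the flattened (n_cells*n_cells*n_bins,) histogram, unnormalised.
    """
    g = mag.shape[0]
    if g % n_cells != 0:
        raise ValueError(f"grid size {g} not divisible into {n_cells} cells")
    if gaussian_sigma is not None:
        half = (g - 1) / 2.0
        d = np.arange(g) - half
        w = np.exp(-(d[:, None] ** 2 + d[None, :] ** 2) / (2.0 * gaussian_sigma**2))
        mag = mag * w

    bin_width = 2.0 * np.pi / n_bins
    pos = ang / bin_width
    b0 = np.floor(pos).astype(int) % n_bins
    frac = pos - np.floor(pos)
    b1 = (b0 + 1) % n_bins

    cell_size = g // n_cells
    rows, cols = np.meshgrid(np.arange(g), np.arange(g), indexing="ij")
    cell = (rows // cell_size) * n_cells + (cols // cell_size)

    hist = np.zeros((n_cells * n_cells, n_bins))
    np.add.at(hist, (cell.ravel(), b0.ravel()), (mag * (1.0 - frac)).ravel())
    np.add.at(hist, (cell.ravel(), b1.ravel()), (mag * frac).ravel())
    return hist.ravel()


def oriented_gradient_descriptor(
    pixels: np.ndarray,
    center: tuple[float, float],
    angle: float,
    grid_size: int,
    spacing: float,
    n_cells: int = 4,
    n_bins: int = 8,
    gaussian_sigma: float | None = None,
    clip: float | None = None,
) -> np.ndarray:
    """Full pipeline: resample, differentiate, accumulate, normalise.

    ``clip`` (e.g. 0.2) applies the SIFT-style normalise/clip/renormalise
    step; without it the histogram is L2-normalised once.  A patch with no
    gradient mass yields the uniform unit-norm fallback.
    """
    patch, inside = sample_rotated_patch(
        pixels, center, grid_size + 2, spacing, angle
    )
    mag, ang = patch_gradients(patch, inside)
    vec = accumulate_histogram(mag, ang, n_cells, n_bins, gaussian_sigma)
    norm = np.linalg.norm(vec)
    if norm < 1e-12:
        return uniform_fallback(vec.size)
    vec = vec / norm
    if clip is not None:
        vec = np.minimum(vec, clip)
        norm = np.linalg.norm(vec)
        if norm < 1e-12:
            return uniform_fallback(vec.size)
        vec = vec / norm
    return vec
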