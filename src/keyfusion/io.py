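"""Volume I/O, down-sampling and slicing.

Axis convention (fixed package-wide): after reorientation to the closest
canonical (RAS) orientation, data axis 0 indexes sagittal planes, axis 1
coronal planes and axis 2 axial planes.  Slicing a volume along one
orientation is a plain index along the corresponding axis, so slice pixels
are views of the volume:

* sagittal slice ``l``: ``data[l, :, :]``  (rows = coronal, cols = axial)
* coronal  slice ``l``: ``data[:, l, :]``  (rows = sagittal, cols = axial)
* axial    slice ``l``: ``data[:, :, l]``  (rows = sagittal, cols = coronal)

All voxel/pixel coordinates are 0-based; the slice order is the 0-based
index along the orthogonal axis.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import nibabel as nib
import numpy as np
import pandas as pd
from skimage.measure import block_reduce

ORIENTATIONS = ("sagittal", "coronal", "axial")
_ORIENT_AXIS = {"sagittal": 0, "coronal": 1, "axial": 2}

GROUPS = ("patient", "control", "template", "test")


@dataclass
class Volume:
    """A 3D single-channel intensity volume with cohort metadata."""

    data: np.ndarray
    subject_id: str
    group: str

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"volume data must be 3D, got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume intensities must be finite")
        if np.any(self.data < 0):
            raise ValueError("volume intensities must be >= 0")
        if min(self.data.shape) < 16:
            raise ValueError(
                f"every volume dimension must be >= 16, got shape {self.data.shape}"
            )
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]


@dataclass
class Slice2D:
    """One 2D plane of a volume, tagged with its orientation and order."""

    orientation: str
    order: int
    pixels: np.ndarray

    def __post_init__(self) -> None:
        if self.orientation not in ORIENTATIONS:
            raise ValueError(f"unknown orientation {self.orientation!r}")
        if self.order < 0:
            raise ValueError("slice order must be >= 0")


def load_volume(path: str | Path, subject_id: str, group: str) -> Volume:
    """Load a 3D NIfTI-1 file, reoriented to canonical (RAS) axes.

    Raises ``IOError`` for unreadable files and ``ValueError`` for images
    that are not 3D single-channel.
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several exception types
        raise IOError(f"cannot read NIfTI file {path}: {exc}") from exc
    img = nib.as_closest_canonical(img)
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data) if data.ndim > 3 and all(
        s == 1 for s in data.shape[3:]
    ) else data
    if data.ndim != 3:
        raise ValueError(
            f"{path}: expected a 3D single-channel image, got shape {data.shape}"
        )
    return Volume(data=np.asarray(data, dtype=np.float64), subject_id=subject_id, group=group)


def save_volume(v: Volume, path: str | Path) -> None:
    """Write a volume as NIfTI-1 with an identity (RAS) affine."""
    img = nib.Nifti1Image(v.data.astype(np.float32), affine=np.eye(4))
    nib.save(img, str(path))


def downsample_volume(v: Volume, factor: int) -> Volume:
    """Block-mean down-sample by an integer factor along every axis.

    Shapes not divisible by ``factor`` are zero-padded at the high end
    before averaging.  ``factor=1`` returns the volume unchanged.
    """
    if factor < 1:
        raise ValueError(f"downsample factor must be >= 1, got {factor}")
    if factor == 1:
        return v
    data = block_reduce(v.data, block_size=(factor,) * 3, func=np.mean, cval=0.0)
    return Volume(data=data, subject_id=v.subject_id, group=v.group)


def get_slice(v: Volume, orientation: str, order: int) -> Slice2D:
    """Extract a single tagged plane."""
    axis = _ORIENT_AXIS[orientation]
    if not 0 <= order < v.data.shape[axis]:
        raise IndexError(
            f"slice order {order} out of range for {orientation} axis of length "
            f"{v.data.shape[axis]}"
        )
    pixels = np.take(v.data, order, axis=axis)
    return Slice2D(orientation=orientation, order=order, pixels=pixels)


def slice_volume(v: Volume) -> list[Slice2D]:
    """Decompose a volume into all 2D planes of the three orientations.

    Returns exactly ``n_sag + n_cor + n_ax`` slices, sagittal first, then
    coronal, then axial, each in increasing order.
    """
    out: list[Slice2D] = []
    for orientation in ORIENTATIONS:
        axis = _ORIENT_AXIS[orientation]
        for order in range(v.data.shape[axis]):
            out.append(get_slice(v, orientation, order))
    return out


def iter_slices(v: Volume) -> Iterator[Slice2D]:
    for orientation in ORIENTATIONS:
        axis = _ORIENT_AXIS[orientation]
        for order in range(v.data.shape[axis]):
            yield get_slice(v, orientation, order)


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a cohort manifest CSV with columns subject_id, path, group.

    Relative paths are resolved against the manifest's own directory.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"subject_id": str, "path": str, "group": str})
    missing = {"subject_id", "path", "group"} - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path} missing columns: {sorted(missing)}")
    df["path"] = [
        str((path.parent / p).resolve()) if not Path(p).is_absolute() else p
        for p in df["path"]
    ]
    bad = set(df["group"]) - set(GROUPS)
    if bad:
        raise ValueError(f"manifest {path} has unknown group labels: {sorted(bad)}")
    return df


def load_cohort(manifest: pd.DataFrame) -> list[Volume]:
    """Load every subject listed in a manifest DataFrame."""
    return [
        load_volume(row.path, subject_id=row.subject_id, group=row.group)
        for row in manifest.itertuples()
    ]
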