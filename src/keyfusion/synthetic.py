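"""Synthetic cohorts with planted landmarks and controllable group effects.

The generator emulates the situation the pipeline is designed for: a
template volume containing blob-like "anatomical" landmarks, and a cohort
of affine-aligned subject volumes that are noisy, locally jittered copies
of it.  Each landmark is an anisotropic Gaussian blob carrying an oriented
sinusoidal grating (a distinct local gradient texture), rendered
analytically so that per-subject landmark jitter is a true sub-voxel
displacement rather than a resampling artefact.

The group difference is injected at a chosen subset of landmarks as a
*structural* texture perturbation: in patient subjects the oriented
grating at an effect landmark is blended toward a concentric-ring pattern
of the same wavelength, amplitude and envelope, with blend weight
``0.75 * min(effect_magnitude, 1)`` (capped below 1 so the residual grating
still dominates the orientation vote and both groups are described in the
same rotational frame).  A ring pattern spreads gradient
orientations over all directions where a grating concentrates them on one
axis, so the difference is visible to an oriented-gradient descriptor in a
way that no global rotation can hide (the descriptors are rotated to the
keypoint's dominant orientation before comparison, which makes a mere
grating rotation — or a frequency change under L2 normalisation —
invisible by design).  Mean intensity, contrast and the blob envelope are
untouched, so detectability and SIFT matching are preserved and coarse
gray values carry much less of the difference than gradients do.
``effect_magnitude = 0`` makes the patient and control generators
distributionally identical.

Landmarks are placed on a 3-valued grid per axis such that every occupied
slice of every orientation holds at least two landmarks; a lone candidate
on a slice could never be matched under the ratio test's single-candidate
rejection rule.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import Volume, save_volume
from .keypoints import FeatureRecord

_SLICE_TO_VOXEL = {
    # orientation -> (axis of slice order, axes of (row, col))
    "sagittal": (0, (1, 2)),
    "coronal": (1, (0, 2)),
    "axial": (2, (0, 1)),
}


def record_voxel_coords(rec: FeatureRecord, factor: int = 1) -> np.ndarray:
    """3D voxel coordinates of a keypoint record (original resolution)."""
    axis, (ra, ca) = _SLICE_TO_VOXEL[rec.orientation]
    out = np.empty(3)
    off = (factor - 1) / 2.0
    out[axis] = rec.order * factor + off
    out[ra] = rec.location[0] * factor + off
    out[ca] = rec.location[1] * factor + off
    return out


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Study conditions for one synthetic cohort.

    ``noise_sd`` is the voxel noise standard deviation as a fraction of the
    landmark blob amplitude; ``jitter_sd`` the per-landmark location jitter
    in voxels; ``effect_magnitude`` scales the patient-group texture
    perturbation (0 = null cohort).
    """

    n_patient: int = 10
    n_control: int = 10
    shape: tuple[int, int, int] = (64, 64, 64)
    n_landmarks: int = 12
    n_effect_landmarks: int = 6
    effect_magnitude: float = 1.0
    jitter_sd: float = 1.0
    noise_sd: float = 0.05
    seed: int = 0
    blob_scale: float = 3.0  # Gaussian sigma of a landmark blob, voxels
    blob_amplitude: float = 1.0
    texture_amplitude: float = 0.5  # relative modulation depth of the grating
    texture_wavelength: float = 4.0  # voxels
    margin: int = 18  # landmark distance from the volume faces

    def __post_init__(self) -> None:
        if self.n_effect_landmarks > self.n_landmarks:
            raise ValueError("n_effect_landmarks cannot exceed n_landmarks")
        if min(self.n_patient, self.n_control) < 0 or self.n_landmarks < 0:
            raise ValueError("counts must be >= 0")
        if self.effect_magnitude < 0:
            raise ValueError("effect_magnitude must be >= 0")
        if min(self.shape) < 2 * self.margin:
            raise ValueError(
                f"shape {self.shape} too small for landmark margin {self.margin}"
            )

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["shape"] = list(self.shape)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticCohortSpec":
        d = dict(d)
        if "shape" in d:
            d["shape"] = tuple(d["shape"])
        return cls(**d)


@dataclass
class Landmark:
    """Ground truth for one planted blob."""

    index: int
    center: np.ndarray  # 3 voxel coordinates
    scale: float
    axis_ratios: np.ndarray  # per-axis anisotropy of the blob
    texture_angle: float  # grating orientation in the axial plane, radians
    has_effect: bool

    def to_dict(self) -> dict:
        return {
            "index": self.index,
            "center": self.center.tolist(),
            "scale": self.scale,
            "axis_ratios": self.axis_ratios.tolist(),
            "texture_angle": self.texture_angle,
            "has_effect": self.has_effect,
        }


def _grid_positions(spec: SyntheticCohortSpec) -> list[tuple[int, int, int]]:
    """Landmark grid indices; every occupied plane holds >= 2 landmarks."""
    if spec.n_landmarks == 0:
        return []
    classes: dict[int, list] = {0: [], 1: [], 2: []}
    for ijk in itertools.product(range(3), repeat=3):
        classes[sum(ijk) % 3].append(ijk)
    ordered = classes[0] + classes[1] + classes[2]
    if spec.n_landmarks > len(ordered):
        raise ValueError(f"at most {len(ordered)} landmarks supported")
    return ordered[: spec.n_landmarks]


def _grid_values(spec: SyntheticCohortSpec) -> list[np.ndarray]:
    return [
        np.linspace(spec.margin, s - 1 - spec.margin, 3) for s in spec.shape
    ]


def make_landmarks(spec: SyntheticCohortSpec) -> list[Landmark]:
    """Deterministic landmark layout and texture assignment for a spec."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    values = _grid_values(spec)
    landmarks = []
    sep = min(float(v[1] - v[0]) for v in values)
    if sep < 4 * spec.blob_scale:
        raise ValueError(
            f"landmark separation {sep:.1f} < 4 * blob scale {spec.blob_scale}"
        )
    for idx, ijk in enumerate(_grid_positions(spec)):
        center = np.array([values[a][ijk[a]] for a in range(3)], dtype=float)
        landmarks.append(
            Landmark(
                index=idx,
                center=center,
                scale=spec.blob_scale,
                axis_ratios=rng.uniform(0.85, 1.2, size=3),
                texture_angle=(idx * np.pi / 7.0) % np.pi,
                has_effect=idx < spec.n_effect_landmarks,
            )
        )
    return landmarks


def _render(
    spec: SyntheticCohortSpec,
    landmarks: list[Landmark],
    centers: np.ndarray,
    angles: np.ndarray,
    wavelengths: np.ndarray,
    phases: np.ndarray,
    ring_weights: np.ndarray | None = None,
) -> np.ndarray:
    """Render background + textured blobs at the given per-landmark state."""
    shape = spec.shape
    data = np.full(shape, 0.3)
    # broad background bump so slices are never constant
    grids = np.ogrid[: shape[0], : shape[1], : shape[2]]
    mid = [(s - 1) / 2.0 for s in shape]
    bg = np.exp(
        -sum((g - m) ** 2 for g, m in zip(grids, mid)) / (2.0 * (0.6 * min(shape)) ** 2)
    )
    data += 0.2 * bg
    if ring_weights is None:
        ring_weights = np.zeros(len(landmarks))
    for lm, c, ang, lam, ph, beta in zip(
        landmarks, centers, angles, wavelengths, phases, ring_weights
    ):
        sig = lm.scale * lm.axis_ratios
        sig_tex = 2.5 * lm.scale  # texture fills the 16x16 descriptor block
        r = int(math.ceil(2.5 * sig_tex))
        lo = [max(0, int(math.floor(c[a])) - r) for a in range(3)]
        hi = [min(shape[a], int(math.ceil(c[a])) + r + 1) for a in range(3)]
        local = np.ogrid[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
        d2 = sum(((g - c[a]) / sig[a]) ** 2 for a, g in enumerate(local))
        env = np.exp(-d2 / 2.0)
        d2_tex = sum((g - c[a]) ** 2 for a, g in enumerate(local)) / sig_tex**2
        env_tex = np.exp(-d2_tex / 2.0)
        kvec = 2.0 * np.pi / lam * np.array([np.cos(ang), np.sin(ang), 0.0])
        phase = sum(kvec[a] * (local[a] - c[a]) for a in range(3)) + ph
        wave = np.cos(phase)
        if beta > 0:
            # concentric spherical shells, same wavelength and phase; every
            # slice orientation through the landmark sees a ring pattern
            rho = np.sqrt(sum((local[a] - c[a]) ** 2 for a in range(3)))
            rings = np.cos(2.0 * np.pi / lam * rho + ph)
            wave = (1.0 - beta) * wave + beta * rings
        data[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] += spec.blob_amplitude * (
            env + spec.texture_amplitude * env_tex * wave
        )
    return np.clip(data, 0.0, None)


def generate_template(
    spec: SyntheticCohortSpec,
) -> tuple[Volume, list[Landmark]]:
    """Template volume plus landmark ground truth; deterministic in the seed."""
    landmarks = make_landmarks(spec)
    n = len(landmarks)
    data = _render(
        spec,
        landmarks,
        centers=np.array([lm.center for lm in landmarks]).reshape(n, 3),
        angles=np.array([lm.texture_angle for lm in landmarks]),
        wavelengths=np.full(n, spec.texture_wavelength),
        phases=np.zeros(n),
    )
    return Volume(data=data, subject_id="template", group="template"), landmarks


def generate_subject(
    landmarks: list[Landmark],
    group: str,
    spec: SyntheticCohortSpec,
    rng: np.random.Generator,
    subject_id: str,
) -> Volume:
    """One subject volume: jittered, noisy, and (if patient) texture-shifted.

    All subjects share the template layout with per-landmark location
    jitter, per-subject texture variation scaled by ``jitter_sd`` (angle sd
    0.05 * jitter_sd rad, phase sd 1.2 * jitter_sd rad), so ``jitter_sd = 0``
    with ``noise_sd = 0`` reproduces the template layout exactly and additive voxel noise.  Patients additionally carry the
    grating-to-rings effect perturbation at the effect landmarks.
    """
    n = len(landmarks)
    centers = np.array([lm.center for lm in landmarks]).reshape(n, 3)
    centers = centers + rng.normal(0.0, spec.jitter_sd, size=(n, 3))
    angles = np.array([lm.texture_angle for lm in landmarks])
    angles = angles + rng.normal(0.0, 0.05 * spec.jitter_sd, size=n)
    wavelengths = np.full(n, spec.texture_wavelength)
    phases = rng.normal(0.0, 1.2 * spec.jitter_sd, size=n)
    ring_weights = np.zeros(n)
    if group == "patient" and spec.effect_magnitude > 0:
        for i, lm in enumerate(landmarks):
            if lm.has_effect:
                # cap below 1 so the grating still wins the orientation
                # vote and both groups share a stable descriptor frame
                ring_weights[i] = 0.75 * min(spec.effect_magnitude, 1.0)
    data = _render(spec, landmarks, centers, angles, wavelengths, phases, ring_weights)
    if spec.noise_sd > 0:
        data = data + rng.normal(
            0.0, spec.noise_sd * spec.blob_amplitude, size=data.shape
        )
    return Volume(data=np.clip(data, 0.0, None), subject_id=subject_id, group=group)


def generate_cohort(
    spec: SyntheticCohortSpec,
) -> tuple[Volume, list[Volume], list[Landmark]]:
    """Template, labelled subject volumes and ground truth for a spec."""
    template, landmarks = generate_template(spec)
    subjects = []
    for i in range(spec.n_patient):
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 2, i]))
        subjects.append(
            generate_subject(landmarks, "patient", spec, rng, f"p{i:03d}")
        )
    for i in range(spec.n_control):
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 3, i]))
        subjects.append(
            generate_subject(landmarks, "control", spec, rng, f"c{i:03d}")
        )
    return template, subjects, landmarks


def write_cohort(
    spec: SyntheticCohortSpec, out_dir: str | Path
) -> tuple[Path, Path, Path]:
    """Write template, subjects, manifest CSV and ground-truth JSON to disk."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    template, subjects, landmarks = generate_cohort(spec)
    template_path = out_dir / "template.nii.gz"
    save_volume(template, template_path)
    rows = []
    for v in subjects:
        p = out_dir / f"{v.subject_id}.nii.gz"
        save_volume(v, p)
        rows.append({"subject_id": v.subject_id, "path": p.name, "group": v.group})
    manifest_path = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest_path, index=False)
    truth_path = out_dir / "ground_truth.json"
    truth_path.write_text(
        json.dumps(
            {
                "spec": spec.to_dict(),
                "landmarks": [lm.to_dict() for lm in landmarks],
            },
            indent=2,
        )
    )
    return template_path, manifest_path, truth_path


def assign_keypoints_to_landmarks(
    records: list[FeatureRecord],
    landmarks: list[Landmark],
    factor: int = 1,
    max_dist: float | None = None,
) -> list[int | None]:
    """Nearest-landmark assignment for keypoints (None beyond ``max_dist``).

    ``max_dist`` defaults to 2.3x the blob scale, covering the textured
    neighbourhood a landmark imprints while staying below half the minimum
    landmark separation.
    """
    if max_dist is None and landmarks:
        max_dist = 2.3 * landmarks[0].scale
    centers = np.array([lm.center for lm in landmarks]).reshape(len(landmarks), 3)
    out: list[int | None] = []
    for rec in records:
        if not landmarks:
            out.append(None)
            continue
        v = record_voxel_coords(rec, factor)
        d = np.linalg.norm(centers - v, axis=1)
        j = int(np.argmin(d))
        out.append(j if d[j] <= max_dist else None)
    return out
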