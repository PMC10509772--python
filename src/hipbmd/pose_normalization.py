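"""Two-stage landmark-driven rotation of the femur to the neutral position.

Stage 1 uses the two distal shaft landmarks (2 cm and 5 cm below the
lesser-trochanter tip): the single minimal rotation that maps the shaft
axis onto +z removes flexion and abduction.  Stage 2 uses the head and
neck centres: a rotation about +z brings the neck axis into the coronal
plane (zero anteroposterior component), compensating axial rotation and
femoral anteversion.  After both stages the femur stands the way a DXA
technologist would position the leg.

Angle report convention: abduction/flexion are the coronal/sagittal tilt
components of the original shaft axis, ``abduction = atan2(u_x, u_z)``
and ``flexion = atan2(u_y, u_z)``; ``axial_rotation`` is the detected
axial malrotation, i.e. minus the stage-2 correction angle, so a femur
with anteversion ``a`` imaged with axial rotation ``r`` reports
``a + r`` degrees.

Pivots (they do not affect the projected areal density, which is
translation-invariant, but are fixed for reproducibility): stage 1
rotates about the femur-mask centroid, stage 2 about the head centre.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .volumes_io import (
    CTVolume,
    DensityVolume,
    LabelMask,
    LandmarkSet,
    VolumeError,
    _Grid3,
)

__all__ = [
    "PoseTransform",
    "AnglesDecomposition",
    "PoseError",
    "shaft_axis",
    "stage1_transform",
    "stage2_transform",
    "resample_trilinear",
    "transform_landmarks",
    "decompose_angles",
    "compose_transforms",
    "mask_centroid",
    "angles_from_landmarks",
]


class PoseError(ValueError):
    """Raised for degenerate landmark geometry."""


Z = np.array([0.0, 0.0, 1.0])

_DEFAULT_FILL = {CTVolume: -1024.0, DensityVolume: 0.0, LabelMask: 0}


@dataclass(frozen=True)
class PoseTransform:
    """Rigid map ``x -> R (x - pivot) + pivot + translation``.

    ``translation`` is zero for the two elementary stages and only
    non-zero for composites of rotations about different pivots.
    """

    rotation: np.ndarray
    pivot: np.ndarray
    stage: str  # stage1 | stage2 | composite
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        object.__setattr__(self, "rotation",
                           np.asarray(self.rotation, dtype=float).reshape(3, 3))
        object.__setattr__(self, "pivot",
                           np.asarray(self.pivot, dtype=float).reshape(3))
        object.__setattr__(self, "translation",
                           np.asarray(self.translation, dtype=float).reshape(3))
        R = self.rotation
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise PoseError("rotation must be orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-9):
            raise PoseError("rotation must be proper (det +1)")
        if self.stage not in ("stage1", "stage2", "composite"):
            raise PoseError(f"unknown stage {self.stage!r}")

    def apply(self, points) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = (pts - self.pivot) @ self.rotation.T + self.pivot + self.translation
        return out[0] if np.ndim(points) == 1 else out

    def apply_inverse(self, points) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = (pts - self.pivot - self.translation) @ self.rotation + self.pivot
        return out[0] if np.ndim(points) == 1 else out

    def to_json(self) -> str:
        return json.dumps(
            {
                "rotation": self.rotation.reshape(-1).tolist(),  # row-major
                "pivot": self.pivot.tolist(),
                "translation": self.translation.tolist(),
                "stage": self.stage,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "PoseTransform":
        obj = json.loads(text)
        return cls(
            np.asarray(obj["rotation"]).reshape(3, 3),
            np.asarray(obj["pivot"]),
            obj["stage"],
            np.asarray(obj.get("translation", [0.0, 0.0, 0.0])),
        )

    @classmethod
    def identity(cls, pivot=(0.0, 0.0, 0.0), stage: str = "composite"):
        return cls(np.eye(3), np.asarray(pivot, dtype=float), stage)


@dataclass(frozen=True)
class AnglesDecomposition:
    """Detected positioning angles, degrees, each in (-180, 180]."""

    abduction: float        # shaft tilt in the coronal (x-z) plane
    flexion: float          # shaft tilt in the sagittal (y-z) plane
    axial_rotation: float   # neck-axis rotation about the superior axis

    def __post_init__(self):
        for v in (self.abduction, self.flexion, self.axial_rotation):
            if not np.isfinite(v):
                raise PoseError("angles must be finite")


def _wrap_deg(a: float) -> float:
    a = (a + 180.0) % 360.0 - 180.0
    return 180.0 if a == -180.0 else a


def shaft_axis(lm: LandmarkSet) -> np.ndarray:
    """Distal-to-proximal unit vector of the femoral shaft."""
    lm.require(["LT_DISTAL_2CM", "LT_DISTAL_5CM"])
    v = lm["LT_DISTAL_2CM"] - lm["LT_DISTAL_5CM"]
    n = np.linalg.norm(v)
    if n < 1e-9:
        raise PoseError("shaft landmarks coincide; axis undefined")
    return v / n


def stage1_transform(axis, pivot) -> PoseTransform:
    """Minimal rotation mapping the shaft axis onto +z (about axis x z)."""
    u = np.asarray(axis, dtype=float)
    u = u / np.linalg.norm(u)
    c = float(np.clip(u @ Z, -1.0, 1.0))
    if c < -1.0 + 1e-6:
        raise PoseError(
            "shaft axis is antiparallel to +z; minimal rotation is ambiguous"
        )
    k = np.cross(u, Z)
    s = np.linalg.norm(k)
    if s < 1e-15:
        return PoseTransform(np.eye(3), pivot, "stage1")
    k = k / s
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    R = np.eye(3) + s * K + (1.0 - c) * (K @ K)
    # re-orthonormalize for a clean det-+1 matrix
    u_, _, vt = np.linalg.svd(R)
    return PoseTransform(u_ @ vt, pivot, "stage1")


def _rot_z(theta_rad: float) -> np.ndarray:
    c, s = np.cos(theta_rad), np.sin(theta_rad)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def stage2_transform(lm_stage1: LandmarkSet, pivot) -> PoseTransform:
    """Axial rotation putting the neck axis into the coronal plane.

    After application the neck axis (neck centre -> head centre) has zero
    anteroposterior (y) component in the axial plane, with the head on
    the medial (-x) side of the left-femur convention.
    """
    lm_stage1.require(["HEAD_CENTER", "NECK_CENTER"])
    v = lm_stage1["HEAD_CENTER"] - lm_stage1["NECK_CENTER"]
    vxy = np.hypot(v[0], v[1])
    if vxy < 1e-6 * max(np.linalg.norm(v), 1e-12) or vxy < 1e-9:
        raise PoseError("neck axis is parallel to z; axial direction undefined")
    phi = np.arctan2(v[1], v[0])
    theta = np.pi - phi  # rotate the axial neck direction onto -x
    theta = np.arctan2(np.sin(theta), np.cos(theta))
    return PoseTransform(_rot_z(theta), pivot, "stage2")


def compose_transforms(t2: PoseTransform, t1: PoseTransform) -> PoseTransform:
    """Composite transform applying ``t1`` first, then ``t2``."""
    R = t2.rotation @ t1.rotation
    # about pivot p1: translation fixed by matching the image of p1 itself
    tr = t2.apply(t1.apply(t1.pivot)) - t1.pivot
    return PoseTransform(R, t1.pivot, "composite", tr)


def mask_centroid(mask: LabelMask) -> np.ndarray:
    """World-mm centroid of the non-zero voxels of a mask."""
    idx = np.argwhere(mask.labels > 0)
    if idx.size == 0:
        raise VolumeError("mask is empty; centroid undefined")
    return mask.index_to_world(idx.mean(axis=0))


def resample_trilinear(vol: _Grid3, t: PoseTransform, fill=None) -> _Grid3:
    """Resample a volume under a rigid transform, onto its own grid.

    Output voxel at world position w takes the input value at
    ``t^{-1}(w)`` with trilinear interpolation (nearest-neighbour for
    label masks).  Samples falling outside the input field of view take
    ``fill`` (default 0 for density, -1024 HU for CT, 0 for labels).
    """
    if fill is None:
        fill = _DEFAULT_FILL.get(type(vol), 0.0)
    A = vol.direction * vol.spacing[None, :]  # index -> world linear part
    A_inv = np.linalg.inv(A)
    R = t.rotation
    # source_index = A^-1 (R^T (A i + o - p - d) + p - o)
    B = A_inv @ R.T @ A
    b = A_inv @ (R.T @ (vol.origin - t.pivot - t.translation) + t.pivot - vol.origin)
    order = 0 if isinstance(vol, LabelMask) else 1
    data = vol.voxels if order == 0 else np.asarray(vol.voxels, dtype=np.float64)
    out = ndimage.affine_transform(
        data, B, offset=b, order=order, mode="constant", cval=fill,
        prefilter=False,
    )
    if isinstance(vol, LabelMask):
        out = out.astype(vol.voxels.dtype)
    return vol.with_voxels(out)


def transform_landmarks(lm: LandmarkSet, t: PoseTransform) -> LandmarkSet:
    """Rotate every point about the pivot; advance the frame tag."""
    new_frame = {"stage1": "stage1", "stage2": "stage2",
                 "composite": "stage2"}[t.stage]
    return LandmarkSet(
        {n: t.apply(p) for n, p in lm.points.items()}, frame=new_frame
    )


def decompose_angles(t1: PoseTransform, t2: PoseTransform) -> AnglesDecomposition:
    """Positioning angles implied by the two neutralizing rotations."""
    if t1.stage != "stage1" or t2.stage != "stage2":
        raise PoseError("decompose_angles expects a stage1 and a stage2 transform")
    u = t1.rotation.T @ Z  # original shaft axis (stage1 maps it onto +z)
    abduction = np.degrees(np.arctan2(u[0], u[2]))
    flexion = np.degrees(np.arctan2(u[1], u[2]))
    theta_corr = np.degrees(np.arctan2(t2.rotation[1, 0], t2.rotation[0, 0]))
    return AnglesDecomposition(
        abduction=_wrap_deg(abduction),
        flexion=_wrap_deg(flexion),
        axial_rotation=_wrap_deg(-theta_corr),
    )


def angles_from_landmarks(lm: LandmarkSet, pivot=None):
    """Run both stages on a landmark set alone.

    Returns ``(t1, t2, angles)``; the pivot (default: landmark centroid)
    only positions the transforms and does not change the angles.
    """
    if pivot is None:
        pivot = lm.array().mean(axis=0)
    t1 = stage1_transform(shaft_axis(lm), pivot)
    lm1 = transform_landmarks(lm, t1)
    t2 = stage2_transform(lm1, lm1["HEAD_CENTER"])
    return t1, t2, decompose_angles(t1, t2)
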