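"""Sources of the nine proximal-femur landmarks.

Landmarks can come from files (first-class input, see
:mod:`hipbmd.volumes_io`), from a detector plugin discovered through the
``hipbmd.detectors`` entry-point group, or from the built-in geometric
heuristic :func:`detect_synthetic` that is valid on the synthetic femora
of :mod:`hipbmd.synthetic_data` — it lets the pipeline run end-to-end
without any trained network.

The module also provides the detector-facing preprocessing (crop to the
femur bounding box and downsample to 128^3) and the training-time pose
augmentation sampler with the standard ranges: translation within
+/-25 % of the matrix size, rotation within +/-30 deg about x and
+/-15 deg about y and z, scaling within +/-20 %.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib.metadata import entry_points

import numpy as np
from scipy import ndimage

from .volumes_io import CTVolume, LabelMask, LandmarkSet, VolumeError, _Grid3

__all__ = [
    "AugmentationSpec",
    "AugmentationSample",
    "CropRecord",
    "LandmarkDetection",
    "crop_and_downsample",
    "sample_augmentation",
    "detect_synthetic",
    "get_detector",
    "register_detector",
]


@dataclass(frozen=True)
class AugmentationSpec:
    """Pose augmentation ranges (all symmetric about zero)."""

    translation_frac: float = 0.25  # fraction of the matrix size, per axis
    rot_x_deg: float = 30.0
    rot_y_deg: float = 15.0
    rot_z_deg: float = 15.0
    scale_frac: float = 0.20
    seed: int = 0

    def __post_init__(self):
        for v in (self.translation_frac, self.rot_x_deg, self.rot_y_deg,
                  self.rot_z_deg, self.scale_frac):
            if v < 0:
                raise ValueError("augmentation ranges must be non-negative")


@dataclass(frozen=True)
class AugmentationSample:
    translation_frac: tuple[float, float, float]
    rot_x_deg: float
    rot_y_deg: float
    rot_z_deg: float
    scale_frac: float


def sample_augmentation(spec: AugmentationSpec, n: int) -> list[AugmentationSample]:
    """Draw ``n`` pose parameter sets, uniform within the spec's ranges."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(spec.seed)
    tr = rng.uniform(-spec.translation_frac, spec.translation_frac, (n, 3))
    rx = rng.uniform(-spec.rot_x_deg, spec.rot_x_deg, n)
    ry = rng.uniform(-spec.rot_y_deg, spec.rot_y_deg, n)
    rz = rng.uniform(-spec.rot_z_deg, spec.rot_z_deg, n)
    sc = rng.uniform(-spec.scale_frac, spec.scale_frac, n)
    return [
        AugmentationSample(tuple(tr[i]), float(rx[i]), float(ry[i]),
                           float(rz[i]), float(sc[i]))
        for i in range(n)
    ]


# ---------------------------------------------------------------------------
# detector-facing preprocessing
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CropRecord:
    """Exact affine between downsampled indices and world mm."""

    origin: np.ndarray
    spacing: np.ndarray
    direction: np.ndarray
    lo_index: np.ndarray   # crop window start, input index space
    scale: np.ndarray      # input voxels per output voxel, per axis

    def index_to_world(self, index) -> np.ndarray:
        idx = np.atleast_2d(np.asarray(index, dtype=float))
        pts = idx * self.spacing[None, :] @ self.direction.T + self.origin
        return pts[0] if np.ndim(index) == 1 else pts

    def world_to_index(self, point) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(point, dtype=float))
        idx = (pts - self.origin) @ self.direction / self.spacing[None, :]
        return idx[0] if np.ndim(point) == 1 else idx


def crop_and_downsample(
    vol: _Grid3,
    femur_mask: LabelMask,
    out_size: int = 128,
    margin_frac: float = 0.10,
):
    """Crop to the femur bounding box (padded) and resample to ``out_size^3``.

    This is the preprocessing a landmark detector sees.  Returns the
    resampled volume and a :class:`CropRecord` that maps downsampled
    indices back to world mm exactly.
    """
    idx = np.argwhere(femur_mask.labels > 0)
    if idx.size == 0:
        raise VolumeError("femur mask is empty; nothing to crop")
    lo = idx.min(axis=0).astype(float)
    hi = idx.max(axis=0).astype(float)
    size = hi - lo + 1.0
    lo = np.maximum(lo - margin_frac * size, 0.0)
    hi = np.minimum(hi + margin_frac * size, np.array(vol.shape) - 1.0)

    scale = (hi - lo + 1.0) / out_size
    # output voxel u covers input indices [lo + u*scale, lo + (u+1)*scale)
    offset = lo - 0.5 + 0.5 * scale
    order = 0 if isinstance(vol, LabelMask) else 1
    data = vol.voxels if order == 0 else np.asarray(vol.voxels, dtype=float)
    out = ndimage.affine_transform(
        data, np.diag(scale), offset=offset,
        output_shape=(out_size,) * 3, order=order, mode="constant",
        cval=0.0, prefilter=False,
    )
    if isinstance(vol, LabelMask):
        out = out.astype(vol.voxels.dtype)
    record = CropRecord(
        origin=vol.index_to_world(offset),
        spacing=vol.spacing * scale,
        direction=vol.direction.copy(),
        lo_index=lo,
        scale=scale,
    )
    resampled = vol.with_voxels(out)
    resampled.spacing = record.spacing
    resampled.origin = record.origin
    return resampled, record


# ---------------------------------------------------------------------------
# built-in geometric detector for synthetic femora
# ---------------------------------------------------------------------------


@dataclass
class LandmarkDetection:
    """Detector output: landmarks in world mm plus per-landmark confidence."""

    landmarks: LandmarkSet
    confidence: dict[str, float] = field(default_factory=dict)


class DetectionError(ValueError):
    """Raised when the heuristic detector cannot interpret a mask."""


def _fit_sphere(points: np.ndarray):
    """Algebraic least-squares sphere fit; returns (center, radius)."""
    A = np.column_stack([2.0 * points, np.ones(len(points))])
    b = np.sum(points**2, axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    center = sol[:3]
    r2 = sol[3] + center @ center
    return center, float(np.sqrt(max(r2, 0.0)))


def detect_synthetic(femur_mask: LabelMask) -> LandmarkDetection:
    """Geometric landmark heuristic for synthetic femora.

    Works from the mask alone and is pose-robust: the head centre comes
    from a least-squares sphere fit, the shaft axis from the principal
    axis of the distal 40 % of the mask, the neck centre from the
    minimal cross-section between head and trochanter, the
    lesser-trochanter tip from the maximal medial offset off the shaft
    axis, the 2 cm / 5 cm shaft points from the tip's axial station, and
    the head-neck-junction points from the head-sphere/neck intersection
    circle.  Only valid for masks produced by
    :mod:`hipbmd.synthetic_data`; clinical femora need a trained
    detector plugin or manual landmarks.
    """
    mask = femur_mask.labels > 0
    if not mask.any():
        raise DetectionError("empty femur mask")

    spacing = femur_mask.spacing
    edt = ndimage.distance_transform_edt(mask, sampling=spacing)
    r0 = float(edt.max())
    seed_idx = np.unravel_index(int(np.argmax(edt)), mask.shape)
    center0 = femur_mask.index_to_world(np.asarray(seed_idx, dtype=float))

    surface = mask & ~ndimage.binary_erosion(mask)
    surf_pts = femur_mask.index_to_world(np.argwhere(surface).astype(float))

    near = surf_pts[np.linalg.norm(surf_pts - center0, axis=1) < 1.3 * r0]
    if len(near) < 30:
        raise DetectionError("no identifiable head sphere in mask")
    head, r_head = _fit_sphere(near)
    resid = np.abs(np.linalg.norm(near - head, axis=1) - r_head)
    inliers = near[resid < 2.0]
    if len(inliers) >= 30:
        head, r_head = _fit_sphere(inliers)
    if not (0.5 * r0 < r_head < 3.0 * r0):
        raise DetectionError("head sphere fit diverged")
    if r_head < 8.0:  # far below any adult femoral head
        raise DetectionError(
            f"no identifiable head sphere: fitted radius {r_head:.1f} mm"
        )
    resid = np.abs(np.linalg.norm(near - head, axis=1) - r_head)
    if (resid < 1.5).mean() < 0.5:
        raise DetectionError(
            "no identifiable head sphere: surface is not ball-like"
        )

    # shaft axis: principal axis of the distal 40 % of the mask voxels
    vox_pts = femur_mask.index_to_world(np.argwhere(mask).astype(float))
    dist_to_head = np.linalg.norm(vox_pts - head, axis=1)
    cut = np.quantile(dist_to_head, 0.60)
    distal = vox_pts[dist_to_head >= cut]
    centroid = distal.mean(axis=0)
    cov = np.cov((distal - centroid).T)
    evals, evecs = np.linalg.eigh(cov)
    axis = evecs[:, np.argmax(evals)]
    if axis @ (head - centroid) < 0:
        axis = -axis

    # neck direction: from the head centre toward the neck stub
    shell = vox_pts[
        (dist_to_head > r_head + 1.0) & (dist_to_head < r_head + 5.0)
    ]
    if len(shell) < 10:
        raise DetectionError("no neck stub adjacent to the head sphere")
    n_dir = head - shell.mean(axis=0)
    n_dir = n_dir / np.linalg.norm(n_dir)

    # neck centre: midpoint of the minimal cross-section along the neck
    rel = vox_pts - head
    station = -(rel @ n_dir)  # distance from head centre, toward the shaft
    lateral = np.linalg.norm(rel + station[:, None] * n_dir, axis=1)
    t_grid = np.arange(0.8 * r_head, 2.4 * r_head, 1.0)
    voxel_vol = float(np.prod(spacing))

    def corridor_scan(max_lateral):
        corridor = lateral < max_lateral
        counts = np.array(
            [int((corridor & (np.abs(station - t) < 1.0)).sum())
             for t in t_grid]
        )
        return corridor, counts

    # first pass bounds the neck radius; the second restricts the corridor
    # to it so shaft voxels stop skewing the minimal-cross-section plateau
    corridor, counts = corridor_scan(0.9 * r_head)
    if counts.min() == 0:
        raise DetectionError("neck corridor is empty")
    r_neck = float(np.sqrt(counts.min() * voxel_vol / (2.0 * np.pi)))
    corridor, counts = corridor_scan(r_neck + 4.0)
    if counts.min() == 0:
        raise DetectionError("neck corridor is empty")
    r_neck = float(np.sqrt(counts.min() * voxel_vol / (2.0 * np.pi)))
    near_min = np.flatnonzero(counts <= 1.02 * counts.min())
    t_star = 0.5 * (t_grid[near_min].min() + t_grid[near_min].max())
    slab = corridor & (np.abs(station - t_star) < 1.0)
    neck_center = vox_pts[slab].mean(axis=0)

    n_dir = head - neck_center
    n_dir = n_dir / np.linalg.norm(n_dir)

    # refit the shaft axis on pure-shaft voxels well below the trochanter;
    # the spherical distal-40% cut slices the shaft obliquely and tilts PCA
    s_all = (vox_pts - centroid) @ axis
    s_neck0 = (neck_center - centroid) @ axis
    pure = s_all < s_neck0 - 50.0
    if pure.sum() > 200:
        shaft_pts = vox_pts[pure]
        centroid = shaft_pts.mean(axis=0)
        cov = np.cov((shaft_pts - centroid).T)
        evals, evecs = np.linalg.eigh(cov)
        axis = evecs[:, np.argmax(evals)]
        if axis @ (head - centroid) < 0:
            axis = -axis

    # medial direction: component of (head - shaft centroid) off the axis
    m = head - centroid
    m = m - (m @ axis) * axis
    m = m / np.linalg.norm(m)

    # lesser-trochanter tip: maximal medial offset in the trochanteric zone
    w = vox_pts - centroid
    s_v = w @ axis
    perp = w - s_v[:, None] * axis
    medial = perp @ m
    s_neck = (neck_center - centroid) @ axis
    not_head = np.linalg.norm(vox_pts - head, axis=1) > r_head + 2.0
    # neck exclusion spans the whole neck: head centre down to where the
    # neck line meets the shaft axis (flared base included)
    delta = neck_center - head
    cross = np.cross(delta, axis)
    denom = cross @ cross
    if denom > 1e-9:
        # closest approach of the neck line to the shaft axis line
        t_base = (np.cross(centroid - head, axis) @ cross) / denom
    else:
        t_base = 1.0
    base = head + max(t_base, 1.0) * delta + 5.0 * (delta / np.linalg.norm(delta))
    seg = head - base
    seg_len2 = seg @ seg
    tt = np.clip(((vox_pts - base) @ seg) / seg_len2, 0.0, 1.0)
    d_neckline = np.linalg.norm(vox_pts - (base + tt[:, None] * seg),
                                axis=1)
    zone = (
        not_head
        & (d_neckline > r_neck + 3.0)
        & (s_v > s_neck - 60.0)
        & (s_v < s_neck - 15.0)
    )
    if not zone.any():
        raise DetectionError("no trochanteric zone voxels")
    med_zone = medial[zone]
    pts_zone = vox_pts[zone]
    top = med_zone > med_zone.max() - 1.5
    lt_tip = pts_zone[top].mean(axis=0)

    s_lt = (lt_tip - centroid) @ axis
    lt2 = centroid + (s_lt - 20.0) * axis
    lt5 = centroid + (s_lt - 50.0) * axis

    # head-neck junction circle extremes
    d_j = np.sqrt(max(r_head**2 - r_neck**2, 0.0))
    J = head - d_j * n_dir
    s_dir = axis - (axis @ n_dir) * n_dir
    s_dir = s_dir / np.linalg.norm(s_dir)
    a_dir = np.cross(s_dir, n_dir)
    a_dir = a_dir / np.linalg.norm(a_dir)

    lm = LandmarkSet(
        {
            "LT_DISTAL_2CM": lt2,
            "LT_DISTAL_5CM": lt5,
            "HEAD_CENTER": head,
            "NECK_CENTER": neck_center,
            "HNJ_SUP": J + r_neck * s_dir,
            "HNJ_ANT": J + r_neck * a_dir,
            "HNJ_POST": J - r_neck * a_dir,
            "HNJ_INF": J - r_neck * s_dir,
            "LT_TIP": lt_tip,
        },
        frame="original",
    )
    conf = {name: 1.0 for name in lm.names()}
    return LandmarkDetection(landmarks=lm, confidence=conf)


# ---------------------------------------------------------------------------
# detector registry / plugins
# ---------------------------------------------------------------------------

_REGISTRY: dict[str, object] = {
    "synthetic": lambda ct, mask: detect_synthetic(mask),
}


def register_detector(name: str, fn) -> None:
    """Register a detector callable ``fn(ct, femur_mask) -> LandmarkSet``."""
    _REGISTRY[name] = fn


def get_detector(name: str):
    """Look up a detector by name: built-ins first, then entry points.

    Plugins are python callables exposed in the ``hipbmd.detectors``
    entry-point group, taking ``(ct, femur_mask)`` and returning a
    :class:`LandmarkSet` or :class:`LandmarkDetection` with world-mm
    coordinates inside the volume bounds.
    """
    if name in _REGISTRY:
        return _REGISTRY[name]
    for ep in entry_points(group="hipbmd.detectors"):
        if ep.name == name:
            fn = ep.load()
            _REGISTRY[name] = fn
            return fn
    raise KeyError(f"no landmark detector named {name!r}")
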