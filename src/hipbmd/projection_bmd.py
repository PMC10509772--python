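"""Coronal DRR projection, proximal-femur ROI and CT-aBMD.

After calibration and pose normalization the femur stands shaft-up with
the neck in the coronal plane.  The masked density volume (negative
marrow values clipped to zero inside the bone mask, zero elsewhere) is
integrated along anteroposterior rays with trilinear sampling at a 1 mm
step, producing a DXA-like digitally reconstructed radiograph in
g/cm^2.  The projected landmarks then crop the proximal femur: bone
pixels at or above the distal border 2 cm below the lesser-trochanter
tip, with the femoral head excluded by the chord through the superior
and inferior head-neck-junction points.  CT-aBMD is the mean areal
density over the included bone pixels — the DXA definition
aBMD = BMC / bone area.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .phantom_calibration import (
    CalibrationModel,
    apply_calibration,
    extract_rod_samples,
    fit_calibration,
)
from .pose_normalization import (
    AnglesDecomposition,
    PoseTransform,
    compose_transforms,
    decompose_angles,
    mask_centroid,
    resample_trilinear,
    shaft_axis,
    stage1_transform,
    stage2_transform,
    transform_landmarks,
)
from .volumes_io import (
    CTVolume,
    DensityVolume,
    LabelMask,
    LandmarkSet,
    VolumeError,
    mirror_to_left,
)

__all__ = [
    "DRRImage",
    "ProximalROI",
    "ABMDResult",
    "Classification",
    "FixedCutoff",
    "TScoreCriterion",
    "OSTEOPOROSIS_CUTOFF_PRESET",
    "PipelineFailure",
    "PipelineResult",
    "project_coronal",
    "project_points",
    "ProjectedLandmarks",
    "define_proximal_roi",
    "compute_abmd",
    "classify_osteoporosis",
    "run_pipeline",
]


class ROIError(ValueError):
    """Raised for degenerate or empty regions of interest."""


# ---------------------------------------------------------------------------
# DRR
# ---------------------------------------------------------------------------


@dataclass
class DRRImage:
    """Coronal areal-density image in g/cm^2.

    ``pixels[row, col]``: rows run superior -> inferior (row 0 at
    ``z_top``), columns run along +x from ``x_left``.
    """

    pixels: np.ndarray
    pixel_mm: float
    x_left: float   # world x of column 0 centre
    z_top: float    # world z of row 0 centre

    def __post_init__(self):
        if self.pixel_mm <= 0:
            raise ROIError("pixel spacing must be positive")
        if self.pixels.min() < 0:
            raise ROIError("DRR pixels must be non-negative")

    @property
    def shape(self):
        return self.pixels.shape

    def world_to_pixel(self, x, z):
        """(x, z) world mm -> fractional (row, col)."""
        col = (np.asarray(x, dtype=float) - self.x_left) / self.pixel_mm
        row = (self.z_top - np.asarray(z, dtype=float)) / self.pixel_mm
        return row, col

    def pixel_to_world(self, row, col):
        x = self.x_left + np.asarray(col, dtype=float) * self.pixel_mm
        z = self.z_top - np.asarray(row, dtype=float) * self.pixel_mm
        return x, z

    @property
    def pixel_area_cm2(self) -> float:
        return (self.pixel_mm / 10.0) ** 2


def project_coronal(
    density: DensityVolume,
    femur_mask: LabelMask,
    step_mm: float = 1.0,
    pixel_mm: float = 1.0,
) -> DRRImage:
    """Integrate the masked density along +y (anteroposterior) rays.

    Each (x, z) pixel sums trilinear samples of the masked density
    (density where the mask is set, negatives clipped to zero, zero
    elsewhere) taken every ``step_mm`` along y; the pixel value is
    ``sum * step_cm / 1000`` in g/cm^2.
    """
    if not density.geometry_matches(femur_mask):
        raise VolumeError("density and femur mask geometries differ")
    masked = np.where(femur_mask.labels > 0,
                      np.clip(density.voxels, 0.0, None), 0.0)

    lo, hi = density.world_bounds()
    xs = np.arange(lo[0], hi[0] + 0.5 * pixel_mm, pixel_mm)
    zs = np.arange(hi[2], lo[2] - 0.5 * pixel_mm, -pixel_mm)
    n_steps = int(np.ceil((hi[1] - lo[1]) / step_mm))
    ys = lo[1] + (np.arange(n_steps) + 0.5) * step_mm

    # world -> index affine of the (shared) grid
    A = density.direction * density.spacing[None, :]
    A_inv = np.linalg.inv(A)

    gz, gx, gy = np.meshgrid(zs, xs, ys, indexing="ij")  # (rows, cols, steps)
    pts = np.stack([gx, gy, gz], axis=-1)
    idx = (pts.reshape(-1, 3) - density.origin) @ A_inv.T
    samples = ndimage.map_coordinates(
        masked, idx.T, order=1, mode="constant", cval=0.0, prefilter=False
    ).reshape(gz.shape)
    pixels = samples.sum(axis=-1) * (step_mm / 10.0) / 1000.0
    pixels = np.clip(pixels, 0.0, None)
    return DRRImage(pixels=pixels, pixel_mm=pixel_mm,
                    x_left=float(xs[0]), z_top=float(zs[0]))


@dataclass
class ProjectedLandmarks:
    """2-D landmark positions on a DRR, fractional (row, col)."""

    points: dict[str, tuple[float, float]]
    outside: tuple[str, ...] = ()   # flagged, never silently clamped

    def __getitem__(self, name):
        return self.points[name]

    def __contains__(self, name):
        return name in self.points


def project_points(lm: LandmarkSet, drr: DRRImage) -> ProjectedLandmarks:
    """Drop the y coordinate and map (x, z) onto the DRR pixel grid."""
    if lm.frame != "stage2":
        raise ROIError(
            "landmarks must be in the stage-2 (pose-normalized) frame before "
            "projection"
        )
    pts = {}
    outside = []
    n_rows, n_cols = drr.shape
    for name, p in lm.points.items():
        row, col = drr.world_to_pixel(p[0], p[2])
        pts[name] = (float(row), float(col))
        if not (-0.5 <= row <= n_rows - 0.5 and -0.5 <= col <= n_cols - 0.5):
            outside.append(name)
    return ProjectedLandmarks(points=pts, outside=tuple(outside))


# ---------------------------------------------------------------------------
# ROI
# ---------------------------------------------------------------------------


@dataclass
class ProximalROI:
    """Pixels of the DRR that enter the CT-aBMD average."""

    included_pixels: np.ndarray       # boolean, same shape as the DRR
    distal_row: float                 # fractional row of the distal border
    head_cut: tuple[tuple[float, float], tuple[float, float]]  # (sup, inf)
    empty: bool = False

    @property
    def n_pixels(self) -> int:
        return int(self.included_pixels.sum())


def define_proximal_roi(plm: ProjectedLandmarks, drr: DRRImage,
                        distal_margin_mm: float = 20.0) -> ProximalROI:
    """Crop the proximal femur on the DRR from the projected landmarks.

    Included pixels have positive areal density, sit at or above
    (superior to) the distal border ``distal_margin_mm`` below the
    projected lesser-trochanter tip, and lie on the neck/trochanter side
    of the chord through the projected superior and inferior head-neck
    junction points (the femoral-head side is excluded).
    """
    for name in ("LT_TIP", "HNJ_SUP", "HNJ_INF", "HEAD_CENTER"):
        if name not in plm:
            raise ROIError(f"projected landmark {name} required for the ROI")
    lt_row, _ = plm["LT_TIP"]
    distal_row = lt_row + distal_margin_mm / drr.pixel_mm

    sup = np.asarray(plm["HNJ_SUP"])
    inf = np.asarray(plm["HNJ_INF"])
    head = np.asarray(plm["HEAD_CENTER"])
    chord = inf - sup
    if np.linalg.norm(chord) < 1e-9:
        raise ROIError("degenerate head cut: HNJ_SUP and HNJ_INF coincide")

    n_rows, n_cols = drr.shape
    rows = np.arange(n_rows)[:, None]
    cols = np.arange(n_cols)[None, :]

    def side(r, c):
        return chord[0] * (c - sup[1]) - chord[1] * (r - sup[0])

    head_side = np.sign(side(head[0], head[1]))
    if head_side == 0:
        raise ROIError("head centre lies on the head-cut chord")

    included = (
        (drr.pixels > 0)
        & (rows <= distal_row + 1e-9)
        & (np.sign(side(rows, cols)) != head_side)
    )
    empty = not bool(included.any())
    return ProximalROI(
        included_pixels=included,
        distal_row=float(distal_row),
        head_cut=(tuple(sup), tuple(inf)),
        empty=empty,
    )


# ---------------------------------------------------------------------------
# aBMD and classification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FixedCutoff:
    """Osteoporotic iff aBMD < cutoff (strict)."""

    cutoff: float  # g/cm^2
    name: str = "fixed-cutoff"


@dataclass(frozen=True)
class TScoreCriterion:
    """Osteoporotic iff T = (aBMD - ref_mean)/ref_sd <= threshold.

    Reference mean/SD (young-adult values) are user configuration; none
    are shipped as defaults.
    """

    ref_mean: float
    ref_sd: float
    threshold: float = -2.5

    def __post_init__(self):
        if self.ref_sd <= 0:
            raise ValueError("reference SD must be positive")


#: Published total-proximal-femur screening cutoff, g/cm^2.
OSTEOPOROSIS_CUTOFF_PRESET = FixedCutoff(0.625, name="total-hip-0.625")


@dataclass(frozen=True)
class Classification:
    label: str                  # osteoporotic | non-osteoporotic
    t_score: float | None = None


def classify_osteoporosis(abmd: float, criterion) -> Classification:
    if isinstance(criterion, FixedCutoff):
        label = "osteoporotic" if abmd < criterion.cutoff else "non-osteoporotic"
        return Classification(label=label)
    if isinstance(criterion, TScoreCriterion):
        t = (abmd - criterion.ref_mean) / criterion.ref_sd
        label = "osteoporotic" if t <= criterion.threshold else "non-osteoporotic"
        return Classification(label=label, t_score=float(t))
    raise ValueError(
        "criterion must be a FixedCutoff or a fully specified TScoreCriterion"
    )


@dataclass
class ABMDResult:
    """CT-aBMD of the proximal femur and its bookkeeping."""

    ct_abmd: float          # g/cm^2
    bone_area: float        # cm^2
    bmc: float              # g
    n_pixels: int
    classification: str | None = None
    t_score: float | None = None
    cross_calibrated: bool = False


def compute_abmd(drr: DRRImage, roi: ProximalROI,
                 cross_calibration: tuple[float, float] | None = None) -> ABMDResult:
    """Mean areal density over the ROI (aBMD = BMC / bone area).

    ``cross_calibration`` is an optional affine (slope, intercept) map
    into another densitometer's unit system, applied last; BMC is kept
    consistent with the converted aBMD.
    """
    if roi.empty or roi.n_pixels == 0:
        raise ROIError("ROI is empty; no bone pixels to average")
    values = drr.pixels[roi.included_pixels]
    area = roi.n_pixels * drr.pixel_area_cm2
    abmd = float(values.mean())
    cross = False
    if cross_calibration is not None:
        slope, intercept = cross_calibration
        converted = slope * abmd + intercept
        cross = not (slope == 1.0 and intercept == 0.0)
        abmd = float(converted)
    return ABMDResult(
        ct_abmd=abmd,
        bone_area=float(area),
        bmc=float(abmd * area),
        n_pixels=roi.n_pixels,
        cross_calibrated=cross,
    )


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PipelineFailure:
    stage: str
    message: str


@dataclass
class PipelineResult:
    """Everything the measurement produced, or a stage-labeled failure."""

    abmd: ABMDResult | None = None
    drr: DRRImage | None = None
    roi: ProximalROI | None = None
    landmarks_stage2: LandmarkSet | None = None
    stage1: PoseTransform | None = None
    stage2: PoseTransform | None = None
    angles: AnglesDecomposition | None = None
    calibration: CalibrationModel | None = None
    mirrored: bool = False
    failure: PipelineFailure | None = None

    @property
    def success(self) -> bool:
        return self.failure is None


def run_pipeline(
    ct: CTVolume,
    femur_mask: LabelMask,
    calibration,
    landmarks,
    criterion=OSTEOPOROSIS_CUTOFF_PRESET,
    cross_calibration: tuple[float, float] | None = None,
    step_mm: float = 1.0,
    pixel_mm: float = 1.0,
) -> PipelineResult:
    """Full CT-to-aBMD measurement in the standard order.

    calibrate -> (mirror right femora to left) -> stage-1 landmarks ->
    stage-1 rotation -> full landmark set -> stage-2 rotation -> coronal
    projection -> proximal ROI -> aBMD -> classification.

    ``calibration`` is a :class:`CalibrationModel` or a tuple
    ``(rod_mask, {label: nominal_density})`` to fit one from the scan's
    own phantom.  ``landmarks`` is a :class:`LandmarkSet` in the scanner
    frame or a detector callable ``(volume, mask) -> LandmarkSet``.
    Stage errors are captured as a structured, stage-labeled failure
    record instead of propagating.
    """
    result = PipelineResult()

    def fail(stage, exc):
        result.failure = PipelineFailure(stage=stage, message=str(exc))
        return result

    # -- calibration -------------------------------------------------------
    try:
        if isinstance(calibration, CalibrationModel):
            model = calibration
        else:
            rod_mask, densities = calibration
            samples = extract_rod_samples(ct, rod_mask, densities)
            model = fit_calibration(samples)
        result.calibration = model
        density = apply_calibration(ct, model)
    except Exception as exc:
        return fail("calibration", exc)

    # -- mirroring ---------------------------------------------------------
    lm_input = None if callable(landmarks) else landmarks
    try:
        if ct.side == "right":
            density, femur_mask, lm_input = mirror_to_left(
                density, femur_mask, lm_input
            )
            result.mirrored = True
    except Exception as exc:
        return fail("mirroring", exc)

    detector = landmarks if callable(landmarks) else None

    # -- femoral volume extraction ------------------------------------------
    # The segmented femoral volume (masked density, negative marrow values
    # clipped) is extracted *before* rotation, so the subsequent rigid
    # resampling redistributes but never discards bone mass.
    masked = density.with_voxels(
        np.where(femur_mask.labels > 0,
                 np.clip(density.voxels, 0.0, None), 0.0)
    )

    # -- stage 1 -----------------------------------------------------------
    try:
        pivot1 = mask_centroid(femur_mask)
        if detector is not None:
            lm_stage1 = _as_landmarks(detector(density, femur_mask))
        else:
            lm_stage1 = lm_input
        t1 = stage1_transform(shaft_axis(lm_stage1), pivot1)
        result.stage1 = t1
    except Exception as exc:
        return fail("stage1_rotation", exc)

    # -- stage 2 -----------------------------------------------------------
    try:
        if detector is not None:
            masked1 = resample_trilinear(masked, t1)
            mask1 = resample_trilinear(femur_mask, t1)
            lm1 = _as_landmarks(detector(masked1, mask1))
            lm1 = LandmarkSet(lm1.points, frame="stage1")
        else:
            lm1 = transform_landmarks(lm_input, t1)
        lm1.require(["HEAD_CENTER", "NECK_CENTER"])
        t2 = stage2_transform(lm1, lm1["HEAD_CENTER"])
        result.stage2 = t2
        result.angles = decompose_angles(t1, t2)
    except Exception as exc:
        return fail("stage2_rotation", exc)

    # -- resampling to neutral ----------------------------------------------
    try:
        if detector is not None:
            masked2 = resample_trilinear(masked1, t2)
        else:
            composite = compose_transforms(t2, t1)
            masked2 = resample_trilinear(masked, composite)
        lm2 = transform_landmarks(lm1, t2)
        result.landmarks_stage2 = lm2
    except Exception as exc:
        return fail("resampling", exc)

    # -- projection, ROI, aBMD ----------------------------------------------
    try:
        support = LabelMask(
            (masked2.voxels > 0).astype(np.int16),
            masked2.spacing, masked2.origin, masked2.direction,
            side=masked2.side,
        )
        drr = project_coronal(masked2, support, step_mm=step_mm,
                              pixel_mm=pixel_mm)
        result.drr = drr
    except Exception as exc:
        return fail("projection", exc)

    try:
        plm = project_points(lm2, drr)
        roi = define_proximal_roi(plm, drr)
        result.roi = roi
        if roi.empty:
            raise ROIError("proximal ROI contains no bone pixels")
    except Exception as exc:
        return fail("roi", exc)

    try:
        abmd = compute_abmd(drr, roi, cross_calibration=cross_calibration)
        if criterion is not None:
            cls = classify_osteoporosis(abmd.ct_abmd, criterion)
            abmd.classification = cls.label
            abmd.t_score = cls.t_score
        result.abmd = abmd
    except Exception as exc:
        return fail("abmd", exc)

    return result


def _as_landmarks(obj) -> LandmarkSet:
    if isinstance(obj, LandmarkSet):
        return obj
    landmarks = getattr(obj, "landmarks", None)
    if isinstance(landmarks, LandmarkSet):
        return landmarks
    raise TypeError("detector must return a LandmarkSet or LandmarkDetection")
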