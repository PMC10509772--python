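"""Volumes, masks and landmark files, pinned to one coordinate convention.

Everything downstream of this module assumes the **LPS world frame**
(+x patient-left, +y posterior, +z superior — DICOM patient space) with
0-based voxel indices mapping to world millimetres as

    world = origin + direction @ (spacing * index)

NIfTI stores RAS+ affines; they are flipped to LPS on load and back on
save, so in-memory objects are always LPS.  Landmark files carry world
millimetres, never voxel indices.  Right femora are mirrored into the
left-femur convention (:func:`mirror_to_left`) before any processing, so
a single anatomical convention holds everywhere: for a left femur the
head points medially toward -x and "coronal projection" is integration
along +y.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import nibabel as nib
import pydicom

__all__ = [
    "LANDMARK_NAMES",
    "STAGE1_NAMES",
    "CTVolume",
    "DensityVolume",
    "LabelMask",
    "LandmarkSet",
    "load_volume",
    "save_volume",
    "load_landmarks",
    "save_landmarks",
    "mirror_to_left",
]

#: Canonical proximal-femur landmark names, in the conventional 1..9 order:
#: two shaft points (2 cm / 5 cm distal to the lesser-trochanter tip), head
#: centre, neck centre, four head-neck-junction points, lesser-trochanter tip.
LANDMARK_NAMES = (
    "LT_DISTAL_2CM",
    "LT_DISTAL_5CM",
    "HEAD_CENTER",
    "NECK_CENTER",
    "HNJ_SUP",
    "HNJ_ANT",
    "HNJ_POST",
    "HNJ_INF",
    "LT_TIP",
)

#: The two landmarks needed for the stage-1 (shaft) rotation.
STAGE1_NAMES = ("LT_DISTAL_2CM", "LT_DISTAL_5CM")

_SIDES = ("left", "right", "unknown")

# RAS <-> LPS flip of the first two world axes.
_RAS2LPS = np.diag([-1.0, -1.0, 1.0, 1.0])


class VolumeError(ValueError):
    """Raised for malformed volumes, masks or landmark files."""


# ---------------------------------------------------------------------------
# grid types
# ---------------------------------------------------------------------------


@dataclass
class _Grid3:
    """Oriented 3-D scalar grid in LPS world coordinates."""

    voxels: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    direction: np.ndarray
    side: str = "unknown"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.direction = np.asarray(self.direction, dtype=float).reshape(3, 3)
        if self.voxels.ndim != 3:
            raise VolumeError("voxel grid must be 3-D")
        if any(n < 2 for n in self.voxels.shape):
            raise VolumeError("grid needs at least 2 voxels per axis")
        if not np.all(self.spacing > 0):
            raise VolumeError(f"spacing must be positive, got {self.spacing}")
        if not np.allclose(self.direction.T @ self.direction, np.eye(3), atol=1e-5):
            raise VolumeError("direction matrix is not orthonormal")
        if np.linalg.det(self.direction) < 0:
            raise VolumeError("direction matrix must be right-handed (det +1)")
        if self.side not in _SIDES:
            raise VolumeError(f"side must be one of {_SIDES}, got {self.side!r}")

    # -- geometry ----------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def affine(self) -> np.ndarray:
        """4x4 index -> LPS world (mm) affine."""
        a = np.eye(4)
        a[:3, :3] = self.direction * self.spacing[None, :]
        a[:3, 3] = self.origin
        return a

    def index_to_world(self, index) -> np.ndarray:
        idx = np.atleast_2d(np.asarray(index, dtype=float))
        pts = idx * self.spacing[None, :] @ self.direction.T + self.origin
        return pts[0] if np.ndim(index) == 1 else pts

    def world_to_index(self, point) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(point, dtype=float))
        idx = (pts - self.origin) @ self.direction / self.spacing[None, :]
        return idx[0] if np.ndim(point) == 1 else idx

    def world_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """Axis-aligned world bounding box of all voxel centres."""
        n = np.array(self.shape) - 1
        corners = np.array(
            [[i, j, k] for i in (0, n[0]) for j in (0, n[1]) for k in (0, n[2])],
            dtype=float,
        )
        w = self.index_to_world(corners)
        return w.min(axis=0), w.max(axis=0)

    def with_voxels(self, voxels: np.ndarray):
        """Same geometry, new voxel data."""
        return replace(self, voxels=voxels)

    def geometry_matches(self, other: "_Grid3", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
            and np.allclose(self.direction, other.direction, atol=atol)
        )


@dataclass
class CTVolume(_Grid3):
    """CT attenuation volume in Hounsfield units."""


@dataclass
class DensityVolume(_Grid3):
    """Calibrated volume in mg/cm^3 hydroxyapatite-equivalent density."""


@dataclass
class LabelMask(_Grid3):
    """Integer label grid: 0 = background, 1..K = structures / rods."""

    def __post_init__(self) -> None:
        super().__post_init__()
        if not np.issubdtype(self.voxels.dtype, np.integer):
            raise VolumeError("label mask must have an integer dtype")
        if self.voxels.min() < 0:
            raise VolumeError("label values must be non-negative")

    @property
    def labels(self) -> np.ndarray:
        return self.voxels


# ---------------------------------------------------------------------------
# landmarks
# ---------------------------------------------------------------------------


@dataclass
class LandmarkSet:
    """Named proximal-femur points in world mm.

    ``frame`` records how far through pose normalization the coordinates
    are: ``original`` (scanner frame), ``stage1`` (shaft vertical) or
    ``stage2`` (neck also in the coronal plane).
    """

    points: dict[str, np.ndarray]
    frame: str = "original"

    def __post_init__(self) -> None:
        clean: dict[str, np.ndarray] = {}
        for name, p in self.points.items():
            if name not in LANDMARK_NAMES:
                raise VolumeError(f"unknown landmark name {name!r}")
            if name in clean:
                raise VolumeError(f"duplicate landmark {name!r}")
            arr = np.asarray(p, dtype=float).reshape(3)
            if not np.all(np.isfinite(arr)):
                raise VolumeError(f"non-finite coordinates for {name!r}")
            clean[name] = arr
        self.points = clean
        if self.frame not in ("original", "stage1", "stage2"):
            raise VolumeError(f"unknown frame tag {self.frame!r}")
        if "LT_DISTAL_2CM" in clean and "LT_DISTAL_5CM" in clean:
            if np.allclose(clean["LT_DISTAL_2CM"], clean["LT_DISTAL_5CM"]):
                raise VolumeError(
                    "LT_DISTAL_2CM and LT_DISTAL_5CM coincide; shaft axis undefined"
                )

    def __getitem__(self, name: str) -> np.ndarray:
        return self.points[name]

    def __contains__(self, name: str) -> bool:
        return name in self.points

    def __len__(self) -> int:
        return len(self.points)

    def names(self) -> tuple[str, ...]:
        return tuple(self.points)

    def array(self, names=None) -> np.ndarray:
        names = tuple(names) if names is not None else self.names()
        return np.array([self.points[n] for n in names])

    def require(self, names) -> None:
        missing = [n for n in names if n not in self.points]
        if missing:
            raise VolumeError(f"missing required landmarks: {missing}")

    def with_points(self, points: dict[str, np.ndarray], frame: str | None = None):
        return LandmarkSet(points, frame=frame if frame is not None else self.frame)


# ---------------------------------------------------------------------------
# NIfTI / DICOM loading
# ---------------------------------------------------------------------------


def _decompose_lps_affine(affine_lps: np.ndarray):
    lin = affine_lps[:3, :3]
    spacing = np.linalg.norm(lin, axis=0)
    if np.any(spacing <= 0):
        raise VolumeError("degenerate affine: zero-length axis")
    direction = lin / spacing[None, :]
    if not np.allclose(direction.T @ direction, np.eye(3), atol=1e-3):
        raise VolumeError(
            "volume has a non-orthonormal direction matrix; resample it upstream"
        )
    # re-orthonormalize against rounding in the stored affine
    u, _, vt = np.linalg.svd(direction)
    direction = u @ vt
    return spacing, affine_lps[:3, 3].copy(), direction


def _side_from_descrip(descrip: str) -> str:
    for side in ("left", "right"):
        if f"side={side}" in descrip:
            return side
    return "unknown"


_KIND_TO_CLASS = {"ct": CTVolume, "density": DensityVolume, "labels": LabelMask}


def load_volume(path, kind: str = "ct") -> _Grid3:
    """Load a NIfTI file or a DICOM series directory.

    ``kind`` selects the returned type: ``"ct"`` (HU), ``"density"``
    (mg/cm^3) or ``"labels"``.  DICOM directories are always CT and have
    the rescale slope/intercept applied.  World geometry is returned in
    the package's LPS convention.
    """
    if kind not in _KIND_TO_CLASS:
        raise VolumeError(f"unknown volume kind {kind!r}")
    path = Path(path)
    if not path.exists():
        raise VolumeError(f"no such file or directory: {path}")
    if path.is_dir():
        if kind != "ct":
            raise VolumeError("DICOM series can only be loaded as CT")
        return _load_dicom_series(path)
    img = nib.load(str(path))
    affine_lps = _RAS2LPS @ img.affine
    spacing, origin, direction = _decompose_lps_affine(affine_lps)
    data = np.asarray(img.dataobj)
    try:
        descrip = img.header["descrip"].item()
        if isinstance(descrip, bytes):
            descrip = descrip.decode(errors="ignore")
    except Exception:
        descrip = ""
    side = _side_from_descrip(str(descrip))
    cls = _KIND_TO_CLASS[kind]
    if cls is LabelMask:
        data = np.rint(np.asarray(data, dtype=float)).astype(np.int32)
    else:
        data = np.asarray(data, dtype=np.float64)
    return cls(data, spacing, origin, direction, side=side)


def _load_dicom_series(directory: Path) -> CTVolume:
    files = sorted(p for p in directory.iterdir() if p.is_file())
    slices = []
    for f in files:
        try:
            ds = pydicom.dcmread(str(f))
        except Exception:
            continue
        if hasattr(ds, "PixelData"):
            slices.append(ds)
    if not slices:
        raise VolumeError(f"no DICOM image files in {directory}")
    uids = {getattr(ds, "SeriesInstanceUID", None) for ds in slices}
    if len(uids) != 1:
        raise VolumeError(f"directory {directory} mixes {len(uids)} DICOM series")

    first = slices[0]
    iop = np.asarray(first.ImageOrientationPatient, dtype=float)
    row_dir = iop[:3]   # direction of increasing column index
    col_dir = iop[3:]   # direction of increasing row index
    normal = np.cross(row_dir, col_dir)
    slices.sort(key=lambda ds: float(np.dot(ds.ImagePositionPatient, normal)))

    positions = np.array([np.dot(ds.ImagePositionPatient, normal) for ds in slices])
    steps = np.diff(positions)
    if len(steps) == 0:
        raise VolumeError("DICOM series needs at least two slices")
    if np.ptp(steps) > 0.01 * abs(steps.mean()) + 1e-6:
        raise VolumeError("non-uniform slice spacing in DICOM series")
    dz = float(abs(steps.mean()))

    ps = np.asarray(first.PixelSpacing, dtype=float)  # [row spacing, col spacing]
    spacing = np.array([ps[1], ps[0], dz])
    direction = np.column_stack([row_dir, col_dir, normal])
    origin = np.asarray(slices[0].ImagePositionPatient, dtype=float)

    vol = np.empty((first.Columns, first.Rows, len(slices)), dtype=np.float64)
    for k, ds in enumerate(slices):
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        vol[:, :, k] = ds.pixel_array.astype(np.float64).T * slope + intercept
    return CTVolume(vol, spacing, origin, direction)


def save_volume(volume: _Grid3, path) -> None:
    """Write a volume/mask as NIfTI (the package's canonical on-disk format).

    Integer grids round-trip bit-exactly; real grids are stored as float64
    so densities round-trip well below 1e-6 mg/cm^3.
    """
    path = Path(path)
    if isinstance(volume, LabelMask):
        data = np.asarray(volume.voxels, dtype=np.int32)
    else:
        data = np.asarray(volume.voxels, dtype=np.float64)
        if not np.all(np.isfinite(data)):
            raise VolumeError("refusing to save volume with non-finite voxels")
    affine_ras = _RAS2LPS @ volume.affine
    img = nib.Nifti1Image(data, affine_ras)
    img.header["descrip"] = f"hipbmd side={volume.side}".encode()
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# landmark files
# ---------------------------------------------------------------------------


def load_landmarks(path, require: str = "all") -> LandmarkSet:
    """Read landmarks from CSV (``name,x,y,z`` in world mm) or JSON.

    ``require`` controls completeness: ``"all"`` needs all nine canonical
    points, ``"stage1"`` only the two distal shaft points, ``"any"``
    accepts any non-empty subset (explicit opt-in for partial sets).
    """
    path = Path(path)
    if not path.exists():
        raise VolumeError(f"no such landmark file: {path}")
    raw: dict[str, list[float]] = {}
    frame = "original"
    if path.suffix.lower() == ".json":
        obj = json.loads(path.read_text())
        frame = obj.pop("frame", "original") if isinstance(obj, dict) else "original"
        items = obj.items()
        for name, xyz in items:
            if name in raw:
                raise VolumeError(f"duplicate landmark {name!r} in {path}")
            raw[name] = [float(v) for v in xyz]
    else:
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            cols = {c.strip().lower() for c in reader.fieldnames or ()}
            if not {"name", "x", "y", "z"} <= cols:
                raise VolumeError(f"landmark CSV {path} must have header name,x,y,z")
            for row in reader:
                row = {k.strip().lower(): v for k, v in row.items()}
                name = row["name"].strip()
                if name in raw:
                    raise VolumeError(f"duplicate landmark {name!r} in {path}")
                raw[name] = [float(row["x"]), float(row["y"]), float(row["z"])]
    lm = LandmarkSet({n: np.asarray(p) for n, p in raw.items()}, frame=frame)
    if require == "all":
        lm.require(LANDMARK_NAMES)
    elif require == "stage1":
        lm.require(STAGE1_NAMES)
    elif require == "any":
        if len(lm) == 0:
            raise VolumeError(f"landmark file {path} is empty")
    else:
        raise VolumeError(f"unknown requirement level {require!r}")
    return lm


def save_landmarks(lm: LandmarkSet, path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        obj = {n: list(map(float, p)) for n, p in lm.points.items()}
        obj["frame"] = lm.frame
        path.write_text(json.dumps(obj, indent=1))
    else:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["name", "x", "y", "z"])
            for n, p in lm.points.items():
                writer.writerow([n, repr(float(p[0])), repr(float(p[1])),
                                 repr(float(p[2]))])


# ---------------------------------------------------------------------------
# mirroring
# ---------------------------------------------------------------------------


def _reflect_points(pts: np.ndarray, plane_x: float) -> np.ndarray:
    out = np.array(pts, dtype=float, copy=True)
    out[..., 0] = 2.0 * plane_x - out[..., 0]
    return out


def _mirror_grid(grid: _Grid3, plane_x: float) -> _Grid3:
    # Reflect across the sagittal plane x = plane_x and flip the voxel array
    # along the grid axis most aligned with world x, keeping det(direction)=+1.
    axis = int(np.argmax(np.abs(grid.direction[0, :])))
    refl = np.diag([-1.0, 1.0, 1.0])
    flip = np.eye(3)
    flip[axis, axis] = -1.0

    e = np.zeros(3)
    e[axis] = grid.shape[axis] - 1
    last_center = grid.index_to_world(e)
    new_origin = _reflect_points(last_center, plane_x)
    new_direction = refl @ grid.direction @ flip
    new_voxels = np.flip(grid.voxels, axis=axis).copy()
    new_side = {"left": "right", "right": "left"}.get(grid.side, "unknown")
    return replace(
        grid,
        voxels=new_voxels,
        origin=new_origin,
        direction=new_direction,
        side=new_side,
    )


def mirror_to_left(volume: _Grid3, mask: LabelMask | None,
                   landmarks: LandmarkSet | None, plane_x: float = 0.0):
    """Bring a femur into the left-femur convention.

    Left inputs are returned unchanged.  Right inputs are reflected across
    the patient mid-sagittal plane (``x = plane_x`` in LPS world mm), the
    side tag is set to ``left`` and landmark x-coordinates are negated
    about the reflection plane.  The operation is an involution and
    preserves the voxel value histogram exactly.
    """
    if volume.side == "unknown":
        raise VolumeError(
            "volume side is unknown; set side='left' or side='right' before "
            "mirroring"
        )
    if volume.side == "left":
        return volume, mask, landmarks
    mirrored_vol = _mirror_grid(volume, plane_x)
    mirrored_mask = _mirror_grid(mask, plane_x) if mask is not None else None
    if mirrored_mask is not None:
        mirrored_mask.side = "left"
    mirrored_lm = None
    if landmarks is not None:
        mirrored_lm = landmarks.with_points(
            {n: _reflect_points(p, plane_x) for n, p in landmarks.points.items()}
        )
    return mirrored_vol, mirrored_mask, mirrored_lm
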