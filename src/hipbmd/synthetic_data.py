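"""Synthetic CT phantom and proximal femur with exact ground truth.

The generator exists so that every stage of the areal-BMD pipeline can
be verified without clinical scans: it emits (a) a B-MAS200-style rod
phantom whose voxel HU follow a known affine map of the nominal
hydroxyapatite densities, and (b) a parametric left proximal femur —
head sphere, neck cylinder, shaft cylinder and a lesser-trochanter
bump, each with a cortical shell around a trabecular interior — imaged
at an arbitrary pose, together with analytically placed landmarks,
per-voxel component labels and an independent areal-density oracle.

The oracle (:func:`reference_abmd`) integrates the analytic solid
geometry along anteroposterior rays in closed form on a fine in-plane
grid; it shares no voxelization, resampling or interpolation code with
the measurement pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .volumes_io import CTVolume, LabelMask, LandmarkSet, _mirror_grid, _reflect_points

__all__ = [
    "FemurSpec",
    "PoseParams",
    "AcquisitionSpec",
    "GroundTruth",
    "COMPONENT_LABELS",
    "build_phantom",
    "build_femur",
    "reference_abmd",
    "reference_areal_image",
    "simulate_cohort",
    "B_MAS200_DENSITIES",
]

#: Nominal hydroxyapatite densities of the modeled calibration phantom,
#: mg/cm^3 (four rods plus the zero-density base material).
B_MAS200_DENSITIES = (0.0, 50.0, 100.0, 150.0, 200.0)

#: Legend of the per-voxel ground-truth component labels.
COMPONENT_LABELS = {1: "head", 2: "neck", 3: "trochanter", 4: "shaft"}

# Fixed anatomical stations of the parametric femur (mm, neutral frame;
# the neck-base point on the shaft axis is the origin).
_SHAFT_TOP = 15.0       # greater-trochanter shoulder above the neck base
_Z_LT_TIP = -15.0       # axial station of the lesser-trochanter tip


class SyntheticError(ValueError):
    """Raised for invalid generator specifications."""


@dataclass(frozen=True)
class FemurSpec:
    """Parametric proximal femur (left-femur convention, sizes in mm).

    Defaults are adult-femur scale: a ~46 mm head, 127 deg neck-shaft
    angle, 15 deg anteversion, and hydroxyapatite-equivalent densities
    of 150 mg/cm^3 (trabecular) inside an 800 mg/cm^3, 3 mm cortical
    shell.
    """

    head_radius: float = 23.0
    neck_radius: float = 13.0          # waist radius at mid-neck
    neck_length: float = 55.0          # neck base (on shaft axis) to head centre
    neck_shaft_angle: float = 127.0    # degrees
    anteversion: float = 15.0          # degrees
    neck_flare: float = 0.15           # fractional radius increase at both ends
    shaft_radius: float = 14.0
    shaft_length: float = 100.0        # below the neck base
    lesser_trochanter_offset: float = 24.0  # medial tip offset from shaft axis
    trabecular_density: float = 150.0  # mg/cm^3
    cortical_density: float = 800.0    # mg/cm^3
    cortical_thickness: float = 3.0    # mm

    def __post_init__(self):
        lengths = (
            self.head_radius, self.neck_radius, self.neck_length,
            self.shaft_radius, self.shaft_length,
            self.lesser_trochanter_offset, self.cortical_thickness,
        )
        if any(v <= 0 for v in lengths):
            raise SyntheticError("all lengths must be positive")
        if not (0.0 <= self.neck_flare < 1.0):
            raise SyntheticError("neck_flare must lie in [0, 1)")
        if self.head_radius <= self.neck_radius * (1.0 + self.neck_flare):
            raise SyntheticError("head_radius must exceed the flared neck radius")
        if self.lesser_trochanter_offset <= self.shaft_radius:
            raise SyntheticError(
                "lesser_trochanter_offset must exceed shaft_radius"
            )
        if min(self.trabecular_density, self.cortical_density) < 0:
            raise SyntheticError("densities must be >= 0")


@dataclass(frozen=True)
class PoseParams:
    """Injected positioning of the femur during the simulated scan.

    Angles in degrees: ``abduction`` tilts the shaft in the coronal
    plane, ``flexion`` in the sagittal plane, ``axial_rotation`` spins
    the femur about the superior axis.  All must stay within +/-90 deg.
    """

    abduction: float = 0.0
    flexion: float = 0.0
    axial_rotation: float = 0.0
    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        for v in (self.abduction, self.flexion, self.axial_rotation):
            if abs(v) >= 90.0:
                raise SyntheticError("pose angles must stay within +/-90 deg")

    @property
    def rotation(self) -> np.ndarray:
        """Pose rotation: axial spin about z, then minimal shaft tilt."""
        abd, flex, rot = map(math.radians,
                             (self.abduction, self.flexion, self.axial_rotation))
        u = np.array([math.tan(abd), math.tan(flex), 1.0])
        u /= np.linalg.norm(u)
        z = np.array([0.0, 0.0, 1.0])
        k = np.cross(z, u)
        s = np.linalg.norm(k)
        c = float(u @ z)
        if s < 1e-15:
            r_tilt = np.eye(3)
        else:
            k = k / s
            K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
            r_tilt = np.eye(3) + s * K + (1 - c) * (K @ K)
        cz, sz = math.cos(rot), math.sin(rot)
        r_axial = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1.0]])
        return r_tilt @ r_axial

    def apply(self, pts) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        return pts @ self.rotation.T + np.asarray(self.translation)


@dataclass(frozen=True)
class AcquisitionSpec:
    """Scanner emulation: HU map, noise, voxel grid and patient pose."""

    hu_slope: float = 0.8       # HU per mg/cm^3
    hu_intercept: float = -10.0  # HU at zero density
    noise_sd: float = 5.0       # HU
    voxel_size: tuple[float, float, float] = (0.8, 0.8, 1.25)
    pose: PoseParams = field(default_factory=PoseParams)
    seed: int = 0

    def __post_init__(self):
        if any(v <= 0 for v in self.voxel_size):
            raise SyntheticError("voxel sizes must be positive")
        if self.noise_sd < 0:
            raise SyntheticError("noise_sd must be >= 0")


@dataclass
class GroundTruth:
    """Exact truth shipped with every synthetic femur volume."""

    landmarks: LandmarkSet          # in the rendered (posed) frame
    pose: PoseParams
    components: LabelMask           # COMPONENT_LABELS legend
    reference_abmd: float | None = None  # g/cm^2, neutral-frame oracle


# ---------------------------------------------------------------------------
# analytic solid geometry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class _Sphere:
    center: np.ndarray
    radius: float


@dataclass(frozen=True)
class _Frustum:
    """Right circular cone frustum; a cylinder when r0 == r1."""

    p0: np.ndarray
    p1: np.ndarray
    r0: float
    r1: float

    @property
    def axis(self) -> np.ndarray:
        v = self.p1 - self.p0
        return v / np.linalg.norm(v)

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.p1 - self.p0))

    def radius_at(self, s):
        """Surface radius at axial station ``s`` in [0, length]."""
        return self.r0 + (self.r1 - self.r0) * np.asarray(s) / self.length


def _neck_direction(spec: FemurSpec) -> np.ndarray:
    beta = math.radians(spec.neck_shaft_angle - 90.0)
    av = math.radians(spec.anteversion)
    return np.array(
        [-math.cos(beta) * math.cos(av), -math.cos(beta) * math.sin(av),
         math.sin(beta)]
    )


class _FemurGeometry:
    """Neutral-frame primitives, shells and landmarks of a FemurSpec."""

    def __init__(self, spec: FemurSpec):
        self.spec = spec
        n = _neck_direction(spec)
        self.neck_dir = n
        base = np.zeros(3)
        head = base + spec.neck_length * n
        self.head_center = head
        mid = base + 0.5 * spec.neck_length * n  # the neck waist

        r_lt = 0.5 * (spec.lesser_trochanter_offset - spec.shaft_radius) + 3.0
        lt_center = np.array(
            [-(spec.lesser_trochanter_offset - r_lt), 0.0, _Z_LT_TIP]
        )
        self.lt_radius = r_lt

        # neck: two frustums flaring from the mid-neck waist toward both
        # ends, so the minimal cross-section is unique (real necks taper)
        r_waist = spec.neck_radius
        r_flare = spec.neck_radius * (1.0 + spec.neck_flare)

        # order fixes the component label priority: head, neck, troch, shaft
        self.primitives = [
            _Sphere(head, spec.head_radius),
            _Frustum(base, mid, r_flare, r_waist),
            _Frustum(mid, head, r_waist, r_flare),
            _Sphere(lt_center, r_lt),
            _Frustum(np.array([0.0, 0.0, -spec.shaft_length]),
                     np.array([0.0, 0.0, _SHAFT_TOP]),
                     spec.shaft_radius, spec.shaft_radius),
        ]
        self.component_of_primitive = [1, 2, 2, 3, 4]

        t = spec.cortical_thickness
        cores = []
        for p in self.primitives:
            if isinstance(p, _Sphere):
                cores.append(_Sphere(p.center, max(p.radius - t, 0.0)))
            else:
                a = p.axis
                if p.length > 2 * t and min(p.r0, p.r1) > t:
                    cores.append(
                        _Frustum(p.p0 + t * a, p.p1 - t * a,
                                 p.r0 - t, p.r1 - t)
                    )
                else:
                    cores.append(_Frustum(p.p0, p.p0 + 1e-6 * a, 0.0, 0.0))
        self.cores = cores

    # -- landmarks --------------------------------------------------------

    def junction_offset(self) -> float:
        """Distance from the head centre to the head-neck junction circle.

        Fixed point of d = sqrt(R_head^2 - r_neck(d)^2) with the tapered
        neck radius; converges in a few iterations.
        """
        spec = self.spec
        half = 0.5 * spec.neck_length
        r_waist = spec.neck_radius
        r_flare = r_waist * (1.0 + spec.neck_flare)
        d = math.sqrt(max(spec.head_radius**2 - r_waist**2, 0.0))
        for _ in range(20):
            u = max(min(half - d, half), 0.0)  # station above the waist
            r_j = r_flare + (r_waist - r_flare) * u / half
            d = math.sqrt(max(spec.head_radius**2 - r_j**2, 0.0))
        return d

    def junction_radius(self) -> float:
        spec = self.spec
        half = 0.5 * spec.neck_length
        u = max(min(half - self.junction_offset(), half), 0.0)
        r_flare = spec.neck_radius * (1.0 + spec.neck_flare)
        return r_flare + (spec.neck_radius - r_flare) * u / half

    def landmarks(self) -> LandmarkSet:
        spec = self.spec
        n = self.neck_dir
        H = self.head_center
        d = self.junction_offset()
        J = H - d * n  # centre of the head-neck junction circle
        z = np.array([0.0, 0.0, 1.0])
        s = z - (z @ n) * n
        s /= np.linalg.norm(s)
        a = np.cross(s, n)  # anterior (-y) at neutral for a left femur
        a /= np.linalg.norm(a)
        rn = self.junction_radius()
        pts = {
            "LT_DISTAL_2CM": np.array([0.0, 0.0, _Z_LT_TIP - 20.0]),
            "LT_DISTAL_5CM": np.array([0.0, 0.0, _Z_LT_TIP - 50.0]),
            "HEAD_CENTER": H,
            "NECK_CENTER": 0.5 * spec.neck_length * n,
            "HNJ_SUP": J + rn * s,
            "HNJ_ANT": J + rn * a,
            "HNJ_POST": J - rn * a,
            "HNJ_INF": J - rn * s,
            "LT_TIP": np.array([-spec.lesser_trochanter_offset, 0.0, _Z_LT_TIP]),
        }
        return LandmarkSet(pts, frame="original")

    # -- membership (vectorized over an (N,3) point array) ----------------

    @staticmethod
    def _inside_sphere(pts, sph: _Sphere):
        d2 = np.sum((pts - sph.center) ** 2, axis=-1)
        return d2 <= sph.radius**2

    @staticmethod
    def _inside_frustum(pts, fr: _Frustum):
        a = fr.axis
        w = pts - fr.p0
        t = w @ a
        radial2 = np.sum(w * w, axis=-1) - t * t
        r = fr.radius_at(np.clip(t, 0.0, fr.length))
        return (t >= 0) & (t <= fr.length) & (radial2 <= r * r)

    def _inside(self, pts, prim):
        if isinstance(prim, _Sphere):
            return self._inside_sphere(pts, prim)
        return self._inside_frustum(pts, prim)

    def density_and_component(self, pts: np.ndarray):
        """Density (mg/cm^3) and component label for neutral-frame points."""
        in_full = [self._inside(pts, p) for p in self.primitives]
        in_core = [self._inside(pts, c) for c in self.cores]
        any_full = np.logical_or.reduce(in_full)
        any_core = np.logical_or.reduce(in_core)
        density = np.where(
            any_core, self.spec.trabecular_density,
            np.where(any_full, self.spec.cortical_density, 0.0),
        )
        comp = np.zeros(pts.shape[:-1], dtype=np.int16)
        for mask, label in zip(reversed(in_full),
                               reversed(self.component_of_primitive)):
            comp[mask] = label
        return density, comp, any_full

    def bounding_box(self, pose: PoseParams, margin: float = 6.0):
        pts = []
        radii = []
        for p in self.primitives:
            if isinstance(p, _Sphere):
                pts.append(p.center)
                radii.append(p.radius)
            else:
                pts.extend([p.p0, p.p1])
                radii.extend([p.r0, p.r1])
        posed = pose.apply(np.array(pts))
        r = np.array(radii)[:, None]
        lo = (posed - r).min(axis=0) - margin
        hi = (posed + r).max(axis=0) + margin
        return lo, hi


# ---------------------------------------------------------------------------
# phantom
# ---------------------------------------------------------------------------


def build_phantom(
    rod_densities=B_MAS200_DENSITIES,
    acq: AcquisitionSpec | None = None,
    rod_radius: float = 7.5,
    rod_spacing: float = 25.0,
    rod_length: float = 60.0,
):
    """Synthetic rod calibration phantom.

    Parallel cylindrical rods with the given hydroxyapatite densities sit
    in a zero-density base slab; voxel HU follow
    ``hu_slope * density + hu_intercept`` plus Gaussian noise.  Returns
    the CT volume and a label mask with one label per rod (1..K, in the
    order the densities were given).
    """
    acq = acq or AcquisitionSpec()
    dens = [float(d) for d in rod_densities]
    if len(dens) < 2:
        raise SyntheticError("phantom needs at least 2 rods")
    if any(d < 0 for d in dens):
        raise SyntheticError("rod densities must be >= 0")
    if rod_spacing < 2 * rod_radius + 2.0:
        raise SyntheticError(
            f"rods of radius {rod_radius} overlap at spacing {rod_spacing}"
        )
    n = len(dens)
    half_x = 0.5 * (n - 1) * rod_spacing + rod_radius + 8.0
    half_z = 0.5 * rod_length + 6.0
    lo = np.array([-half_x, -12.0, -half_z])
    hi = np.array([half_x, 12.0, half_z])
    vs = np.asarray(acq.voxel_size)
    shape = np.maximum(np.ceil((hi - lo) / vs).astype(int) + 1, 2)
    origin = lo

    ii, jj, kk = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    pts = np.stack([ii, jj, kk], axis=-1) * vs + origin

    density = np.zeros(shape, dtype=float)
    labels = np.zeros(shape, dtype=np.int16)
    centers_x = (np.arange(n) - 0.5 * (n - 1)) * rod_spacing
    for idx, (cx, d) in enumerate(zip(centers_x, dens), start=1):
        inside = (
            ((pts[..., 0] - cx) ** 2 + pts[..., 1] ** 2 <= rod_radius**2)
            & (np.abs(pts[..., 2]) <= 0.5 * rod_length)
        )
        density[inside] = d
        labels[inside] = idx

    rng = np.random.default_rng(acq.seed)
    hu = acq.hu_slope * density + acq.hu_intercept
    if acq.noise_sd > 0:
        hu = hu + rng.normal(0.0, acq.noise_sd, size=hu.shape)
    ct = CTVolume(hu, vs, origin, np.eye(3))
    mask = LabelMask(labels, vs, origin.copy(), np.eye(3))
    return ct, mask


# ---------------------------------------------------------------------------
# femur rendering
# ---------------------------------------------------------------------------


def build_femur(
    fspec: FemurSpec | None = None,
    acq: AcquisitionSpec | None = None,
    side: str = "left",
    with_reference_abmd: bool = False,
):
    """Render a synthetic femur CT at the requested pose.

    Returns ``(ct, femur_mask, ground_truth)``.  The femur mask has a
    single label 1; the ground truth carries posed landmarks, per-voxel
    component labels and (optionally) the neutral-pose oracle aBMD.  A
    right femur is the exact mirror image of the left one built from the
    same spec.
    """
    fspec = fspec or FemurSpec()
    acq = acq or AcquisitionSpec()
    if side not in ("left", "right"):
        raise SyntheticError("side must be left or right")
    geom = _FemurGeometry(fspec)
    pose = acq.pose
    lo, hi = geom.bounding_box(pose)
    vs = np.asarray(acq.voxel_size)
    shape = np.maximum(np.ceil((hi - lo) / vs).astype(int) + 1, 2)
    origin = lo

    R_inv = pose.rotation.T
    trans = np.asarray(pose.translation)

    density = np.empty(shape, dtype=float)
    labels = np.zeros(shape, dtype=np.int16)
    comps = np.zeros(shape, dtype=np.int16)
    xs = origin[0] + np.arange(shape[0]) * vs[0]
    ys = origin[1] + np.arange(shape[1]) * vs[1]
    zs = origin[2] + np.arange(shape[2]) * vs[2]
    chunk = max(1, int(4e6 / (shape[1] * shape[2])))
    for i0 in range(0, shape[0], chunk):
        i1 = min(i0 + chunk, shape[0])
        gx, gy, gz = np.meshgrid(xs[i0:i1], ys, zs, indexing="ij")
        pts = np.stack([gx, gy, gz], axis=-1).reshape(-1, 3)
        neutral = (pts - trans) @ R_inv.T
        d, c, inside = geom.density_and_component(neutral)
        block = (i1 - i0, shape[1], shape[2])
        density[i0:i1] = d.reshape(block)
        comps[i0:i1] = c.reshape(block)
        labels[i0:i1] = inside.reshape(block).astype(np.int16)

    rng = np.random.default_rng(acq.seed)
    hu = acq.hu_slope * density + acq.hu_intercept
    if acq.noise_sd > 0:
        hu = hu + rng.normal(0.0, acq.noise_sd, size=hu.shape)

    ct = CTVolume(hu, vs, origin, np.eye(3), side="left")
    mask = LabelMask(labels, vs, origin.copy(), np.eye(3), side="left")
    comp_mask = LabelMask(comps, vs, origin.copy(), np.eye(3), side="left")
    lm = LandmarkSet(
        {n: pose.apply(p) for n, p in geom.landmarks().points.items()},
        frame="original",
    )
    ref = reference_abmd(fspec) if with_reference_abmd else None
    gt = GroundTruth(landmarks=lm, pose=pose, components=comp_mask,
                     reference_abmd=ref)

    if side == "right":
        ct = _mirror_grid(ct, 0.0)
        mask = _mirror_grid(mask, 0.0)
        comp_mask = _mirror_grid(comp_mask, 0.0)
        ct.side = mask.side = comp_mask.side = "right"
        lm = lm.with_points(
            {n: _reflect_points(p, 0.0) for n, p in lm.points.items()}
        )
        gt = GroundTruth(landmarks=lm, pose=pose, components=comp_mask,
                         reference_abmd=ref)
    return ct, mask, gt


# ---------------------------------------------------------------------------
# analytic areal-density oracle
# ---------------------------------------------------------------------------


def _ray_interval_sphere(x, z, sph: _Sphere):
    dx = x - sph.center[0]
    dz = z - sph.center[2]
    disc = sph.radius**2 - dx * dx - dz * dz
    valid = disc > 0
    h = np.sqrt(np.maximum(disc, 0.0))
    return sph.center[1] - h, sph.center[1] + h, valid


_BIG = 1e9


def _ray_interval_frustum(x, z, fr: _Frustum):
    # Rays run along +y.  Radial condition |perp(y)|^2 <= r(s(y))^2 with a
    # linearly varying radius stays quadratic in y.
    a = fr.axis
    L = fr.length
    vx = x - fr.p0[0]
    vy = -fr.p0[1]
    vz = z - fr.p0[2]
    va = vx * a[0] + vy * a[1] + vz * a[2]
    vv = vx * vx + vy * vy + vz * vz
    ea = a[1]
    k = (fr.r1 - fr.r0) / L
    alpha = fr.r0 + k * va
    gamma = k * ea
    A = (1.0 - ea * ea) - gamma * gamma
    B = 2.0 * (vy - va * ea) - 2.0 * alpha * gamma
    C = vv - va * va - alpha * alpha
    if A > 1e-9:
        disc = B * B - 4.0 * A * C
        rad_ok = disc > 0
        h = np.sqrt(np.maximum(disc, 0.0))
        r_lo = (-B - h) / (2 * A)
        r_hi = (-B + h) / (2 * A)
    elif abs(k) < 1e-12:  # ray parallel to a cylinder's axis
        rad_ok = C <= 0
        r_lo = np.full_like(x, -_BIG)
        r_hi = np.full_like(x, _BIG)
    else:  # ray nearly parallel to a cone surface: no supported interval
        rad_ok = np.zeros(np.shape(x), dtype=bool)
        r_lo = np.zeros_like(x)
        r_hi = np.zeros_like(x)
    if abs(ea) > 1e-12:
        s0 = (0.0 - va) / ea
        s1 = (L - va) / ea
        s_lo = np.minimum(s0, s1)
        s_hi = np.maximum(s0, s1)
        slab_ok = np.ones_like(rad_ok)
    else:
        slab_ok = (va >= 0) & (va <= L)
        s_lo = np.full_like(x, -_BIG)
        s_hi = np.full_like(x, _BIG)
    lo = np.maximum(r_lo, s_lo)
    hi = np.minimum(r_hi, s_hi)
    valid = rad_ok & slab_ok & (hi > lo)
    return lo, hi, valid


def _union_length(los, his, valids):
    """Total length of the union of k intervals, vectorized over rays."""
    los = np.stack(los, axis=-1)
    his = np.stack(his, axis=-1)
    valids = np.stack(valids, axis=-1)
    los = np.where(valids, los, 0.0)
    his = np.where(valids, his, 0.0)
    order = np.argsort(los, axis=-1)
    los = np.take_along_axis(los, order, axis=-1)
    his = np.take_along_axis(his, order, axis=-1)
    total = np.zeros(los.shape[:-1])
    cur_end = np.full(los.shape[:-1], -np.inf)
    for j in range(los.shape[-1]):
        s = los[..., j]
        e = his[..., j]
        total += np.clip(e - np.maximum(s, cur_end), 0.0, None)
        cur_end = np.maximum(cur_end, e)
    return total


def reference_areal_image(fspec: FemurSpec, grid_mm: float = 0.2,
                          pad: float = 2.0):
    """Closed-form coronal areal-density image of the neutral femur.

    For every (x, z) grid point the anteroposterior path lengths through
    the cortical shell and the trabecular core are computed analytically
    (ray-solid intersections, interval union), giving areal density in
    g/cm^2 with no voxelization or interpolation.  Returns
    ``(image[ix, iz], xs, zs)``.
    """
    geom = _FemurGeometry(fspec)
    lo, hi = geom.bounding_box(PoseParams(), margin=pad)
    xs = np.arange(lo[0], hi[0] + grid_mm, grid_mm)
    zs = np.arange(lo[2], hi[2] + grid_mm, grid_mm)
    gx, gz = np.meshgrid(xs, zs, indexing="ij")

    def union_len(prims):
        los, his, oks = [], [], []
        for p in prims:
            if isinstance(p, _Sphere):
                l, h, ok = _ray_interval_sphere(gx, gz, p)
            else:
                l, h, ok = _ray_interval_frustum(gx, gz, p)
            los.append(l)
            his.append(h)
            oks.append(ok)
        return _union_length(los, his, oks)

    len_full = union_len(geom.primitives)
    len_core = union_len(geom.cores)
    len_core = np.minimum(len_core, len_full)
    # mm paths -> g/cm^2: density [mg/cm^3] * length [cm] / 1000
    img = (
        fspec.trabecular_density * len_core
        + fspec.cortical_density * (len_full - len_core)
    ) * 0.1 / 1000.0
    return img, xs, zs


def _roi_mask_analytic(img, xs, zs, lm: LandmarkSet, roi_rule: str):
    bone = img > 0
    if roi_rule == "all":
        return bone
    if roi_rule != "proximal":
        raise SyntheticError(f"unknown roi rule {roi_rule!r}")
    z_cut = lm["LT_TIP"][2] - 20.0
    gx, gz = np.meshgrid(xs, zs, indexing="ij")
    keep = bone & (gz >= z_cut)
    sup = lm["HNJ_SUP"][[0, 2]]
    inf = lm["HNJ_INF"][[0, 2]]
    head = lm["HEAD_CENTER"][[0, 2]]
    d = inf - sup

    def side_sign(px, pz):
        return d[0] * (pz - sup[1]) - d[1] * (px - sup[0])

    head_side = np.sign(side_sign(head[0], head[1]))
    keep &= ~(np.sign(side_sign(gx, gz)) == head_side)
    return keep


def reference_abmd(fspec: FemurSpec, roi_rule: str = "proximal",
                   grid_mm: float = 0.2) -> float:
    """Brute-force oracle for the proximal-femur areal BMD, g/cm^2.

    Mean areal density over bone pixels of the analytic coronal image at
    neutral pose, with the same ROI rule as the pipeline: distal border
    2 cm below the lesser-trochanter tip, femoral head excluded by the
    chord through the superior/inferior head-neck-junction landmarks.
    """
    img, xs, zs = reference_areal_image(fspec, grid_mm=grid_mm)
    lm = _FemurGeometry(fspec).landmarks()
    roi = _roi_mask_analytic(img, xs, zs, lm, roi_rule)
    if not roi.any():
        raise SyntheticError("analytic ROI is empty")
    return float(img[roi].mean())


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

#: Default cohort density distribution: mean (SD) of trabecular and
#: cortical hydroxyapatite densities in mg/cm^3, spanning osteoporotic to
#: normal bone.
DENSITY_DISTRIBUTION = {"trabecular": (150.0, 50.0), "cortical": (800.0, 120.0)}


def simulate_cohort(
    n: int,
    density_distribution: dict | None = None,
    dxa_noise_sd: float = 0.0,
    seed: int = 0,
    compute_ct_abmd: bool = True,
    base_spec: FemurSpec | None = None,
    acq: AcquisitionSpec | None = None,
) -> pd.DataFrame:
    """Paired surrogate-DXA / CT-aBMD table for agreement experiments.

    ``n`` femora share the base geometry; trabecular and cortical
    densities are drawn from normal distributions (clipped to plausible
    ranges) and each case is imaged at a random pose within the
    augmentation ranges.  The surrogate DXA-BMD is the analytic oracle
    value plus Gaussian noise of ``dxa_noise_sd`` g/cm^2.  With
    ``compute_ct_abmd`` the full pipeline (phantom calibration, pose
    normalization, projection, ROI) is run per case with ground-truth
    landmarks.
    """
    if n < 2:
        raise SyntheticError("cohort needs n >= 2")
    dist = density_distribution or DENSITY_DISTRIBUTION
    base_spec = base_spec or FemurSpec()
    acq = acq or AcquisitionSpec()
    rng = np.random.default_rng(seed)

    mt, st = dist["trabecular"]
    mc, sc = dist["cortical"]
    trab = np.clip(rng.normal(mt, st, n), 10.0, 500.0)
    cort = np.clip(rng.normal(mc, sc, n), 300.0, 1400.0)
    abd = rng.uniform(-15, 15, n)
    flex = rng.uniform(-30, 30, n)
    rot = rng.uniform(-15, 15, n)

    ref = np.array([
        reference_abmd(replace(base_spec, trabecular_density=float(t),
                               cortical_density=float(c)))
        for t, c in zip(trab, cort)
    ])
    dxa = ref + (rng.normal(0.0, dxa_noise_sd, n) if dxa_noise_sd > 0 else 0.0)

    table = pd.DataFrame(
        {
            "case_id": [f"case{i:03d}" for i in range(n)],
            "trabecular_density": trab,
            "cortical_density": cort,
            "abduction": abd,
            "flexion": flex,
            "axial_rotation": rot,
            "reference_abmd": ref,
            "dxa_bmd": dxa,
        }
    )

    if compute_ct_abmd:
        from .phantom_calibration import extract_rod_samples, fit_calibration
        from .projection_bmd import run_pipeline

        pct, pmask = build_phantom(acq=replace(acq, seed=int(rng.integers(2**31))))
        dens_by_label = {i + 1: d for i, d in enumerate(B_MAS200_DENSITIES)}
        model = fit_calibration(extract_rod_samples(pct, pmask, dens_by_label))

        values = []
        for i in range(n):
            fs = replace(base_spec, trabecular_density=float(trab[i]),
                         cortical_density=float(cort[i]))
            case_acq = replace(
                acq,
                pose=PoseParams(abduction=float(abd[i]), flexion=float(flex[i]),
                                axial_rotation=float(rot[i])),
                seed=int(rng.integers(2**31)),
            )
            ct, mask, gt = build_femur(fs, case_acq)
            result = run_pipeline(ct, mask, model, gt.landmarks)
            if result.failure is not None:
                values.append(np.nan)
            else:
                values.append(result.abmd.ct_abmd)
        table["ct_abmd"] = values
    return table
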