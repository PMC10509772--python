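"""Phantom-based HU -> density calibration.

A rod phantom with known hydroxyapatite-equivalent densities (B-MAS200
style: 0, 50, 100, 150, 200 mg/cm^3) is scanned with the patient.  The
mean HU of each rod is regressed against its nominal density (ordinary
least squares, density on HU) and the fitted affine map converts every
voxel of the CT volume into mg/cm^3.  A fixed (phantom-less /
asynchronous) calibration can be supplied instead when no phantom was
scanned; it must be chosen explicitly — there is no silent fallback.

Rod labels are eroded by one voxel before averaging to suppress
partial-volume voxels at the rod surface.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage, stats

from .volumes_io import CTVolume, DensityVolume, LabelMask, VolumeError

__all__ = [
    "RodSample",
    "CalibrationModel",
    "CalibrationError",
    "extract_rod_samples",
    "fit_calibration",
    "apply_calibration",
    "make_fixed_calibration",
    "save_calibration",
    "load_calibration",
]

#: Minimum voxels a rod must keep after the one-voxel erosion.
MIN_ROD_VOXELS = 50


class CalibrationError(ValueError):
    """Raised for unusable rod samples or calibration models."""


@dataclass(frozen=True)
class RodSample:
    """Per-rod statistics used to fit the calibration line."""

    label: int
    nominal_density: float  # mg/cm^3 hydroxyapatite
    mean_hu: float
    sd_hu: float
    voxel_count: int

    def __post_init__(self):
        if self.nominal_density < 0:
            raise CalibrationError("nominal density must be >= 0")
        if self.voxel_count < 1:
            raise CalibrationError(
                f"rod label {self.label} has no voxels"
            )


@dataclass(frozen=True)
class CalibrationModel:
    """Linear HU -> density map: density = slope * HU + intercept."""

    slope: float       # mg/cm^3 per HU
    intercept: float   # mg/cm^3
    r_squared: float
    n_rods: int
    source: str        # phantom | fixed | stored

    def __post_init__(self):
        if self.slope <= 0:
            raise CalibrationError("calibration slope must be positive")
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise CalibrationError("r_squared must lie in [0, 1]")
        if self.source not in ("phantom", "fixed", "stored"):
            raise CalibrationError(f"unknown calibration source {self.source!r}")
        if self.source == "phantom" and self.n_rods < 2:
            raise CalibrationError("phantom calibration needs >= 2 rods")

    def density_from_hu(self, hu):
        return self.slope * np.asarray(hu, dtype=float) + self.intercept


def extract_rod_samples(
    ct: CTVolume,
    rod_mask: LabelMask,
    nominal_densities: dict[int, float],
    min_voxels: int = MIN_ROD_VOXELS,
) -> list[RodSample]:
    """Mean/SD HU per rod label after a one-voxel erosion.

    ``nominal_densities`` maps every label present in the mask to its
    hydroxyapatite density in mg/cm^3.  Samples are returned ordered by
    nominal density.
    """
    if not ct.geometry_matches(rod_mask):
        raise VolumeError("rod mask geometry does not match the CT volume")
    labels = [int(v) for v in np.unique(rod_mask.labels) if v != 0]
    missing = [lab for lab in labels if lab not in nominal_densities]
    if missing:
        raise CalibrationError(f"mask labels without a nominal density: {missing}")

    samples = []
    for lab in labels:
        region = rod_mask.labels == lab
        eroded = ndimage.binary_erosion(region)  # partial-volume guard
        n = int(eroded.sum())
        if n < min_voxels:
            raise CalibrationError(
                f"rod label {lab} has {n} voxels after erosion "
                f"(minimum {min_voxels})"
            )
        vals = ct.voxels[eroded]
        samples.append(
            RodSample(
                label=lab,
                nominal_density=float(nominal_densities[lab]),
                mean_hu=float(vals.mean()),
                sd_hu=float(vals.std()),
                voxel_count=n,
            )
        )
    samples.sort(key=lambda s: s.nominal_density)
    return samples


def fit_calibration(samples: list[RodSample]) -> CalibrationModel:
    """Ordinary least squares of nominal density on mean HU."""
    if len(samples) < 2:
        raise CalibrationError("need at least 2 rod samples to fit a line")
    hu = np.array([s.mean_hu for s in samples], dtype=float)
    dens = np.array([s.nominal_density for s in samples], dtype=float)
    if np.ptp(hu) < 1e-12:
        raise CalibrationError("all rod mean HUs are equal; singular fit")
    res = stats.linregress(hu, dens)
    slope, intercept = float(res.slope), float(res.intercept)
    # r^2 of the simple regression; exact 1 for an interpolating 2-point line
    pred = slope * hu + intercept
    ss_res = float(np.sum((dens - pred) ** 2))
    ss_tot = float(np.sum((dens - dens.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else max(0.0, min(1.0, 1.0 - ss_res / ss_tot))
    return CalibrationModel(slope, intercept, r2, n_rods=len(samples),
                            source="phantom")


def apply_calibration(ct: CTVolume, model: CalibrationModel) -> DensityVolume:
    """Voxelwise density = slope*HU + intercept; geometry preserved.

    Values may come out negative for soft tissue / marrow; they are kept
    as-is here — clipping happens only inside the bone mask at projection
    time.
    """
    return DensityVolume(
        model.density_from_hu(ct.voxels),
        ct.spacing.copy(),
        ct.origin.copy(),
        ct.direction.copy(),
        side=ct.side,
    )


def make_fixed_calibration(slope: float, intercept: float,
                           source: str = "fixed") -> CalibrationModel:
    """Phantom-less / stored calibration used verbatim by apply_calibration."""
    if source not in ("fixed", "stored"):
        raise CalibrationError("fixed calibration source must be fixed|stored")
    return CalibrationModel(float(slope), float(intercept), r_squared=1.0,
                            n_rods=0, source=source)


def save_calibration(model: CalibrationModel, path) -> None:
    Path(path).write_text(json.dumps(asdict(model), indent=1))


def load_calibration(path) -> CalibrationModel:
    obj = json.loads(Path(path).read_text())
    src = obj["source"]
    if src == "phantom":  # a reloaded phantom fit is an asynchronous calibration
        src = "stored"
    return CalibrationModel(obj["slope"], obj["intercept"], obj["r_squared"],
                            obj["n_rods"], src)
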