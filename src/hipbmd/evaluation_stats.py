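"""Agreement, ROC, segmentation and landmark-error machinery.

These are the standard tools for validating a densitometry pipeline
against a reference: Pearson correlation and Bland-Altman limits of
agreement between paired BMD measurements, ROC analysis with the
Youden-optimal cutoff for the osteoporosis classification, Dice and
mean symmetric surface distance for segmentation masks, and per-landmark
3-D distance / positioning-angle error summaries for landmark sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from scipy.spatial import cKDTree

from .pose_normalization import angles_from_landmarks
from .volumes_io import LabelMask, LandmarkSet, VolumeError

__all__ = [
    "AgreementReport",
    "ROCReport",
    "LandmarkEvalReport",
    "agreement",
    "roc_analysis",
    "segmentation_metrics",
    "landmark_eval",
]


@dataclass(frozen=True)
class AgreementReport:
    """Pearson + Bland-Altman + absolute-error summary of paired values.

    Differences are a - b; limits of agreement are mean +/- 1.96 SD.
    ``pearson_r`` is None when either series has zero variance.
    """

    pearson_r: float | None
    mean_difference: float
    sd_difference: float
    loa_low: float
    loa_high: float
    median_abs_error: float
    iqr_abs_error: tuple[float, float]
    n: int


def agreement(a, b) -> AgreementReport:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired measurements must be 1-D and equal length")
    if len(a) < 3:
        raise ValueError("need at least 3 pairs")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("measurements must be finite")

    if np.ptp(a) == 0 or np.ptp(b) == 0:
        r = None  # correlation undefined for a constant series
    else:
        r = float(stats.pearsonr(a, b).statistic)

    diff = a - b
    mean_d = float(diff.mean())
    sd_d = float(diff.std(ddof=1))
    abs_err = np.abs(diff)
    q25, q75 = np.percentile(abs_err, [25, 75])
    return AgreementReport(
        pearson_r=r,
        mean_difference=mean_d,
        sd_difference=sd_d,
        loa_low=mean_d - 1.96 * sd_d,
        loa_high=mean_d + 1.96 * sd_d,
        median_abs_error=float(np.median(abs_err)),
        iqr_abs_error=(float(q25), float(q75)),
        n=len(a),
    )


@dataclass(frozen=True)
class ROCReport:
    """ROC summary; sensitivity/specificity in percent at the cutoff."""

    auc: float
    optimal_cutoff: float
    sensitivity: float
    specificity: float
    curve: np.ndarray  # (k, 2) array of (1-specificity, sensitivity) in [0,1]

    def __post_init__(self):
        if not (0.0 <= self.auc <= 1.0):
            raise ValueError("AUC must lie in [0, 1]")


def roc_analysis(scores, labels, direction: str = "lower") -> ROCReport:
    """ROC analysis of a BMD score against osteoporotic flags.

    ``direction="lower"`` means a lower score indicates the positive
    (osteoporotic) class — the clinical reading of a BMD cutoff.  The
    AUC is the rank (Mann-Whitney) statistic with ties counted half;
    the optimal cutoff maximizes Youden's J, ties broken toward the
    lower (more sensitive, for direction="lower") cutoff.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-D and equal length")
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present")
    if direction not in ("lower", "higher"):
        raise ValueError("direction must be 'lower' or 'higher'")

    s = -scores if direction == "lower" else scores
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    ranks = stats.rankdata(s)  # average ranks handle ties => half credit
    auc = float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0)
                / (n_pos * n_neg))

    uniq = np.unique(scores)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    candidates = np.concatenate(([uniq[0] - 1.0], mids, [uniq[-1] + 1.0]))
    if direction == "lower":
        pos_pred = scores[None, :] < candidates[:, None]
    else:
        pos_pred = scores[None, :] > candidates[:, None]
    tp = (pos_pred & labels[None, :]).sum(axis=1)
    fp = (pos_pred & ~labels[None, :]).sum(axis=1)
    sens = tp / n_pos
    spec = 1.0 - fp / n_neg
    j = sens + spec - 1.0
    best_j = j.max()
    best_idx = np.flatnonzero(j >= best_j - 1e-12)
    cutoff = float(candidates[best_idx].min())  # tie -> lower cutoff
    at = int(best_idx[np.argmin(candidates[best_idx])])

    order = np.argsort(1.0 - spec, kind="stable")
    curve = np.column_stack([(1.0 - spec)[order], sens[order]])
    return ROCReport(
        auc=auc,
        optimal_cutoff=cutoff,
        sensitivity=float(100.0 * sens[at]),
        specificity=float(100.0 * spec[at]),
        curve=curve,
    )


def segmentation_metrics(a: LabelMask, b: LabelMask) -> tuple[float, float]:
    """Dice coefficient and mean symmetric surface distance (mm).

    Dice = 2|A n B| / (|A| + |B|) over non-zero voxels.  MSD is the mean
    of the nearest-surface distances between boundary voxel centres,
    symmetrized over both directions.
    """
    if not a.geometry_matches(b):
        raise VolumeError("masks must share geometry")
    am = a.labels > 0
    bm = b.labels > 0
    na, nb = int(am.sum()), int(bm.sum())
    if na == 0 and nb == 0:
        raise VolumeError("both masks are empty")
    inter = int((am & bm).sum())
    dice = 2.0 * inter / (na + nb)
    if na == 0 or nb == 0:
        return dice, float("inf")

    def boundary_points(mask, grid):
        surf = mask & ~ndimage.binary_erosion(mask)
        return grid.index_to_world(np.argwhere(surf).astype(float))

    pa = boundary_points(am, a)
    pb = boundary_points(bm, b)
    d_ab, _ = cKDTree(pb).query(pa)
    d_ba, _ = cKDTree(pa).query(pb)
    msd = (d_ab.sum() + d_ba.sum()) / (len(pa) + len(pb))
    return float(dice), float(msd)


@dataclass
class LandmarkEvalReport:
    """Per-landmark 3-D distances and positioning-angle errors."""

    distances: pd.DataFrame        # cases x landmark names, mm
    distance_summary: pd.DataFrame  # median / IQR per landmark
    angle_errors: pd.DataFrame     # per-case |angle difference|, degrees
    angle_summary: pd.DataFrame


def landmark_eval(manual: list[LandmarkSet], auto: list[LandmarkSet]
                  ) -> LandmarkEvalReport:
    """Compare automatically selected landmarks against manual ones.

    Reports per-landmark Euclidean distances (median and IQR across
    cases) and, per case, the absolute differences of the decomposed
    positioning angles (abduction, flexion, axial rotation) implied by
    each landmark set.
    """
    if len(manual) != len(auto) or not manual:
        raise ValueError("need equally many manual and automatic cases")
    names = manual[0].names()
    rows = []
    angle_rows = []
    for i, (m, au) in enumerate(zip(manual, auto)):
        if set(m.names()) != set(names) or set(au.names()) != set(names):
            raise ValueError(f"case {i}: landmark names mismatch")
        rows.append(
            {n: float(np.linalg.norm(m[n] - au[n])) for n in names}
        )
        _, _, ang_m = angles_from_landmarks(m)
        _, _, ang_a = angles_from_landmarks(au)
        angle_rows.append(
            {
                "abduction": abs(ang_m.abduction - ang_a.abduction),
                "flexion": abs(ang_m.flexion - ang_a.flexion),
                "axial_rotation": abs(ang_m.axial_rotation
                                      - ang_a.axial_rotation),
            }
        )
    distances = pd.DataFrame(rows)
    angle_errors = pd.DataFrame(angle_rows)

    def summary(df):
        return pd.DataFrame(
            {
                "median": df.median(),
                "q25": df.quantile(0.25),
                "q75": df.quantile(0.75),
            }
        )

    return LandmarkEvalReport(
        distances=distances,
        distance_summary=summary(distances),
        angle_errors=angle_errors,
        angle_summary=summary(angle_errors),
    )
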