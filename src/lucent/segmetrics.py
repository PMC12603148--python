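"""Volumetric segmentation metrics: DSC, VOE, RVD, ASSD, precision, FNR,
FPR and mean IoU, with spacing-aware surface distances.

Scale conventions: DSC/VOE/RVD/precision/FNR/FPR are reported in percent,
ASSD in millimetres, and mIoU as a fraction (mean of foreground and
background IoU). RVD is reported as an absolute value; the signed variant
(|P|-|G|)/|G| is exposed as a secondary field. FPR uses the full-grid
background voxel count as its denominator (the standard definition).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass

import numpy as np
from scipy.spatial import cKDTree


@dataclass
class SegMetrics:
    dsc_pct: float
    voe_pct: float
    rvd_pct: float
    assd_mm: float
    precision_pct: float
    fnr_pct: float
    fpr_pct: float
    miou_frac: float
    rvd_signed_pct: float

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    def to_row(self) -> dict:
        return asdict(self)


def _validate(pred: np.ndarray, gt: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred, dtype=bool)
    gt = np.asarray(gt, dtype=bool)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {gt.shape}")
    return pred, gt


def overlap_metrics(pred: np.ndarray, gt: np.ndarray):
    """Voxel-overlap metrics; returns (dsc, voe, rvd, miou, precision, fnr, fpr)
    with percentages except miou (fraction). Both-empty masks are defined as
    perfect agreement (with a warning); empty gt with nonempty pred makes RVD
    undefined and raises.
    """
    pred, gt = _validate(pred, gt)
    n = pred.size
    p = int(pred.sum())
    g = int(gt.sum())
    inter = int((pred & gt).sum())
    union = p + g - inter
    if g == 0 and p == 0:
        warnings.warn("both masks empty: metrics defined as perfect agreement",
                      stacklevel=2)
        return 100.0, 0.0, 0.0, 1.0, 100.0, 0.0, 0.0
    if g == 0:
        raise ValueError("ground truth empty but prediction nonempty: RVD undefined")
    dsc = 100.0 * 2.0 * inter / (p + g)
    voe = 100.0 * (1.0 - inter / union)
    rvd = 100.0 * abs(p - g) / g
    iou_fg = inter / union
    bg_inter = n - union
    bg_union = n - inter
    iou_bg = bg_inter / bg_union if bg_union > 0 else 1.0
    miou = 0.5 * (iou_fg + iou_bg)
    precision = 100.0 * inter / p if p > 0 else float("nan")
    fnr = 100.0 * (g - inter) / g
    fpr = 100.0 * (p - inter) / (n - g) if n > g else 0.0
    return dsc, voe, rvd, miou, precision, fnr, fpr


def surface_voxels(mask: np.ndarray, spacing_mm=(1.0, 1.0, 1.0)) -> np.ndarray:
    """Centers (mm) of foreground voxels with >= 1 background 6-neighbour.

    The volume border counts as background, so voxels on the array edge are
    surface voxels.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask has no surface")
    padded = np.pad(mask, 1)
    interior = padded.copy()
    for ax in range(3):
        for shift in (1, -1):
            interior &= np.roll(padded, shift, axis=ax)
    surface = mask & ~interior[1:-1, 1:-1, 1:-1]
    pts = np.argwhere(surface).astype(float)
    return pts * np.asarray(spacing_mm)


def assd(pred: np.ndarray, gt: np.ndarray, spacing_mm=(1.0, 1.0, 1.0)) -> float:
    """Average symmetric surface distance in mm between two nonempty masks."""
    sp = surface_voxels(pred, spacing_mm)
    sg = surface_voxels(gt, spacing_mm)
    d_pg = cKDTree(sg).query(sp)[0]
    d_gp = cKDTree(sp).query(sg)[0]
    return float((d_pg.sum() + d_gp.sum()) / (len(sp) + len(sg)))


def seg_report(pred: np.ndarray, gt: np.ndarray,
               spacing_mm=(1.0, 1.0, 1.0)) -> SegMetrics:
    """Assemble the full metric row for one (prediction, ground truth) pair."""
    pred, gt = _validate(pred, gt)
    dsc, voe, rvd, miou, precision, fnr, fpr = overlap_metrics(pred, gt)
    p, g = int(pred.sum()), int(gt.sum())
    signed = 100.0 * (p - g) / g if g > 0 else 0.0
    a = assd(pred, gt, spacing_mm) if (p > 0 and g > 0) else (
        0.0 if p == g == 0 else float("nan"))
    return SegMetrics(dsc, voe, rvd, a, precision, fnr, fpr, miou, signed)
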