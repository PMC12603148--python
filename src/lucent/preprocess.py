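"""Standardized CT preprocessing.

Pipeline order is fixed: resample to isotropic spacing (trilinear;
nearest-neighbour for masks) -> clip to the chest HU window [-1000, +400]
and min-max normalize to [0, 1] -> center-crop/zero-pad to a standard shape
about the airway centroid -> Gaussian smooth (sigma in voxels). 2D
projection images destined for the classifier additionally get a Z-score
normalization.

Padding uses 0.0, i.e. air in the normalized intensity domain. Smoothing is
the only non-idempotent step; re-running the pipeline on its own output is
otherwise a no-op.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from lucent.core import HU, UNIT, CTVolume

DEFAULT_HU_WINDOW = (-1000.0, 400.0)


@dataclass
class PreprocessConfig:
    target_spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    hu_window: tuple[float, float] = DEFAULT_HU_WINDOW
    target_shape: tuple[int, int, int] = (128, 128, 128)
    smoothing_sigma: float = 1.0
    zscore_mean: float | tuple = 0.0
    zscore_sd: float | tuple = 1.0

    def __post_init__(self) -> None:
        if self.hu_window[0] >= self.hu_window[1]:
            raise ValueError("hu_window lower bound must be < upper bound")
        if any(s <= 0 for s in self.target_shape):
            raise ValueError("target_shape must be positive")
        if self.smoothing_sigma < 0:
            raise ValueError("smoothing_sigma must be >= 0")


def resample_isotropic(vol: CTVolume, target_spacing=(1.0, 1.0, 1.0),
                       is_mask: bool = False) -> CTVolume:
    """Resample to the target spacing (trilinear; nearest-neighbour for masks).

    Output shape is round(input_shape * input_spacing / target_spacing).
    """
    target = np.asarray(target_spacing, dtype=float)
    if (target <= 0).any():
        raise ValueError(f"non-positive target spacing {target_spacing}")
    src = np.asarray(vol.spacing_mm)
    out_shape = np.round(np.array(vol.shape) * src / target).astype(int)
    out_shape = np.maximum(out_shape, 1)
    zoom = out_shape / np.array(vol.shape)
    if np.allclose(zoom, 1.0):
        return vol.with_voxels(vol.voxels.copy(), spacing_mm=tuple(target))
    order = 0 if is_mask else 1
    data = ndimage.zoom(vol.voxels, zoom, order=order, mode="nearest", grid_mode=True)
    # grid_mode=True treats voxels as cells so physical extent is preserved
    if is_mask:
        data = (data > 0.5).astype(np.float32)
    return vol.with_voxels(data.astype(np.float32), spacing_mm=tuple(target))


def clip_normalize(vol: CTVolume, window=DEFAULT_HU_WINDOW) -> CTVolume:
    """Clip HU to ``window`` and min-max scale to [0, 1]."""
    lo, hi = float(window[0]), float(window[1])
    if lo >= hi:
        raise ValueError(f"degenerate HU window {window}")
    if vol.intensity_domain != HU:
        raise ValueError("clip_normalize expects an HU-domain volume")
    v = (np.clip(vol.voxels, lo, hi) - lo) / (hi - lo)
    return vol.with_voxels(v.astype(np.float32), intensity_domain=UNIT)


def center_crop_pad(vol: CTVolume, mask: np.ndarray | None,
                    target_shape=(128, 128, 128)) -> tuple[CTVolume, np.ndarray | None]:
    """Center-crop or zero-pad to ``target_shape`` about the mask centroid.

    The window is centered on the integer-rounded centroid of mask voxels
    (volume center if the mask is empty or absent). The volume pads with
    0.0 — air in the normalized domain — and the mask with background. A
    warning reports any ground-truth voxels clipped away.
    """
    shape = np.array(vol.shape)
    tgt = np.array(target_shape, dtype=int)
    if mask is not None and mask.any():
        centroid = np.round(np.argwhere(mask).mean(axis=0)).astype(int)
    else:
        centroid = shape // 2
    start = centroid - tgt // 2
    # source/destination index ranges after clipping to the input bounds
    src_lo = np.maximum(start, 0)
    src_hi = np.minimum(start + tgt, shape)
    dst_lo = src_lo - start
    dst_hi = dst_lo + (src_hi - src_lo)

    out_v = np.zeros(tuple(tgt), dtype=np.float32)
    sl_src = tuple(slice(a, b) for a, b in zip(src_lo, src_hi))
    sl_dst = tuple(slice(a, b) for a, b in zip(dst_lo, dst_hi))
    out_v[sl_dst] = vol.voxels[sl_src]
    out_m = None
    if mask is not None:
        out_m = np.zeros(tuple(tgt), dtype=bool)
        out_m[sl_dst] = mask[sl_src]
        lost = int(mask.sum() - out_m.sum())
        if lost > 0:
            warnings.warn(f"center_crop_pad clipped {lost} mask voxels outside "
                          f"the target window", stacklevel=2)
    return vol.with_voxels(out_v), out_m


def smooth(vol: CTVolume, sigma: float = 1.0) -> CTVolume:
    """Gaussian smoothing with sigma in voxel units; sigma=0 is the identity."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return vol.with_voxels(vol.voxels.copy())
    return vol.with_voxels(ndimage.gaussian_filter(vol.voxels, sigma).astype(np.float32))


def zscore_image(img: np.ndarray, mean, sd) -> np.ndarray:
    """Channel-wise (img - mean) / sd for 2D projection images."""
    mean = np.asarray(mean, dtype=np.float32)
    sd = np.asarray(sd, dtype=np.float32)
    if (sd <= 0).any():
        raise ValueError("sd must be > 0")
    return (np.asarray(img, dtype=np.float32) - mean) / sd


def preprocess_volume(vol: CTVolume, mask: np.ndarray | None,
                      cfg: PreprocessConfig | None = None
                      ) -> tuple[CTVolume, np.ndarray | None]:
    """Full pipeline: resample -> clip/normalize -> center-crop/pad -> smooth."""
    cfg = cfg or PreprocessConfig()
    v = resample_isotropic(vol, cfg.target_spacing_mm)
    m = None
    if mask is not None:
        mvol = CTVolume(mask.astype(np.float32), spacing_mm=vol.spacing_mm)
        m = resample_isotropic(mvol, cfg.target_spacing_mm, is_mask=True).voxels > 0.5
    v = clip_normalize(v, cfg.hu_window)
    v, m = center_crop_pad(v, m, cfg.target_shape)
    v = smooth(v, cfg.smoothing_sigma)
    return v, m
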