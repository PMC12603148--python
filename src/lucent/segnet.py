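"""3D encoder-decoder airway segmentation network with focal-loss training.

The architecture follows the encoder-decoder-with-skips family used for
airway segmentation: each encoder level is two 3x3x3 convolutions with
batch normalization and ReLU (optionally wrapped in a residual shortcut),
followed by 2x2x2 max pooling; the decoder upsamples with transposed
convolutions, concatenates the symmetric encoder features, and may apply
squeeze-and-excitation channel attention; a final 1x1x1 convolution with a
sigmoid produces the per-voxel airway probability.

Training minimizes the voxel-wise focal loss

    L = -alpha_t * (1 - p_t)^gamma * log(p_t),

with p_t the predicted probability of the true voxel class and alpha_t the
class weight (alpha on airway voxels, 1-alpha on background); the defaults
gamma = 2.0, alpha = 0.25 down-weight the abundant easy background.

Everything runs on CPU NumPy; the desk-scale default (depth 2, 8 base
channels, 32-cubed crops) trains in minutes, while deeper/full-resolution
configurations are expressible through the same config.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from lucent.core import CTVolume
from lucent import nn

EPS = 1e-7


@dataclass
class FocalParams:
    alpha: float = 0.25
    gamma: float = 2.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")


@dataclass
class SegNetConfig:
    depth: int = 2
    base_channels: int = 8
    use_residual: bool = True
    use_channel_attention: bool = True
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.base_channels < 4:
            raise ValueError("base_channels must be >= 4")
        if not 0.0 < self.threshold < 1.0 and self.threshold != 1.0:
            # threshold 1.0 is a documented edge (empty mask under strict >)
            raise ValueError("threshold must be in (0, 1]")


@dataclass
class SegAugmentConfig:
    """Online 3D augmentation menu for segmentation training."""

    flip: bool = True
    rotate_deg: float = 15.0          # small in-plane rotations, +/- range
    noise_sd: float = 0.02            # additive Gaussian, normalized units
    brightness: float = 0.15          # +/- additive shift
    contrast: float = 0.15            # +/- multiplicative about the mean
    elastic: bool = False             # smooth random displacement field
    elastic_alpha: float = 2.0
    elastic_sigma: float = 4.0

    @classmethod
    def disabled(cls) -> "SegAugmentConfig":
        return cls(flip=False, rotate_deg=0.0, noise_sd=0.0,
                   brightness=0.0, contrast=0.0, elastic=False)


# --------------------------------------------------------------------------
# focal loss
# --------------------------------------------------------------------------


def focal_loss(p: np.ndarray, y: np.ndarray, params: FocalParams) -> float:
    """Mean voxel-wise focal loss of probabilities ``p`` against binary ``y``.

    p_t = p where y = 1 else 1 - p; alpha_t = alpha on positives, 1 - alpha
    on negatives. Probabilities are clamped to [1e-7, 1 - 1e-7] before the
    logarithm.
    """
    p = np.asarray(p, dtype=np.float64)
    y = np.asarray(y)
    if p.shape != y.shape:
        raise ValueError(f"shape mismatch {p.shape} vs {y.shape}")
    y = y.astype(bool)
    p = np.clip(p, EPS, 1.0 - EPS)
    pt = np.where(y, p, 1.0 - p)
    at = np.where(y, params.alpha, 1.0 - params.alpha)
    return float(np.mean(-at * (1.0 - pt) ** params.gamma * np.log(pt)))


def focal_loss_grad(p: np.ndarray, y: np.ndarray, params: FocalParams) -> np.ndarray:
    """dL/dp of the mean focal loss (same clamping as :func:`focal_loss`)."""
    y = np.asarray(y).astype(bool)
    pc = np.clip(np.asarray(p, dtype=np.float64), EPS, 1.0 - EPS)
    a, g = params.alpha, params.gamma
    pt = np.where(y, pc, 1.0 - pc)
    at = np.where(y, a, 1.0 - a)
    # dL/dpt, then chain dpt/dp = +1 (y=1) or -1 (y=0)
    dpt = at * (g * (1.0 - pt) ** (g - 1.0) * np.log(pt) - (1.0 - pt) ** g / pt)
    grad = np.where(y, dpt, -dpt) / p.size
    # clamped region carries no gradient
    grad[(np.asarray(p) < EPS) | (np.asarray(p) > 1.0 - EPS)] = 0.0
    return grad.astype(np.float32)


# --------------------------------------------------------------------------
# network
# --------------------------------------------------------------------------


class SegNet3d(nn.Module):
    """Encoder-decoder with skip connections; maps (B,1,D,H,W) -> per-voxel
    probabilities of the same spatial shape (D,H,W divisible by 2^depth)."""

    def __init__(self, cfg: SegNetConfig, rng: np.random.Generator, dtype=np.float32):
        self.cfg = cfg
        ch = [cfg.base_channels * 2 ** i for i in range(cfg.depth)]
        self.enc = []
        cin = 1
        for c in ch:
            self.enc.append(nn.ConvBlock3d(cin, c, rng, residual=cfg.use_residual,
                                           dtype=dtype))
            cin = c
        self.pools = [nn.MaxPool3d() for _ in ch]
        self.bottleneck = nn.ConvBlock3d(ch[-1], ch[-1] * 2, rng,
                                         residual=cfg.use_residual, dtype=dtype)
        self.ups = []
        self.dec = []
        self.att = []
        prev = ch[-1] * 2
        for c in reversed(ch):
            self.ups.append(nn.ConvTranspose3d(prev, c, rng, dtype=dtype))
            self.dec.append(nn.ConvBlock3d(2 * c, c, rng, residual=False, dtype=dtype))
            self.att.append(nn.SqueezeExcite3d(c, rng, dtype=dtype)
                            if cfg.use_channel_attention else None)
            prev = c
        self.final = nn.Conv3d(ch[0], 1, 1, rng, pad=0, dtype=dtype)
        self.sigmoid = nn.Sigmoid()

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        d = 2 ** self.cfg.depth
        if any(s % d for s in x.shape[2:]):
            raise ValueError(f"input spatial shape {x.shape[2:]} not divisible by {d}")
        skips = []
        h = x
        for enc, pool in zip(self.enc, self.pools):
            h = enc.forward(h, train)
            skips.append(h)
            h = pool.forward(h, train)
        h = self.bottleneck.forward(h, train)
        self._split = []
        for up, dec, att, skip in zip(self.ups, self.dec, self.att, reversed(skips)):
            h = up.forward(h, train)
            self._split.append(skip.shape[1])
            h = np.concatenate([skip, h], axis=1)
            h = dec.forward(h, train)
            if att is not None:
                h = att.forward(h, train)
        logits = self.final.forward(h, train)
        return self.sigmoid.forward(logits, train)

    def backward(self, gp: np.ndarray) -> np.ndarray:
        g = self.final.backward(self.sigmoid.backward(gp))
        gskips = []
        for up, dec, att, c in zip(reversed(self.ups), reversed(self.dec),
                                   reversed(self.att), reversed(self._split)):
            if att is not None:
                g = att.backward(g)
            g = dec.backward(g)
            gskips.append(g[:, :c])
            g = up.backward(g[:, c:])
        g = self.bottleneck.backward(g)
        for enc, pool, gskip in zip(reversed(self.enc), reversed(self.pools),
                                    reversed(gskips)):
            g = pool.backward(g)
            g = enc.backward(g + gskip)
        return g


def build_segnet(cfg: SegNetConfig | None = None, seed: int = 0) -> SegNet3d:
    """Construct a seeded segmentation network from its configuration."""
    cfg = cfg or SegNetConfig()
    return SegNet3d(cfg, np.random.default_rng(np.random.SeedSequence([seed, 0x5E6])))


# --------------------------------------------------------------------------
# augmentation
# --------------------------------------------------------------------------


def augment_volume(vol: np.ndarray, mask: np.ndarray, cfg: SegAugmentConfig,
                   rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Apply the online 3D augmentation menu to one (volume, mask) pair."""
    v, m = vol, mask
    if cfg.flip:
        for ax in range(3):
            if rng.random() < 0.5:
                v = np.flip(v, ax)
                m = np.flip(m, ax)
    if cfg.rotate_deg > 0:
        ang = rng.uniform(-cfg.rotate_deg, cfg.rotate_deg)
        v = ndimage.rotate(v, ang, axes=(0, 1), reshape=False, order=1, mode="nearest")
        m = ndimage.rotate(m.astype(np.float32), ang, axes=(0, 1), reshape=False,
                           order=0, mode="nearest") > 0.5
    if cfg.elastic:
        disp = [ndimage.gaussian_filter(rng.standard_normal(v.shape), cfg.elastic_sigma)
                * cfg.elastic_alpha for _ in range(3)]
        idx = np.meshgrid(*[np.arange(s) for s in v.shape], indexing="ij")
        coords = [i + d for i, d in zip(idx, disp)]
        v = ndimage.map_coordinates(v, coords, order=1, mode="nearest")
        m = ndimage.map_coordinates(m.astype(np.float32), coords, order=0,
                                    mode="nearest") > 0.5
    if cfg.contrast > 0 or cfg.brightness > 0:
        c = rng.uniform(1.0 - cfg.contrast, 1.0 + cfg.contrast)
        b = rng.uniform(-cfg.brightness, cfg.brightness)
        mu = v.mean()
        v = np.clip(mu + (v - mu) * c + b, 0.0, 1.0)
    if cfg.noise_sd > 0:
        v = np.clip(v + rng.normal(0.0, cfg.noise_sd, v.shape), 0.0, 1.0)
    return np.ascontiguousarray(v, dtype=np.float32), np.ascontiguousarray(m)


def _crop_around(vol: np.ndarray, mask: np.ndarray, size: int,
                 rng: np.random.Generator | None) -> tuple[np.ndarray, np.ndarray]:
    """Cube crop of ``size`` centered on the mask centroid, with optional jitter."""
    shape = np.array(vol.shape)
    centroid = np.round(np.argwhere(mask).mean(axis=0)).astype(int)
    if rng is not None:
        centroid = centroid + rng.integers(-4, 5, 3)
    start = np.clip(centroid - size // 2, 0, np.maximum(shape - size, 0))
    sl = tuple(slice(s, s + size) for s in start)
    v, m = vol[sl], mask[sl]
    if v.shape != (size, size, size):  # pad if the volume is smaller than the crop
        pv = np.zeros((size, size, size), np.float32)
        pm = np.zeros((size, size, size), bool)
        pv[:v.shape[0], :v.shape[1], :v.shape[2]] = v
        pm[:m.shape[0], :m.shape[1], :m.shape[2]] = m
        v, m = pv, pm
    return v, m


# --------------------------------------------------------------------------
# training / inference
# --------------------------------------------------------------------------


def dice_coefficient(pred: np.ndarray, gt: np.ndarray) -> float:
    """Plain Dice on boolean masks (1.0 when both empty)."""
    pred = np.asarray(pred, bool)
    gt = np.asarray(gt, bool)
    denom = pred.sum() + gt.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * (pred & gt).sum() / denom)


def train_segnet(train_pairs, cfg: SegNetConfig | None = None,
                 focal: FocalParams | None = None,
                 aug: SegAugmentConfig | None = None,
                 val_pairs=None, epochs: int = 20, lr: float = 1e-3,
                 crop_size: int = 32, seed: int = 0,
                 model: SegNet3d | None = None) -> tuple[SegNet3d, dict]:
    """Train a segmentation network on (volume, mask) array pairs.

    Volumes must be preprocessed (unit-normalized, common spacing). Each
    step draws one airway-centred crop per sample with online augmentation
    (training set only). History records per-step training loss, per-epoch
    mean loss and validation Dice; the best-validation-Dice weights are
    restored at the end. All randomness derives from ``seed``.
    """
    if len(train_pairs) == 0:
        raise ValueError("empty training set")
    cfg = cfg or SegNetConfig()
    focal = focal or FocalParams()
    aug = aug if aug is not None else SegAugmentConfig()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x7A]))
    model = model or build_segnet(cfg, seed=seed)
    opt = nn.Adam(model.params(), lr=lr)

    history = {"step_loss": [], "train_loss": [], "val_dsc": [], "epoch": []}
    best = (-1.0, None)
    for epoch in range(epochs):
        order = rng.permutation(len(train_pairs))
        losses = []
        for i in order:
            vol, mask = train_pairs[i]
            v, m = _crop_around(vol, mask, crop_size, rng)
            v, m = augment_volume(v, m, aug, rng)
            x = v[None, None]
            p = model.forward(x, train=True)
            loss = focal_loss(p[0, 0], m, focal)
            gp = focal_loss_grad(p[0, 0], m, focal)[None, None]
            opt.zero_grad()
            model.backward(gp.astype(p.dtype))
            opt.step()
            losses.append(loss)
            history["step_loss"].append(loss)
        history["epoch"].append(epoch)
        history["train_loss"].append(float(np.mean(losses)))
        if val_pairs:
            dscs = []
            for vol, mask in val_pairs:
                v, m = _crop_around(vol, mask, crop_size, None)
                pred = predict_mask(model, v, threshold=cfg.threshold)
                dscs.append(dice_coefficient(pred, m))
            vd = float(np.mean(dscs))
            history["val_dsc"].append(vd)
            if vd > best[0]:
                best = (vd, model.state())
    if best[1] is not None:
        model.load_state(best[1])
    return model, history


def predict_mask(model: SegNet3d, vol: np.ndarray | CTVolume,
                 threshold: float = 0.5, largest_component: bool = True) -> np.ndarray:
    """Binary airway mask from a preprocessed volume.

    The probability field is thresholded with a strict ``>`` (threshold 1.0
    therefore yields an empty mask); by default only the largest
    26-connected component is retained to stabilize downstream meshing.
    """
    v = vol.voxels if isinstance(vol, CTVolume) else np.asarray(vol, np.float32)
    p = model.forward(v[None, None].astype(np.float32), train=False)[0, 0]
    mask = p > threshold
    if largest_component and mask.any():
        lab, n = ndimage.label(mask, structure=np.ones((3, 3, 3)))
        if n > 1:
            sizes = ndimage.sum_labels(mask, lab, index=np.arange(1, n + 1))
            mask = lab == (1 + int(np.argmax(sizes)))
    return mask
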