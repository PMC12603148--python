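"""Multi-view CNN classification of rendered airway surfaces.

Each patient contributes an ordered set of grayscale snapshot views of
their segmented airway tree. Every view passes through a residual 2D
backbone with a 256-unit dense head, dropout and SoftMax; the patient-level
prediction is the arithmetic mean of the per-view SoftMax probabilities,
thresholded on the FBA probability (strict >, so an exact 0.5 tie resolves
to NFBA in favour of specificity).

Two backbones are provided: ``resnet18`` — the standard four-stage
ResNet-18 layout for full-scale use — and ``tiny_resnet``, a two-stage
narrow variant suited to CPU training on phantom cohorts. Pretrained
weights are optional and never required (this package runs offline).

Training follows the recipe: focal loss (gamma 2.0, alpha 0.25), Adam at
1e-4 (desk-scale default 1e-3), 1:1 class-stratified batches, learning rate
x0.1 on a 5-epoch validation-loss plateau, early stop after 10
non-improving epochs, final weights from the best validation-F1 epoch
(earliest on ties).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from lucent import nn
from lucent.segnet import FocalParams

EPS = 1e-7


@dataclass
class AugmentConfig2D:
    """2D view-level augmentation menu."""

    affine_frac: float = 0.10      # rotation (deg*?), translation, zoom, all +/-10%
    occlusion_prob: float = 0.3
    occlusion_radius: tuple[float, float] = (0.05, 0.20)  # fraction of width
    jitter_frac: float = 0.15      # brightness/contrast jitter
    view_dropout_min: int = 1
    view_dropout_max: int = 2
    view_dropout_prob: float = 0.5

    @classmethod
    def disabled(cls) -> "AugmentConfig2D":
        return cls(affine_frac=0.0, occlusion_prob=0.0, jitter_frac=0.0,
                   view_dropout_prob=0.0)


@dataclass
class ClassifierConfig:
    backbone: str = "tiny_resnet"      # or "resnet18"
    pretrained: bool = False
    in_channels: int = 1
    head_units: int = 256
    dropout_p: float = 0.5
    n_classes: int = 2
    input_size: int = 224
    lr0: float = 1e-4
    plateau_factor: float = 0.1
    plateau_patience: int = 5
    batch_size: int = 16
    max_epochs: int = 100
    early_stop_patience: int = 10
    min_rel_improvement: float = 1e-4
    focal: FocalParams = field(default_factory=FocalParams)
    threshold: float = 0.5
    zscore_mean: float = 0.0   # projection-image Z-score constants; identity by
    zscore_sd: float = 1.0     # default, set from training-set render statistics
    view_chunk: int = 32       # views per optimizer step within a patient batch
    bn_momentum: float = 0.2   # faster-converging running stats for short runs
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout_p < 1.0:
            raise ValueError("dropout_p must be in [0, 1)")
        if self.batch_size % 2:
            raise ValueError("batch_size must be even for 1:1 batches")
        if self.lr0 <= 0:
            raise ValueError("lr0 must be > 0")
        if self.backbone not in ("tiny_resnet", "resnet18"):
            raise ValueError(f"unknown backbone {self.backbone!r}")


@dataclass
class PatientPrediction:
    patient_id: str
    per_view_probs: np.ndarray          # (n_views, 2), rows sum to 1
    aggregate_prob: np.ndarray          # (2,), mean of per-view rows
    label_pred: str                     # "FBA" iff aggregate FBA prob > threshold
    label_true: str | None = None


# --------------------------------------------------------------------------
# networks
# --------------------------------------------------------------------------


class _MultiViewNet(nn.Module):
    """Backbone + dense head producing 2-class logits for a batch of views.

    ``tiny_resnet`` keeps the final 8x-downsampled feature map and flattens
    it into the dense head: the truncation signature of an obstructed
    airway is positional (a branch missing at a particular image location),
    and a global average pool would discard exactly that information — a
    from-scratch CPU-scale network cannot afford to re-encode it into
    channels. ``resnet18`` follows the standard four-stage layout
    with global average pooling.
    """

    def __init__(self, cfg: ClassifierConfig, rng: np.random.Generator,
                 dtype=np.float32):
        c = cfg.in_channels
        if cfg.backbone == "tiny_resnet":
            if cfg.input_size % 8:
                raise ValueError("tiny_resnet input_size must be divisible by 8")
            feat = 32 * (cfg.input_size // 8) ** 2
            self.backbone = nn.Sequential(
                nn.Conv2d(c, 8, 3, rng, dtype=dtype), nn.BatchNorm(8, dtype=dtype),
                nn.ReLU(),
                nn.ResBlock2d(8, 16, rng, stride=2, dtype=dtype),
                nn.ResBlock2d(16, 32, rng, stride=2, dtype=dtype),
                nn.MaxPool2d(),
                nn.Flatten(),
            )
        else:  # resnet18: four residual stages of two blocks each
            feat = 512
            layers = [nn.Conv2d(c, 64, 7, rng, stride=2, pad=3, dtype=dtype),
                      nn.BatchNorm(64, dtype=dtype), nn.ReLU(), nn.MaxPool2d()]
            chans = [(64, 64, 1), (64, 64, 1), (64, 128, 2), (128, 128, 1),
                     (128, 256, 2), (256, 256, 1), (256, 512, 2), (512, 512, 1)]
            layers += [nn.ResBlock2d(ci, co, rng, stride=s, dtype=dtype)
                       for ci, co, s in chans]
            layers.append(nn.GlobalAvgPool2d())
            self.backbone = nn.Sequential(*layers)
        self.head = nn.Sequential(
            nn.Dense(feat, cfg.head_units, rng, dtype=dtype), nn.ReLU(),
            nn.Dropout(cfg.dropout_p),
            nn.Dense(cfg.head_units, cfg.n_classes, rng, dtype=dtype),
        )
        self._set_bn_momentum(self, cfg.bn_momentum)

    @classmethod
    def _set_bn_momentum(cls, module, momentum: float) -> None:
        for v in vars(module).values():
            if isinstance(v, nn.BatchNorm):
                v.momentum = momentum
            elif isinstance(v, nn.Module):
                cls._set_bn_momentum(v, momentum)
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, nn.Module):
                        cls._set_bn_momentum(item, momentum)

    def set_dropout_rng(self, rng: np.random.Generator) -> None:
        for layer in self.head.layers:
            if isinstance(layer, nn.Dropout):
                layer.rng = rng

    def forward(self, x, train=True):
        return self.head.forward(self.backbone.forward(x, train), train)

    def backward(self, gy):
        return self.backbone.backward(self.head.backward(gy))


def build_classifier(cfg: ClassifierConfig | None = None,
                     seed: int | None = None) -> _MultiViewNet:
    """Construct a seeded classifier network from its configuration."""
    cfg = cfg or ClassifierConfig()
    if cfg.pretrained:
        raise RuntimeError(
            "pretrained backbone weights are not bundled; this package runs "
            "offline — set pretrained=False (weights can be loaded via "
            "Module.load_state if available locally)")
    seed = cfg.seed if seed is None else seed
    return _MultiViewNet(cfg, np.random.default_rng(np.random.SeedSequence([seed, 0xC1F])))


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def focal_loss_logits(logits: np.ndarray, labels: np.ndarray,
                      params: FocalParams) -> tuple[float, np.ndarray]:
    """Mean focal loss over SoftMax outputs and its gradient w.r.t. logits.

    ``labels`` are 0/1 with 1 = FBA (the alpha-weighted positive class).
    """
    labels = np.asarray(labels, dtype=int)
    probs = softmax(logits.astype(np.float64))
    n = logits.shape[0]
    pt = np.clip(probs[np.arange(n), labels], EPS, 1.0 - EPS)
    at = np.where(labels == 1, params.alpha, 1.0 - params.alpha)
    g = params.gamma
    loss = float(np.mean(-at * (1.0 - pt) ** g * np.log(pt)))
    # dL/dp_t, then through SoftMax: dp_t/dz_j = p_t (delta_tj - p_j)
    dpt = at * (g * (1.0 - pt) ** (g - 1.0) * np.log(pt) - (1.0 - pt) ** g / pt)
    onehot = np.zeros_like(probs)
    onehot[np.arange(n), labels] = 1.0
    dlogits = (dpt * pt)[:, None] * (onehot - probs) / n
    return loss, dlogits.astype(np.float32)


# --------------------------------------------------------------------------
# augmentation and batching
# --------------------------------------------------------------------------


def augment_view(img: np.ndarray, cfg: AugmentConfig2D,
                 rng: np.random.Generator) -> np.ndarray:
    """Random affine (+/-10%), circular occlusion and brightness/contrast
    jitter on one [0,1] grayscale view; a pure function of the rng state."""
    out = np.asarray(img, dtype=np.float32)
    size = out.shape[0]
    if cfg.affine_frac > 0:
        ang = rng.uniform(-10.0, 10.0) * (cfg.affine_frac / 0.10)
        zoom = 1.0 + rng.uniform(-cfg.affine_frac, cfg.affine_frac)
        shift = rng.uniform(-cfg.affine_frac, cfg.affine_frac, 2) * size
        c = np.array(out.shape) / 2.0
        a = np.deg2rad(ang)
        rot = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]]) / zoom
        offset = c - rot @ c + shift
        out = ndimage.affine_transform(out, rot, offset=offset, order=1,
                                       mode="constant", cval=0.0)
    if cfg.occlusion_prob > 0 and rng.random() < cfg.occlusion_prob:
        r = rng.uniform(*cfg.occlusion_radius) * size
        cx, cy = rng.uniform(0, size, 2)
        yy, xx = np.ogrid[:size, :size]
        out = np.where((xx - cx) ** 2 + (yy - cy) ** 2 <= r * r, 0.0, out)
    if cfg.jitter_frac > 0:
        cfac = 1.0 + rng.uniform(-cfg.jitter_frac, cfg.jitter_frac)
        b = rng.uniform(-cfg.jitter_frac, cfg.jitter_frac)
        out = out * cfac + b
    return np.clip(out, 0.0, 1.0).astype(np.float32)


def view_dropout(images: np.ndarray, cfg: AugmentConfig2D,
                 rng: np.random.Generator) -> np.ndarray:
    """Randomly omit 1..2 of the views (training-time only)."""
    n = len(images)
    if n < 3:
        raise ValueError("view_dropout needs at least 3 views")
    if cfg.view_dropout_prob <= 0 or rng.random() >= cfg.view_dropout_prob:
        return images
    k = int(rng.integers(cfg.view_dropout_min, cfg.view_dropout_max + 1))
    k = min(k, n - 1)
    drop = rng.choice(n, size=k, replace=False)
    keep = np.setdiff1d(np.arange(n), drop)
    return images[keep]


def balanced_batches(patient_ids, labels, batch_size: int,
                     rng: np.random.Generator) -> list[list]:
    """Stratified 1:1 mini-batches of patient ids.

    The majority class is sampled without replacement until exhausted; the
    minority class is oversampled with replacement, so every batch holds
    batch_size/2 of each class.
    """
    labels = np.asarray(labels)
    ids = np.asarray(patient_ids, dtype=object)
    pos = ids[labels == 1]
    neg = ids[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    major, minor = (pos, neg) if len(pos) >= len(neg) else (neg, pos)
    half = batch_size // 2
    major = rng.permutation(major)
    n_batches = len(major) // half
    batches = []
    for b in range(n_batches):
        mj = major[b * half:(b + 1) * half]
        mn = rng.choice(minor, size=half, replace=True)
        batch = list(mj) + list(mn)
        rng.shuffle(batch)
        batches.append(batch)
    return batches


# --------------------------------------------------------------------------
# training / inference
# --------------------------------------------------------------------------


def _check_disjoint(a, b, names=("train", "val")) -> None:
    overlap = set(a) & set(b)
    if overlap:
        raise ValueError(f"patient leakage between {names[0]} and {names[1]}: "
                         f"{sorted(overlap)[:5]}")


def predict_patient(model: _MultiViewNet, views: np.ndarray,
                    cfg: ClassifierConfig, patient_id: str = "",
                    label_true: str | None = None) -> PatientPrediction:
    """Patient-level prediction: mean of per-view SoftMax probabilities.

    The complete view set is used (no dropout at inference); the patient is
    called FBA iff the aggregate FBA probability strictly exceeds the
    threshold.
    """
    views = np.asarray(views, dtype=np.float32)
    if len(views) == 0:
        raise ValueError("empty view set")
    x = views[:, None] if views.ndim == 3 else views
    x = (x - cfg.zscore_mean) / cfg.zscore_sd
    probs = softmax(model.forward(x, train=False))
    agg = probs.mean(axis=0)
    label = "FBA" if agg[1] > cfg.threshold else "NFBA"
    return PatientPrediction(patient_id, probs, agg, label, label_true)


def train_classifier(train_items, val_items, cfg: ClassifierConfig | None = None,
                     aug: AugmentConfig2D | None = None,
                     model: _MultiViewNet | None = None,
                     ) -> tuple[_MultiViewNet, dict]:
    """Train the multi-view classifier.

    ``train_items``/``val_items`` are lists of (patient_id, views, label)
    with views a (n_views, H, W) array in [0, 1] and label "FBA"/"NFBA".
    Patient sets must be disjoint (leakage guard). History records per-epoch
    train loss, validation loss, validation F1 and learning rate; the
    plateau rule multiplies the learning rate by ``plateau_factor`` after
    ``plateau_patience`` consecutive non-improving epochs, early stopping
    fires after ``early_stop_patience``, and the returned weights come from
    the best-validation-F1 epoch (earliest on ties).
    """
    cfg = cfg or ClassifierConfig()
    aug = aug if aug is not None else AugmentConfig2D()
    _check_disjoint([t[0] for t in train_items], [t[0] for t in val_items])
    if len(train_items) == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x7C]))
    model = model or build_classifier(cfg)
    model.set_dropout_rng(np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xD0])))
    opt = nn.Adam(model.params(), lr=cfg.lr0)

    by_id = {pid: (np.asarray(v, np.float32), 1 if lab == "FBA" else 0)
             for pid, v, lab in train_items}
    ids = list(by_id)
    labels = np.array([by_id[i][1] for i in ids])

    history = {"train_loss": [], "val_loss": [], "val_f1": [], "lr": []}
    best_f1, best_state = -1.0, None
    best_val_loss = np.inf
    plateau, stall = 0, 0
    for epoch in range(cfg.max_epochs):
        losses = []
        for batch in balanced_batches(ids, labels, cfg.batch_size, rng):
            xs, ys = [], []
            for pid in batch:
                views, lab = by_id[pid]
                views = view_dropout(views, aug, rng)
                for img in views:
                    xs.append(augment_view(img, aug, rng))
                    ys.append(lab)
            x = (np.stack(xs)[:, None] - cfg.zscore_mean) / cfg.zscore_sd
            ys = np.array(ys)
            # one optimizer step per shuffled chunk of views from this
            # class-balanced patient batch
            order = rng.permutation(len(x))
            for c in range(0, len(order), cfg.view_chunk):
                sel = order[c:c + cfg.view_chunk]
                loss, dlogits = focal_loss_logits(model.forward(x[sel], train=True),
                                                  ys[sel], cfg.focal)
                opt.zero_grad()
                model.backward(dlogits)
                opt.step()
                losses.append(loss)
        # validation: loss over all views, F1 at patient level
        vlosses, truths, preds = [], [], []
        for pid, views, lab in val_items:
            x = (np.asarray(views, np.float32)[:, None] - cfg.zscore_mean) / cfg.zscore_sd
            logits = model.forward(x, train=False)
            y = np.full(len(x), 1 if lab == "FBA" else 0)
            vlosses.append(focal_loss_logits(logits, y, cfg.focal)[0])
            pp = predict_patient(model, np.asarray(views, np.float32), cfg, pid, lab)
            truths.append(lab == "FBA")
            preds.append(pp.label_pred == "FBA")
        val_loss = float(np.mean(vlosses)) if vlosses else float("nan")
        truths = np.array(truths)
        preds = np.array(preds)
        tp = int((truths & preds).sum())
        denom = 2 * tp + int((~truths & preds).sum()) + int((truths & ~preds).sum())
        val_f1 = 2.0 * tp / denom if denom > 0 else 0.0

        history["train_loss"].append(float(np.mean(losses)) if losses else float("nan"))
        history["val_loss"].append(val_loss)
        history["val_f1"].append(val_f1)
        history["lr"].append(opt.lr)

        if val_f1 > best_f1:  # strict >: ties keep the earliest epoch
            best_f1, best_state = val_f1, model.state()
        if val_loss < best_val_loss * (1.0 - cfg.min_rel_improvement):
            best_val_loss = val_loss
            plateau, stall = 0, 0
        else:
            plateau += 1
            stall += 1
            if plateau >= cfg.plateau_patience:
                opt.lr *= cfg.plateau_factor
                plateau = 0
            if stall >= cfg.early_stop_patience:
                break
    if best_state is not None:
        model.load_state(best_state)
    return model, history
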