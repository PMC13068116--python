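"""Semantic segmentation of thermal frames into {background, patient, tube, screen}.

A compact UNet-style encoder-decoder (configurable depth and width, skip
connections, 2x2 max-pooling down / nearest-neighbour up) consumes the raw
temperature matrix — standardized per frame — and emits per-pixel class
scores.  Training uses per-pixel categorical cross-entropy with
inverse-frequency class weights, Adam, a seeded 80/20 train/validation split,
and early stopping on validation mean IoU.  An activation threshold for the
foreground decision is selected afterwards by maximizing mean IoU over a grid.

The network runs on the temperature matrix itself, not on a rendered 8-bit
image: the radiometric signal is the input this pipeline trusts.
"""

from __future__ import annotations

import copy
import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np
from skimage.transform import AffineTransform, warp

from . import nn
from .io import LabelMask, ThermalFrame

__all__ = [
    "SegConfig",
    "SegMetrics",
    "SegModel",
    "UNet",
    "augment",
    "train",
    "predict",
    "predict_probs",
    "select_threshold",
    "evaluate",
]

N_CLASSES = 4


@dataclasses.dataclass
class SegConfig:
    encoder_depth: int = 3
    base_channels: int = 16
    classes: int = N_CLASSES
    lr: float = 1e-3
    batch_size: int = 8
    max_epochs: int = 30
    patience: int = 5
    seed: int = 0
    threshold_grid: float = 0.05  # step of the activation-threshold sweep
    val_fraction: float = 0.2
    augment: bool = True

    def __post_init__(self) -> None:
        n_points = int(round(1.0 / self.threshold_grid)) - 1
        if n_points < 10:
            raise ValueError("threshold_grid must divide (0,1) into >= 10 points")


@dataclasses.dataclass
class SegMetrics:
    mean_iou: float
    mean_dice: float
    pixel_accuracy: float
    per_class_iou: dict[int, float]

    def __post_init__(self) -> None:
        for v in (self.mean_iou, self.mean_dice, self.pixel_accuracy,
                  *self.per_class_iou.values()):
            if not 0.0 <= v <= 1.0 + 1e-12:
                raise ValueError(f"metric {v} outside [0, 1]")


# ---------------------------------------------------------------------------
# network
# ---------------------------------------------------------------------------


class UNet:
    """Encoder-decoder with skip connections, built from the NumPy blocks.

    ``encoder_depth`` levels with channel widths ``base * 2**i``; two 3x3
    conv+ReLU per encoder level, 2x2 max-pool between levels, nearest
    upsampling with skip concatenation and three 3x3 conv+ReLU per decoder
    level, 1x1 head to class logits.  Fully convolutional: any input whose
    sides are multiples of ``2**(depth-1)`` works.
    """

    def __init__(self, depth: int, base: int, classes: int, rng: np.random.Generator,
                 dtype=np.float32):
        self.depth, self.base, self.classes = depth, base, classes
        self.dtype = dtype
        ch = [base * 2**i for i in range(depth)]
        self.enc: list[list] = []
        c_in = 1
        for i in range(depth):
            self.enc.append([
                nn.Conv2d(c_in, ch[i], 3, rng, dtype), nn.ReLU(),
                nn.Conv2d(ch[i], ch[i], 3, rng, dtype), nn.ReLU(),
            ])
            c_in = ch[i]
        self.pools = [nn.MaxPool2x2() for _ in range(depth - 1)]
        self.ups = [nn.Upsample2x() for _ in range(depth - 1)]
        self.dec: list[list] = []
        for i in reversed(range(depth - 1)):
            self.dec.append([
                nn.Conv2d(ch[i + 1], ch[i], 3, rng, dtype), nn.ReLU(),
                nn.Conv2d(2 * ch[i], ch[i], 3, rng, dtype), nn.ReLU(),
            ])
        self.head = nn.Conv2d(ch[0], classes, 1, rng, dtype)
        self._skip_channels = ch

    def layers(self):
        for block in self.enc + self.dec:
            yield from block
        yield from self.pools
        yield from self.ups
        yield self.head

    def conv_layers(self):
        return [l for l in self.layers() if isinstance(l, nn.Conv2d)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = x.astype(self.dtype, copy=False)
        skips = []
        for i in range(self.depth):
            for lay in self.enc[i]:
                x = lay.forward(x)
            if i < self.depth - 1:
                skips.append(x)
                x = self.pools[i].forward(x)
        self._concat_split = []
        for j, block in enumerate(self.dec):
            x = self.ups[j].forward(x)
            x = block[1].forward(block[0].forward(x))
            skip = skips[-(j + 1)]
            self._concat_split.append(x.shape[1])
            x = np.concatenate([x, skip], axis=1)
            x = block[3].forward(block[2].forward(x))
        return self.head.forward(x)

    def backward(self, dlogits: np.ndarray) -> None:
        dx = self.head.backward(dlogits)
        dskips: list[np.ndarray | None] = [None] * (self.depth - 1)
        for j in reversed(range(len(self.dec))):
            block = self.dec[j]
            dx = block[2].backward(block[3].backward(dx))
            split = self._concat_split[j]
            dx, dskip = dx[:, :split], dx[:, split:]
            dskips[self.depth - 2 - j] = dskip
            dx = block[0].backward(block[1].backward(dx))
            dx = self.ups[j].backward(dx)
        for i in reversed(range(self.depth)):
            if i < self.depth - 1:
                dx = self.pools[i].backward(dx)
                dx = dx + dskips[i]
            for lay in reversed(self.enc[i]):
                dx = lay.backward(dx)

    def get_state(self) -> list[np.ndarray]:
        out = []
        for lay in self.conv_layers():
            out.extend([lay.w.copy(), lay.b.copy()])
        return out

    def set_state(self, state: list[np.ndarray]) -> None:
        it = iter(state)
        for lay in self.conv_layers():
            lay.w[...] = next(it)
            lay.b[...] = next(it)


@dataclasses.dataclass
class SegModel:
    """A trained network plus everything needed to reapply it."""

    net: UNet
    cfg: SegConfig
    class_weights: np.ndarray
    threshold: float = 0.5
    history: list[dict] = dataclasses.field(default_factory=list)

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        state = {f"p{i}": a for i, a in enumerate(self.net.get_state())}
        meta = {
            "cfg": dataclasses.asdict(self.cfg),
            "threshold": self.threshold,
            "class_weights": self.class_weights.tolist(),
            "history": self.history,
        }
        np.savez(path, meta=json.dumps(meta), **state)
        return path

    @classmethod
    def load(cls, path: str | Path) -> "SegModel":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["meta"]))
            state = [z[f"p{i}"] for i in range(len(z.files) - 1)]
        cfg = SegConfig(**meta["cfg"])
        net = UNet(cfg.encoder_depth, cfg.base_channels, cfg.classes,
                   np.random.default_rng(cfg.seed))
        net.set_state(state)
        return cls(net=net, cfg=cfg, threshold=meta["threshold"],
                   class_weights=np.asarray(meta["class_weights"]),
                   history=meta["history"])


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------


def _augment_arrays(
    temps: np.ndarray,
    labels: np.ndarray,
    rng: np.random.Generator,
    flips: bool = True,
    rotate: bool = True,
    rescale: bool = True,
    brightness: bool = True,
    noise: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    h, w = temps.shape
    if h < 2 or w < 2:
        return temps, labels
    t, m = temps, labels
    if flips:
        if rng.random() < 0.5:
            t, m = t[:, ::-1], m[:, ::-1]
        if rng.random() < 0.5:
            t, m = t[::-1, :], m[::-1, :]
    angle_deg = rng.uniform(-15.0, 15.0) if rotate else 0.0
    scale = rng.uniform(0.9, 1.1) if rescale else 1.0
    if angle_deg != 0.0 or scale != 1.0:
        # one joint affine about the image centre; frame bilinear, mask nearest
        rad = np.deg2rad(angle_deg)
        center = np.array([w / 2.0 - 0.5, h / 2.0 - 0.5])
        tf = (
            AffineTransform(translation=-center)
            + AffineTransform(rotation=rad, scale=(scale, scale))
            + AffineTransform(translation=center)
        )
        t = warp(t, tf.inverse, order=1, mode="edge", preserve_range=True)
        m = warp(m.astype(float), tf.inverse, order=0, mode="constant", cval=0,
                 preserve_range=True).astype(labels.dtype)
    if brightness:
        offset = rng.uniform(-1.0, 1.0)
        gain = rng.uniform(0.9, 1.1)
        t = (t - t.mean()) * gain + t.mean() + offset
    if noise:
        sd = rng.uniform(0.0, 0.3)
        t = t + rng.normal(0.0, sd, size=t.shape)
    return np.ascontiguousarray(t), np.ascontiguousarray(m)


def augment(
    frame: ThermalFrame,
    mask: LabelMask,
    seed: int,
    *,
    flips: bool = True,
    rotate: bool = True,
    rescale: bool = True,
    brightness: bool = True,
    noise: bool = True,
) -> tuple[ThermalFrame, LabelMask]:
    """Sample one augmentation of a frame/mask pair, deterministic in ``seed``.

    Geometric operations (flips, rotation in [-15, 15] degrees, scaling in
    [0.9, 1.1]) are applied identically to the frame (bilinear) and the mask
    (nearest).  Photometric operations — an additive offset in [-1, 1] deg C
    and a contrast gain in [0.9, 1.1] about the frame mean (the thermal
    analogue of brightness/contrast) — and Gaussian noise (sd up to 0.3 deg C)
    touch the frame only.  With every transform disabled the pair is returned
    unchanged.
    """
    if frame.shape != mask.shape:
        raise ValueError("frame and mask must share a shape")
    rng = np.random.default_rng(seed)
    t, m = _augment_arrays(frame.temps, mask.labels, rng, flips=flips, rotate=rotate,
                           rescale=rescale, brightness=brightness, noise=noise)
    return dataclasses.replace(frame, temps=t), LabelMask(labels=m)


# ---------------------------------------------------------------------------
# training and inference
# ---------------------------------------------------------------------------


def _standardize(temps: np.ndarray) -> np.ndarray:
    sd = temps.std()
    return (temps - temps.mean()) / (sd if sd > 1e-6 else 1.0)


def _pad_to(x: np.ndarray, mult: int) -> tuple[np.ndarray, tuple[int, int]]:
    h, w = x.shape[-2:]
    ph = (-h) % mult
    pw = (-w) % mult
    if ph or pw:
        x = np.pad(x, [(0, 0)] * (x.ndim - 2) + [(0, ph), (0, pw)], mode="edge")
    return x, (h, w)


def _class_weights(masks: list[np.ndarray], classes: int) -> np.ndarray:
    counts = np.zeros(classes)
    for m in masks:
        counts += np.bincount(m.ravel(), minlength=classes)[:classes]
    weights = np.zeros(classes)
    present = counts > 0
    if (~present).any():
        missing = np.where(~present)[0].tolist()
        warnings.warn(f"classes {missing} absent from the training set; weight 0")
    weights[present] = counts.sum() / (present.sum() * counts[present])
    return weights


def train(pairs: list[tuple[ThermalFrame, LabelMask]], cfg: SegConfig) -> SegModel:
    """Train the encoder-decoder on frame/mask pairs.

    Splits 80/20 into train/validation (seeded), optimizes weighted
    cross-entropy with Adam, evaluates validation mean IoU after every epoch,
    keeps the best-epoch weights, and stops early after ``cfg.patience``
    epochs without improvement.  Deterministic given ``cfg.seed``.
    """
    if len(pairs) < 8:
        raise ValueError("need at least 8 frame/mask pairs")
    rng = np.random.default_rng(cfg.seed)
    mult = 2 ** (cfg.encoder_depth - 1)

    order = rng.permutation(len(pairs))
    n_val = max(1, int(round(cfg.val_fraction * len(pairs))))
    val_idx, train_idx = order[:n_val], order[n_val:]

    frames = [np.asarray(p[0].filled().temps, dtype=float) for p in pairs]
    masks = [p[1].labels for p in pairs]
    weights = _class_weights([masks[i] for i in train_idx], cfg.classes)

    net = UNet(cfg.encoder_depth, cfg.base_channels, cfg.classes, rng)
    opt = nn.Adam(net.conv_layers(), lr=cfg.lr)

    def batch_arrays(idxs, augment_rng=None):
        xs, ys = [], []
        for i in idxs:
            t, m = frames[i], masks[i]
            if augment_rng is not None:
                t, m = _augment_arrays(t, m, augment_rng)
            t = _standardize(t)
            t, _ = _pad_to(t, mult)
            m, _ = _pad_to(m, mult)
            xs.append(t)
            ys.append(m)
        return np.stack(xs)[:, None], np.stack(ys).astype(int)

    def val_pass():
        x, y = batch_arrays(val_idx)
        logits = net.forward(x)
        loss, _ = nn.weighted_softmax_ce(logits, y, weights)
        pred = logits.argmax(axis=1)
        mious = [
            evaluate(LabelMask(pred[i].astype(np.uint8)), LabelMask(y[i].astype(np.uint8))).mean_iou
            for i in range(len(val_idx))
        ]
        return loss, float(np.mean(mious))

    best_state = net.get_state()
    best_iou = -np.inf
    best_epoch = -1
    history: list[dict] = []
    since_improve = 0
    for epoch in range(cfg.max_epochs):
        perm = rng.permutation(train_idx)
        losses = []
        for start in range(0, len(perm), cfg.batch_size):
            idxs = perm[start:start + cfg.batch_size]
            x, y = batch_arrays(idxs, augment_rng=rng if cfg.augment else None)
            logits = net.forward(x)
            loss, dlogits = nn.weighted_softmax_ce(logits, y, weights)
            opt.zero_grad()
            net.backward(dlogits)
            opt.step()
            losses.append(loss)
        val_loss, val_miou = val_pass()
        history.append({
            "epoch": epoch, "train_loss": float(np.mean(losses)),
            "val_loss": val_loss, "val_mean_iou": val_miou,
        })
        if val_miou > best_iou:
            best_iou = val_miou
            best_state = net.get_state()
            best_epoch = epoch
            since_improve = 0
        else:
            since_improve += 1
            if since_improve >= cfg.patience:
                break

    net.set_state(best_state)
    model = SegModel(net=net, cfg=cfg, class_weights=weights, history=history)
    model.best_epoch = best_epoch  # type: ignore[attr-defined]
    val_pairs = [pairs[i] for i in val_idx]
    model.threshold = select_threshold(model, val_pairs)
    return model


def predict_probs(model: SegModel, frame: ThermalFrame) -> np.ndarray:
    """Per-pixel class probabilities, shape (classes, H, W), summing to 1."""
    mult = 2 ** (model.cfg.encoder_depth - 1)
    x = _standardize(frame.filled().temps.astype(float))
    x, (h, w) = _pad_to(x, mult)
    logits = model.net.forward(x[None, None])
    return nn.softmax(logits, axis=1)[0, :, :h, :w]


def probs_to_mask(probs: np.ndarray, threshold: float) -> LabelMask:
    """Foreground rule: a pixel is foreground when its best foreground-class
    probability reaches ``threshold``; it is then labelled by the argmax over
    foreground classes, otherwise background."""
    fg = probs[1:]
    best = fg.max(axis=0)
    label = fg.argmax(axis=0) + 1
    out = np.where(best >= threshold, label, 0).astype(np.uint8)
    return LabelMask(labels=out)


def predict(model: SegModel, frame: ThermalFrame, threshold: float | None = None) -> LabelMask:
    """Segment a frame; ``threshold`` defaults to the model's selected one."""
    thr = model.threshold if threshold is None else threshold
    if not 0.0 < thr < 1.0:
        raise ValueError(f"threshold must lie in (0, 1), got {thr}")
    return probs_to_mask(predict_probs(model, frame), thr)


def select_threshold(
    model: SegModel, val_pairs: list[tuple[ThermalFrame, LabelMask]],
    grid_step: float | None = None,
) -> float:
    """Activation threshold maximizing mean IoU over the validation pairs.

    Sweeps the grid {step, 2*step, ...} < 1; ties break toward the smaller
    threshold.
    """
    if not val_pairs:
        raise ValueError("need at least one validation pair")
    step = model.cfg.threshold_grid if grid_step is None else grid_step
    thresholds = np.arange(step, 1.0, step)
    thresholds = thresholds[thresholds < 1.0 - 1e-12]
    all_probs = [predict_probs(model, f) for f, _ in val_pairs]
    best_thr, best_iou = float(thresholds[0]), -np.inf
    for thr in thresholds:
        ious = [
            evaluate(probs_to_mask(p, float(thr)), truth).mean_iou
            for p, (_, truth) in zip(all_probs, val_pairs)
        ]
        mean_iou = float(np.mean(ious))
        if mean_iou > best_iou + 1e-12:  # strict: first (smallest) wins ties
            best_iou, best_thr = mean_iou, float(thr)
    return best_thr


def evaluate(pred: LabelMask, truth: LabelMask) -> SegMetrics:
    """IoU, Dice and pixel accuracy between predicted and true masks.

    Per-class IoU is intersection over union of the binary class masks; a
    class absent from both masks is skipped from the means.  Dice is computed
    from the counts directly (and satisfies Dice = 2 IoU / (1 + IoU)).
    """
    if pred.shape != truth.shape:
        raise ValueError("prediction and truth must share a shape")
    p, t = pred.labels, truth.labels
    ious, dices = {}, []
    for c in range(N_CLASSES):
        pm, tm = p == c, t == c
        union = int((pm | tm).sum())
        if union == 0:
            continue
        inter = int((pm & tm).sum())
        ious[c] = inter / union
        dices.append(2 * inter / (pm.sum() + tm.sum()))
    return SegMetrics(
        mean_iou=float(np.mean(list(ious.values()))),
        mean_dice=float(np.mean(dices)),
        pixel_accuracy=float((p == t).mean()),
        per_class_iou=ious,
    )
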