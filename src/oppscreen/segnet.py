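"""Encoder-decoder vertebral-body segmentation network.

Seven-layer (configurable-depth) coding/decoding architecture: the first
``depth-2`` encoder layers each apply a 1x1 convolution (channel mixing /
extra nonlinearity) followed by a 3x3 residual block; all but the first
of them halve the resolution.  The last two encoder layers are plain 2x2
stride-2 convolutions that enlarge the receptive field and reduce the
resolution further.  The decoder mirrors with 2x2 transposed
convolutions; the deepest skip connection is merged by a channel-attention
fusion (concatenate, global average pool, two 1x1 convolutions, sigmoid
weights multiplied onto the skip features and added to the upsampled
features), the shallower skips by plain concatenation + 3x3 convolution.
A final 1x1 convolution maps to the foreground logit.

Images enter in intensity units (mg/cm3-equivalent) and are scaled by
``NORM_SCALE`` before the network.
"""

from __future__ import annotations

import copy
import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage.transform import resize, rotate

from . import nn
from .errors import ConfigurationError, TrainingDivergedError, ValidationError
from .nn import functional as F

__all__ = ["SegModelConfig", "SegTrainConfig", "SegMetrics", "LearningCurve",
           "SegNet", "UNetBaseline", "ChannelAttentionFusion",
           "channel_attention_fuse", "build_segmentation_model",
           "build_unet_baseline", "augment", "apply_transform",
           "train_segmentation", "dsc", "predict_masks", "evaluate_dsc",
           "learning_curve", "save_checkpoint", "load_checkpoint"]

NORM_SCALE = 300.0   # intensity units mapped to ~[0, 1.5] for the networks


@dataclass(frozen=True)
class SegModelConfig:
    depth: int = 7
    base_channels: int = 16
    channel_growth: float = 2.0
    max_channels: int = 256
    attention_reduction: int = 4
    in_channels: int = 1
    out_channels: int = 1

    def __post_init__(self):
        if self.depth < 3:
            raise ConfigurationError("depth must be >= 3")
        if self.base_channels < 1 or self.attention_reduction < 1:
            raise ConfigurationError("invalid channel configuration")

    @classmethod
    def desk(cls, **kw) -> "SegModelConfig":
        kw.setdefault("depth", 5)
        kw.setdefault("base_channels", 8)
        kw.setdefault("max_channels", 32)
        return cls(**kw)

    @property
    def layer_channels(self) -> tuple[int, ...]:
        return tuple(min(int(round(self.base_channels * self.channel_growth ** i)),
                         self.max_channels) for i in range(self.depth))

    def required_divisor(self) -> int:
        return 2 ** (self.depth - 1)

    def validate_input_size(self, size: int) -> None:
        if size % self.required_divisor():
            raise ConfigurationError(
                f"input size {size} not divisible by 2^(depth-1) = "
                f"{self.required_divisor()}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SegModelConfig":
        return cls(**d)


@dataclass(frozen=True)
class SegTrainConfig:
    epochs: int = 500
    batch_size: int = 64
    optimizer: str = "sgd"
    learning_rate: float = 0.001
    momentum: float = 0.9
    augmentation: dict = field(default_factory=lambda: dict(
        flip=True, rotation=True, mirror=True, crop=True))
    loss: str = "dice_bce"
    seed: int = 0
    selection_metric: str = "dsc"

    def __post_init__(self):
        if self.epochs < 1:
            raise ValidationError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValidationError("learning_rate must be > 0")
        if self.optimizer.lower() != "sgd":
            raise ConfigurationError("only the SGD optimizer is supported")

    @classmethod
    def desk(cls, **kw) -> "SegTrainConfig":
        """CPU-scale profile: few epochs compensated by small batches (many
        SGD steps) and heavy momentum at the standard 0.001 learning rate."""
        kw.setdefault("epochs", 15)
        kw.setdefault("batch_size", 2)
        kw.setdefault("momentum", 0.99)
        return cls(**kw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class SegMetrics:
    dsc_mean: float
    dsc_sd: float
    per_image: tuple[float, ...]


@dataclass(frozen=True)
class LearningCurve:
    entries: tuple[tuple[int, float, float], ...]   # (n_train, dsc_mean, dsc_sd)


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

class _ConvBNReLU(nn.Module):
    def __init__(self, cin, cout, kernel, stride, padding, rng):
        super().__init__()
        self.conv = nn.Conv2d(cin, cout, kernel, stride, padding, bias=False, rng=rng)
        self.bn = nn.BatchNorm2d(cout)

    def forward(self, x):
        return F.relu(self.bn(self.conv(x)))


class _ResBlock3x3(nn.Module):
    """Two 3x3 convolutions with an identity (or strided 1x1) shortcut."""

    def __init__(self, ch, stride, rng):
        super().__init__()
        self.conv1 = nn.Conv2d(ch, ch, 3, stride, 1, bias=False, rng=rng)
        self.bn1 = nn.BatchNorm2d(ch)
        self.conv2 = nn.Conv2d(ch, ch, 3, 1, 1, bias=False, rng=rng)
        self.bn2 = nn.BatchNorm2d(ch)
        self.bn2.gamma.data[:] = 0.0   # residual branch starts at identity
        self.proj = None
        if stride != 1:
            self.proj = nn.Conv2d(ch, ch, 1, stride, 0, bias=False, rng=rng)
            self.bn_proj = nn.BatchNorm2d(ch)

    def forward(self, x):
        out = self.bn2(self.conv2(F.relu(self.bn1(self.conv1(x)))))
        skip = x if self.proj is None else self.bn_proj(self.proj(x))
        return F.relu(F.add(out, skip))


class ChannelAttentionFusion(nn.Module):
    """Selective skip fusion: sigmoid channel weights from the pooled
    concatenation reweight the skip (low-level) map before adding it to
    the upsampled (high-level) map."""

    def __init__(self, channels: int, reduction: int, rng):
        super().__init__()
        hidden = max(2 * channels // reduction, 1)
        self.fc1 = nn.Conv2d(2 * channels, hidden, 1, rng=rng)
        self.fc2 = nn.Conv2d(hidden, channels, 1, rng=rng)
        self.channels = channels

    def weights(self, low: nn.Tensor, high: nn.Tensor) -> nn.Tensor:
        cat = F.concat_channels(low, high)
        pooled = F.global_avg_pool(cat)                       # (N, 2C)
        p = nn.Tensor.make(pooled.data[:, :, None, None], (pooled,),
                           lambda g: pooled.accumulate_grad(g[:, :, 0, 0]))
        return F.sigmoid(self.fc2(F.relu(self.fc1(p))))       # (N, C, 1, 1)

    def forward(self, low: nn.Tensor, high: nn.Tensor) -> nn.Tensor:
        if low.shape[2:] != high.shape[2:]:
            raise ValidationError(
                f"spatial mismatch in attention fusion: {low.shape} vs {high.shape}")
        w = self.weights(low, high)
        return F.add(F.channel_scale(w, low), high)


def channel_attention_fuse(fusion: ChannelAttentionFusion,
                           low_level: np.ndarray, high_level: np.ndarray) -> np.ndarray:
    """Apply a fusion module to raw feature-map arrays (N,C,H,W)."""
    with nn.no_grad():
        out = fusion(nn.Tensor(low_level), nn.Tensor(high_level))
    return out.data


class SegNet(nn.Module):
    def __init__(self, config: SegModelConfig, seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        ch = config.layer_channels
        d = config.depth

        # encoder: layers 1..d-2 = 1x1 conv + 3x3 residual block
        self.enc_pre: list[_ConvBNReLU] = []
        self.enc_res: list[_ResBlock3x3] = []
        cin = config.in_channels
        for i in range(d - 2):
            pre = _ConvBNReLU(cin, ch[i], 1, 1, 0, rng)
            res = _ResBlock3x3(ch[i], stride=1 if i == 0 else 2, rng=rng)
            self._modules[f"enc_pre{i}"] = pre
            self._modules[f"enc_res{i}"] = res
            self.enc_pre.append(pre)
            self.enc_res.append(res)
            cin = ch[i]
        # layers d-1, d = 2x2 stride-2 convolutions
        self.enc_tail: list[_ConvBNReLU] = []
        for i in (d - 2, d - 1):
            layer = _ConvBNReLU(cin, ch[i], 2, 2, 0, rng)
            self._modules[f"enc_tail{i}"] = layer
            self.enc_tail.append(layer)
            cin = ch[i]

        # decoder: d-1 upsampling stages; attention fusion at the deepest skip
        self.ups: list[nn.ConvTranspose2d] = []
        self.dec_conv: list[_ConvBNReLU | None] = []
        skip_ch = [ch[i] for i in range(d - 1)]       # skips from layers 1..d-1
        cur = ch[d - 1]
        for j in range(d - 1):
            target = skip_ch[d - 2 - j]
            up = nn.ConvTranspose2d(cur, target, 2, rng=rng)
            self._modules[f"up{j}"] = up
            self.ups.append(up)
            if j == 0:
                self.attention = ChannelAttentionFusion(
                    target, config.attention_reduction, rng)
                self.dec_conv.append(None)
            else:
                conv = _ConvBNReLU(2 * target, target, 3, 1, 1, rng)
                self._modules[f"dec_conv{j}"] = conv
                self.dec_conv.append(conv)
            cur = target
        self.head = nn.Conv2d(cur, config.out_channels, 1, rng=rng)
        # foreground-prior initialisation: vertebral bodies cover ~13% of a
        # slice, so start the output logit at that prior instead of 0.5
        self.head.bias.data[:] = -1.9

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        self.config.validate_input_size(x.shape[2])
        skips = []
        for pre, res in zip(self.enc_pre, self.enc_res):
            x = res(pre(x))
            skips.append(x)
        for layer in self.enc_tail[:-1]:
            x = layer(x)
            skips.append(x)
        x = self.enc_tail[-1](x)
        for j, up in enumerate(self.ups):
            x = up(x)
            skip = skips[len(skips) - 1 - j]
            if j == 0:
                x = self.attention(skip, x)
            else:
                x = self.dec_conv[j](F.concat_channels(skip, x))
        return self.head(x)


def build_segmentation_model(config: SegModelConfig, seed: int = 0) -> SegNet:
    return SegNet(config, seed=seed)


class UNetBaseline(nn.Module):
    """Plain U-Net for comparison: double 3x3 convolutions per level,
    2x2 max-pool downsampling, transposed-convolution upsampling with
    plain concatenation skips.  No residual blocks, no attention."""

    def __init__(self, config: SegModelConfig, seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        ch = config.layer_channels
        d = config.depth

        def double_conv(cin, cout, tag):
            a = _ConvBNReLU(cin, cout, 3, 1, 1, rng)
            b = _ConvBNReLU(cout, cout, 3, 1, 1, rng)
            self._modules[f"{tag}a"] = a
            self._modules[f"{tag}b"] = b
            return (a, b)

        cin = config.in_channels
        self.enc = []
        for i in range(d - 1):
            self.enc.append(double_conv(cin, ch[i], f"enc{i}"))
            cin = ch[i]
        self.bottom = double_conv(cin, ch[d - 1], "bottom")
        self.ups = []
        self.dec = []
        cur = ch[d - 1]
        for j in range(d - 1):
            target = ch[d - 2 - j]
            up = nn.ConvTranspose2d(cur, target, 2, rng=rng)
            self._modules[f"up{j}"] = up
            self.ups.append(up)
            self.dec.append(double_conv(2 * target, target, f"dec{j}"))
            cur = target
        self.head = nn.Conv2d(cur, config.out_channels, 1, rng=rng)
        self.head.bias.data[:] = -1.9

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        if x.shape[2] % (2 ** (self.config.depth - 1)):
            raise ConfigurationError(
                f"input size {x.shape[2]} not divisible by "
                f"2^(depth-1) = {2 ** (self.config.depth - 1)}")
        skips = []
        for a, b in self.enc:
            x = b(a(x))
            skips.append(x)
            x = F.max_pool2d(x, 2, 2, 0)
        a, b = self.bottom
        x = b(a(x))
        for j, up in enumerate(self.ups):
            x = up(x)
            a, b = self.dec[j]
            x = b(a(F.concat_channels(skips[len(skips) - 1 - j], x)))
        return self.head(x)


def build_unet_baseline(config: SegModelConfig, seed: int = 0) -> UNetBaseline:
    """Classic U-Net with the same channel scheme, for baseline comparisons."""
    return UNetBaseline(config, seed=seed)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def dsc(pred: np.ndarray, ref: np.ndarray) -> float:
    """Dice similarity coefficient 2|A&B| / (|A|+|B|); 1.0 if both empty."""
    a = np.asarray(pred)
    b = np.asarray(ref)
    if a.shape != b.shape:
        raise ValidationError(f"mask shape mismatch: {a.shape} vs {b.shape}")
    a = a > 0
    b = b > 0
    sa, sb = int(a.sum()), int(b.sum())
    if sa + sb == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / (sa + sb)


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

def _transform(arr: np.ndarray, params: dict, is_mask: bool) -> np.ndarray:
    order = 0 if is_mask else 1
    out = np.asarray(arr, dtype=np.float64)
    size = out.shape[0]
    if params.get("flip"):
        out = out[::-1, :]
    if params.get("mirror"):
        out = out[:, ::-1]
    angle = params.get("angle", 0.0)
    if angle:
        out = rotate(out, angle, order=order, mode="constant", cval=0.0,
                     preserve_range=True)
    crop = params.get("crop")
    if crop:
        cs, oy, ox = crop
        out = out[oy:oy + cs, ox:ox + cs]
        out = resize(out, (size, size), order=order, mode="edge",
                     preserve_range=True, anti_aliasing=False)
    if is_mask:
        out = (out > 0.5).astype(np.uint8)
    return out


def augment(image: np.ndarray, mask: np.ndarray, switches: dict, seed: int,
            return_params: bool = False):
    """Apply an identical random spatial transform to image and mask.

    Switches: flip (up/down), mirror (left/right), rotation (+-15 deg),
    crop (90-100% area, rescaled back).  Deterministic for a fixed seed.
    """
    image = np.asarray(image)
    mask = np.asarray(mask)
    if image.shape != mask.shape:
        raise ValidationError("image and mask must share a shape")
    rng = np.random.default_rng(seed)
    params: dict = {}
    if switches.get("flip"):
        params["flip"] = bool(rng.uniform() < 0.5)
    if switches.get("mirror"):
        params["mirror"] = bool(rng.uniform() < 0.5)
    if switches.get("rotation"):
        params["angle"] = float(rng.uniform(-15.0, 15.0))
    if switches.get("crop"):
        size = image.shape[0]
        scale = float(rng.uniform(0.9, 1.0))
        cs = max(8, int(round(scale * size)))
        oy = int(rng.integers(0, size - cs + 1))
        ox = int(rng.integers(0, size - cs + 1))
        params["crop"] = (cs, oy, ox)
    img_t = _transform(image, params, is_mask=False)
    msk_t = _transform(mask, params, is_mask=True)
    if return_params:
        return img_t, msk_t, params
    return img_t, msk_t


def apply_transform(arr: np.ndarray, params: dict, is_mask: bool = False) -> np.ndarray:
    """Replay a logged augmentation on another array."""
    return _transform(arr, params, is_mask)


# ---------------------------------------------------------------------------
# training / inference
# ---------------------------------------------------------------------------

def _stack(images: list[np.ndarray]) -> np.ndarray:
    x = np.stack([np.asarray(im, dtype=np.float32) for im in images])
    return (x / NORM_SCALE)[:, None, :, :]


def predict_masks(model: SegNet, images: list[np.ndarray], threshold: float = 0.5,
                  batch_size: int = 8) -> list[np.ndarray]:
    model.eval()
    out: list[np.ndarray] = []
    with nn.no_grad():
        for i in range(0, len(images), batch_size):
            logits = model(nn.Tensor(_stack(images[i:i + batch_size]))).data
            probs = 1.0 / (1.0 + np.exp(-logits[:, 0]))
            out.extend((probs >= threshold).astype(np.uint8))
    return out


def evaluate_dsc(model: SegNet, images: list[np.ndarray],
                 masks: list[np.ndarray]) -> SegMetrics:
    preds = predict_masks(model, images)
    vals = [dsc(p, m) for p, m in zip(preds, masks)]
    return SegMetrics(dsc_mean=float(np.mean(vals)), dsc_sd=float(np.std(vals)),
                      per_image=tuple(vals))


def train_segmentation(train_images, train_masks, tune_images, tune_masks,
                       model_config: SegModelConfig | None = None,
                       cfg: SegTrainConfig | None = None,
                       model: SegNet | None = None):
    """Train the segmentation network; returns (model, history).

    The checkpoint with the best tuning-set mean DSC is restored at the
    end.  Fully deterministic for fixed configs/seed (single-threaded).
    """
    cfg = cfg or SegTrainConfig.desk()
    if not train_images or not tune_images:
        raise ValidationError("training and tuning sets must be non-empty")
    if len(train_images) != len(train_masks):
        raise ValidationError("images/masks length mismatch")
    if model is None:
        model_config = model_config or SegModelConfig.desk()
        model_config.validate_input_size(np.asarray(train_images[0]).shape[0])
        model = SegNet(model_config, seed=cfg.seed)
    opt = nn.SGD(model.parameters(), lr=cfg.learning_rate, momentum=cfg.momentum)
    rng = np.random.default_rng(cfg.seed + 1)
    n = len(train_images)
    history = {"loss": [], "tune_dsc": []}
    best = (-1.0, None)
    any_aug = any(cfg.augmentation.values())
    for epoch in range(cfg.epochs):
        model.train()
        perm = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = perm[start:start + cfg.batch_size]
            imgs, msks = [], []
            for i in idx:
                im, mk = train_images[i], train_masks[i]
                if any_aug:
                    im, mk = augment(im, mk, cfg.augmentation,
                                     seed=int(rng.integers(2 ** 31)))
                imgs.append(im)
                msks.append(mk)
            x = nn.Tensor(_stack(imgs), requires_grad=False)
            y = np.stack([np.asarray(m) > 0 for m in msks])[:, None].astype(np.float32)
            logits = model(x)
            loss = F.dice_bce_loss(logits, y)
            if not np.isfinite(loss.item()):
                raise TrainingDivergedError(
                    f"non-finite loss at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        tune = evaluate_dsc(model, tune_images, tune_masks)
        history["loss"].append(float(np.mean(losses)))
        history["tune_dsc"].append(tune.dsc_mean)
        if tune.dsc_mean > best[0]:
            best = (tune.dsc_mean, copy.deepcopy(model.state_arrays()))
    if best[1] is not None:
        model.load_state_arrays(best[1])
    history["best_tune_dsc"] = best[0]
    return model, history


def learning_curve(pool_images, pool_masks, test_images, test_masks,
                   sizes: list[int], model_config: SegModelConfig,
                   cfg: SegTrainConfig, tune_fraction: float = 0.1) -> LearningCurve:
    """Test DSC after training from scratch on seeded subsamples of the pool.

    Each entry depends only on (configs, size), so repeated sizes give
    identical entries; size == pool size reduces to a plain train/test run.
    """
    pool_n = len(pool_images)
    entries = []
    for size in sizes:
        if size > pool_n:
            raise ValidationError(f"requested size {size} exceeds pool {pool_n}")
        ss = np.random.SeedSequence((cfg.seed, size))
        sub_rng = np.random.default_rng(ss)
        idx = sub_rng.choice(pool_n, size=size, replace=False) \
            if size < pool_n else np.arange(pool_n)
        n_tune = max(1, int(round(tune_fraction * size)))
        tune_idx, train_idx = idx[:n_tune], idx[n_tune:]
        if train_idx.size == 0:
            train_idx = tune_idx
        run_cfg = dataclasses.replace(cfg, seed=int(ss.generate_state(1)[0] % 2 ** 31))
        model, _ = train_segmentation(
            [pool_images[i] for i in train_idx], [pool_masks[i] for i in train_idx],
            [pool_images[i] for i in tune_idx], [pool_masks[i] for i in tune_idx],
            model_config, run_cfg)
        m = evaluate_dsc(model, test_images, test_masks)
        entries.append((int(size), m.dsc_mean, m.dsc_sd))
    return LearningCurve(entries=tuple(entries))


# ---------------------------------------------------------------------------
# checkpoints: .npz weights + JSON sidecar (config, history)
# ---------------------------------------------------------------------------

def save_checkpoint(model: SegNet, history: dict, path: Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path.with_suffix(".npz"), **model.state_arrays())
    sidecar = {"config": model.config.to_dict(), "history": history,
               "kind": "segnet"}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return path.with_suffix(".npz")


def load_checkpoint(path: Path) -> tuple[SegNet, dict]:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    model = SegNet(SegModelConfig.from_dict(sidecar["config"]))
    with np.load(path.with_suffix(".npz")) as state:
        model.load_state_arrays({k: state[k] for k in state.files})
    return model, sidecar.get("history", {})
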