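"""Residual three-class bone-mass classifier.

Model 1 consumes a two-channel fusion feature image (the L1 and L2
segmented vertebral images stacked as channels); model 2 consumes the L1
image alone.  The backbone is a residual network: a 7x7 convolution stem
with 3x3 max-pooling, four residual stages whose unit counts default to
(3, 4, 6, 3) — each stage after the first opens with a projection
("DBlock") unit whose shortcut convolution matches dimensions — then
global average pooling and a fully connected layer to three logits
(normal, osteopenia, osteoporosis).
"""

from __future__ import annotations

import copy
import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage.transform import resize

from . import nn
from .errors import ConfigurationError, TrainingDivergedError, ValidationError
from .evalstats import roc_auc
from .nn import functional as F
from .qct import LABELS
from .segnet import NORM_SCALE

__all__ = ["ClfModelConfig", "ClfTrainConfig", "ResNetClassifier",
           "fuse_features", "build_classifier", "train_classifier",
           "predict_proba", "prepare_input", "save_checkpoint", "load_checkpoint"]

LABEL_TO_INDEX = {lab: i for i, lab in enumerate(LABELS)}

CANONICAL_STAGE_UNITS = (3, 4, 23, 3)   # canonical deep variant


@dataclass(frozen=True)
class ClfModelConfig:
    in_channels: int = 2
    stage_units: tuple[int, int, int, int] = (3, 4, 6, 3)
    base_channels: int = 64
    n_classes: int = 3
    input_size: int = 512

    def __post_init__(self):
        if self.in_channels not in (1, 2):
            raise ConfigurationError("in_channels must be 1 (model 2) or 2 (model 1)")
        if self.n_classes != 3:
            raise ConfigurationError("the screening task has exactly 3 classes")
        if any(u < 1 for u in self.stage_units):
            raise ConfigurationError("each stage needs at least one residual unit")

    @classmethod
    def desk(cls, **kw) -> "ClfModelConfig":
        kw.setdefault("base_channels", 8)
        kw.setdefault("input_size", 96)
        return cls(**kw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stage_units"] = list(self.stage_units)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ClfModelConfig":
        d = dict(d)
        d["stage_units"] = tuple(d["stage_units"])
        return cls(**d)


@dataclass(frozen=True)
class ClfTrainConfig:
    epochs: int = 15
    batch_size: int = 16
    optimizer: str = "sgd"
    learning_rate: float = 0.001
    momentum: float = 0.9
    class_weighting: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1:
            raise ValidationError("epochs and batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValidationError("learning_rate must be > 0")
        if self.optimizer.lower() != "sgd":
            raise ConfigurationError("only the SGD optimizer is supported")

    @classmethod
    def desk(cls, **kw) -> "ClfTrainConfig":
        """CPU-scale profile: heavier momentum compensates the short
        epoch budget at the standard 0.001 learning rate."""
        kw.setdefault("momentum", 0.99)
        return cls(**kw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def fuse_features(l1_roi: np.ndarray, l2_roi: np.ndarray) -> np.ndarray:
    """Stack the L1 and L2 vertebral images as channels, order (L1, L2)."""
    a = np.asarray(l1_roi)
    b = np.asarray(l2_roi)
    if a.shape != b.shape:
        raise ValidationError(f"L1 {a.shape} and L2 {b.shape} sizes differ")
    return np.stack([a, b], axis=0)


def prepare_input(slice_: np.ndarray, mask: np.ndarray | None,
                  input_size: int) -> np.ndarray:
    """Mask out the background (if a mask is given) and resize to the
    classifier's input size; intensities stay in mg/cm3-equivalent units."""
    arr = np.asarray(slice_, dtype=np.float64)
    if mask is not None:
        m = np.asarray(mask) > 0
        if m.shape != arr.shape:
            raise ValidationError("slice/mask shape mismatch")
        arr = arr * m
    if arr.shape != (input_size, input_size):
        arr = resize(arr, (input_size, input_size), order=1, mode="edge",
                     preserve_range=True, anti_aliasing=False)
    return arr


class _Block(nn.Module):
    """Residual unit: 3x3 conv, 3x3 conv, 1x1 conv + shortcut.

    A projection variant ("DBlock") carries a strided 1x1 convolution in
    the shortcut so dimensions match when the stage changes width or
    resolution.
    """

    def __init__(self, cin, cout, stride, rng):
        super().__init__()
        self.conv1 = nn.Conv2d(cin, cout, 3, stride, 1, bias=False, rng=rng)
        self.bn1 = nn.BatchNorm2d(cout)
        self.conv2 = nn.Conv2d(cout, cout, 3, 1, 1, bias=False, rng=rng)
        self.bn2 = nn.BatchNorm2d(cout)
        self.conv3 = nn.Conv2d(cout, cout, 1, 1, 0, bias=False, rng=rng)
        self.bn3 = nn.BatchNorm2d(cout)
        self.bn3.gamma.data[:] = 0.0   # residual branch starts at identity
        self.proj = None
        if stride != 1 or cin != cout:
            self.proj = nn.Conv2d(cin, cout, 1, stride, 0, bias=False, rng=rng)
            self.bn_proj = nn.BatchNorm2d(cout)

    def forward(self, x):
        out = F.relu(self.bn1(self.conv1(x)))
        out = F.relu(self.bn2(self.conv2(out)))
        out = self.bn3(self.conv3(out))
        skip = x if self.proj is None else self.bn_proj(self.proj(x))
        return F.relu(F.add(out, skip))


class ResNetClassifier(nn.Module):
    def __init__(self, config: ClfModelConfig, seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        base = config.base_channels
        self.stem_conv = nn.Conv2d(config.in_channels, base, 7, 2, 3,
                                   bias=False, rng=rng)
        self.stem_bn = nn.BatchNorm2d(base)
        self.blocks: list[_Block] = []
        cin = base
        for s, units in enumerate(config.stage_units):
            width = base * (2 ** s)
            for u in range(units):
                stride = 2 if (s > 0 and u == 0) else 1
                blk = _Block(cin, width, stride, rng)
                self._modules[f"stage{s}_unit{u}"] = blk
                self.blocks.append(blk)
                cin = width
        self.fc = nn.Linear(cin, config.n_classes, rng=rng)

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        x = F.relu(self.stem_bn(self.stem_conv(x)))
        x = F.max_pool2d(x, 3, 2, 1)
        for blk in self.blocks:
            x = blk(x)
        x = F.global_avg_pool(x)
        return self.fc(x)


def build_classifier(config: ClfModelConfig, seed: int = 0) -> ResNetClassifier:
    return ResNetClassifier(config, seed=seed)


def _softmax(z: np.ndarray) -> np.ndarray:
    zs = z - z.max(axis=1, keepdims=True)
    ez = np.exp(zs)
    return ez / ez.sum(axis=1, keepdims=True)


def _forward_proba(model: ResNetClassifier, batch: np.ndarray) -> np.ndarray:
    model.eval()
    with nn.no_grad():
        logits = model(nn.Tensor(batch)).data
    return _softmax(logits)


def predict_proba(model: ResNetClassifier, l1: np.ndarray,
                  l2: np.ndarray | None = None,
                  variant: str = "model2") -> np.ndarray:
    """Class probabilities (normal, osteopenia, osteoporosis) for one subject.

    ``model1`` fuses L1+L2 as channels; ``model2`` uses L1 alone and
    ignores any L2 argument.
    """
    if variant not in ("model1", "model2"):
        raise ValidationError(f"unknown variant {variant!r}")
    if variant == "model1":
        if l2 is None:
            raise ValidationError("model1 requires both L1 and L2 images")
        if model.config.in_channels != 2:
            raise ValidationError("model was not built with in_channels=2")
        x = fuse_features(l1, l2)[None]
    else:
        if model.config.in_channels != 1:
            raise ValidationError("model was not built with in_channels=1")
        x = np.asarray(l1)[None, None]
    return _forward_proba(model, np.asarray(x, dtype=np.float32) / NORM_SCALE)[0]


def predict_proba_batch(model: ResNetClassifier, inputs: list[np.ndarray],
                        batch_size: int = 32) -> np.ndarray:
    """Probabilities for a list of (C,H,W) input arrays (intensity units)."""
    out = []
    for i in range(0, len(inputs), batch_size):
        batch = np.stack([np.asarray(a, dtype=np.float32) for a in
                          inputs[i:i + batch_size]]) / NORM_SCALE
        out.append(_forward_proba(model, batch))
    return np.concatenate(out, axis=0)


def _macro_ovr_auc(probs: np.ndarray, y: np.ndarray) -> float:
    aucs = []
    for k in range(probs.shape[1]):
        if len(np.unique(y == k)) == 2:
            aucs.append(roc_auc(probs[:, k], (y == k).astype(int)))
    return float(np.mean(aucs)) if aucs else float("nan")


def train_classifier(train_inputs, train_labels, val_inputs, val_labels,
                     model_config: ClfModelConfig | None = None,
                     cfg: ClfTrainConfig | None = None,
                     model: ResNetClassifier | None = None):
    """Train the residual classifier; returns (model, history).

    Inputs are (C,H,W) arrays in intensity units; labels are class names
    or indices.  Cross-entropy with optional inverse-frequency class
    weights; the checkpoint with the best validation macro one-vs-rest
    AUC is restored.
    """
    cfg = cfg or ClfTrainConfig()
    y_train = np.array([LABEL_TO_INDEX.get(l, l) for l in train_labels], dtype=int)
    y_val = np.array([LABEL_TO_INDEX.get(l, l) for l in val_labels], dtype=int)
    present = np.unique(y_train)
    if present.size < 3:
        missing = [LABELS[k] for k in range(3) if k not in present]
        raise ValidationError(f"class(es) absent from the training set: {missing}")
    if model is None:
        model_config = model_config or ClfModelConfig.desk()
        model = ResNetClassifier(model_config, seed=cfg.seed)
    weights = None
    if cfg.class_weighting:
        freq = np.bincount(y_train, minlength=3).astype(np.float64)
        weights = (y_train.size / (3.0 * freq)).astype(np.float32)
    opt = nn.SGD(model.parameters(), lr=cfg.learning_rate, momentum=cfg.momentum)
    rng = np.random.default_rng(cfg.seed + 1)
    n = len(train_inputs)
    xs = [np.asarray(a, dtype=np.float32) / NORM_SCALE for a in train_inputs]
    history = {"loss": [], "val_macro_auc": []}
    best = (-1.0, None)
    for epoch in range(cfg.epochs):
        model.train()
        perm = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = perm[start:start + cfg.batch_size]
            if idx.size < 2:
                continue   # batch-norm needs more than one sample
            x = nn.Tensor(np.stack([xs[i] for i in idx]))
            logits = model(x)
            loss = F.cross_entropy(logits, y_train[idx], class_weights=weights)
            if not np.isfinite(loss.item()):
                raise TrainingDivergedError(f"non-finite loss at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        probs = predict_proba_batch(model, val_inputs)
        mauc = _macro_ovr_auc(probs, y_val)
        history["loss"].append(float(np.mean(losses)))
        history["val_macro_auc"].append(mauc)
        if np.isfinite(mauc) and mauc > best[0]:
            best = (mauc, copy.deepcopy(model.state_arrays()))
    if best[1] is not None:
        model.load_state_arrays(best[1])
    history["best_val_macro_auc"] = best[0]
    return model, history


def save_checkpoint(model: ResNetClassifier, history: dict, path: Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path.with_suffix(".npz"), **model.state_arrays())
    sidecar = {"config": model.config.to_dict(), "history": history,
               "kind": "classifier"}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return path.with_suffix(".npz")


def load_checkpoint(path: Path) -> tuple[ResNetClassifier, dict]:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    model = ResNetClassifier(ClfModelConfig.from_dict(sidecar["config"]))
    with np.load(path.with_suffix(".npz")) as state:
        model.load_state_arrays({k: state[k] for k in state.files})
    return model, sidecar.get("history", {})
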