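"""Learnable components: 1D spectral DNN, 2D patch CNN, and a
fully-convolutional parenchyma segmenter, plus patch extraction,
dihedral augmentation, and class balancing.

Architectures follow the intraoperative classification study:

* **1D-DNN** — per-pixel spectrum classifier, 128 -> 28 -> 40 -> K with
  ReLU hidden activations and softmax output; SGD, learning rate 0.1,
  45 (binary) / 40 (multiclass) epochs.
* **2D-CNN** — 11x11xB patch classifier: three 3x3 'same' convolutions
  (64, 92, 128 filters) with sigmoid activations and 40% dropout, one
  3x3 'valid' average pool (11 -> 9, flatten 9*9*128 = 10368), a 1000-wide
  fully-connected layer, and a softmax head; AdaDelta with learning rate
  1.0, batches of 12 patches augmented in-batch to 96 by the dihedral
  group.  A binary variant of the same topology, on 41x41 single-channel
  grayscale patches, detects blood vessels (its layer widths are
  configurable; the study does not print a table for the vessel net, and
  the default uses narrower layers sized for a net meant to run in real
  time).
* **Parenchyma net** — a depth-3 U-Net-style encoder/decoder with skip
  connections on the grayscale image, sigmoid per-pixel foreground
  output, trained on masks augmented by the same factor of eight.

Training is fully seeded; the cross-entropy losses are the conventional
choice (the study does not name its loss).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from hsibrain import _nn
from hsibrain._nn import (
    AdaDelta,
    AvgPool3x3Valid,
    Conv2D,
    Dense,
    Dropout,
    Flatten,
    MaxPool2x2,
    ReLU,
    SGD,
    Sequential,
    Sigmoid,
    Upsample2x,
    sigmoid_bce,
    softmax,
    softmax_cross_entropy,
)
from hsibrain.preprocess import ProcessedCube

__all__ = [
    "TrainConfig",
    "ProbabilityCube",
    "extract_patches",
    "augment_batch",
    "balance_classes",
    "Dnn1DModel",
    "train_dnn1d",
    "predict_dnn1d",
    "Cnn2DModel",
    "train_cnn2d",
    "predict_cnn2d",
    "ParenchymaModel",
    "train_parenchyma_net",
    "predict_parenchyma",
]


@dataclass
class TrainConfig:
    """Hyperparameters of one training run (defaults = multiclass 1D-DNN)."""

    learning_rate: float = 0.1
    epochs: int = 40
    batch_size: int = 12
    optimizer_name: str = "sgd"  # "sgd" | "adadelta"
    dropout_rate: float = 0.0
    patch_size: int = 11
    seed: int = 0
    # architecture knobs (2D-CNN / parenchyma net)
    conv_filters: tuple[int, int, int] = (64, 92, 128)
    fc_width: int = 1000
    conv_activation: str = "sigmoid"  # the printed choice; "relu" available
    base_filters: int = 16  # parenchyma net encoder width

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.patch_size % 2 == 0:
            raise ValueError("patch_size must be odd")


@dataclass
class ProbabilityCube:
    """Per-pixel class probabilities, ``(rows, cols, n_classes)``."""

    probs: np.ndarray
    classes: np.ndarray  # class codes aligned with the last axis

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        sums = self.probs.sum(axis=2)
        if not np.allclose(sums, 1.0, atol=1e-5):
            raise ValueError("per-pixel probabilities must sum to 1")

    def argmax_map(self) -> np.ndarray:
        """Class-coded 2-D map of the per-pixel most probable class."""
        return np.asarray(self.classes)[self.probs.argmax(axis=2)]


# ---------------------------------------------------------------------------
# Patch machinery
# ---------------------------------------------------------------------------


def extract_patches(image: np.ndarray, centers: np.ndarray, size: int) -> np.ndarray:
    """size x size windows centered on each (row, col); reflect-padded borders."""
    if size % 2 == 0:
        raise ValueError("patch size must be odd")
    image = np.asarray(image)
    centers = np.atleast_2d(np.asarray(centers, dtype=int))
    rows, cols = image.shape[:2]
    if (
        (centers[:, 0] < 0).any()
        or (centers[:, 0] >= rows).any()
        or (centers[:, 1] < 0).any()
        or (centers[:, 1] >= cols).any()
    ):
        raise ValueError("patch center outside image")
    half = size // 2
    pad = [(half, half), (half, half)] + [(0, 0)] * (image.ndim - 2)
    padded = np.pad(image, pad, mode="reflect")
    return np.stack(
        [padded[r : r + size, c : c + size] for r, c in centers]
    )


def _dihedral(patch: np.ndarray) -> list[np.ndarray]:
    out = []
    for k in range(4):
        rot = np.rot90(patch, k)
        out.append(rot)
        out.append(rot[::-1])  # vertical mirror
    return out


def augment_batch(patches: np.ndarray) -> np.ndarray:
    """All 8 dihedral variants (rotations x vertical mirror) of each patch.

    A batch of 12 training patches becomes 96 (800% augmentation).
    """
    patches = np.asarray(patches)
    if patches.shape[1] != patches.shape[2]:
        raise ValueError("augmentation requires square patches")
    return np.stack([v for p in patches for v in _dihedral(p)])


def balance_classes(
    samples_by_class: dict[int, np.ndarray], rng: np.random.Generator | int | None = None
) -> dict[int, np.ndarray]:
    """Random subsample (without replacement) of every class down to the
    smallest class count."""
    rng = np.random.default_rng(rng)
    if any(len(v) == 0 for v in samples_by_class.values()):
        raise ValueError("every class needs at least one sample")
    m = min(len(v) for v in samples_by_class.values())
    out = {}
    for c, v in sorted(samples_by_class.items()):
        v = np.asarray(v)
        out[c] = v[rng.choice(len(v), size=m, replace=False)]
    return out


# ---------------------------------------------------------------------------
# 1D spectral DNN
# ---------------------------------------------------------------------------


@dataclass
class Dnn1DModel:
    net: Sequential
    classes: np.ndarray
    n_bands: int
    config: TrainConfig

    def predict_proba(self, spectra: np.ndarray) -> np.ndarray:
        spectra = np.asarray(spectra, dtype=np.float32)
        if spectra.shape[1] != self.n_bands:
            raise ValueError(
                f"spectra have {spectra.shape[1]} bands, model expects {self.n_bands}"
            )
        return softmax(self.net.forward(spectra)).astype(float)

    def weights_hash(self) -> str:
        return _nn.weights_hash(self.net.params())


def _make_optimizer(name: str, params, lr: float):
    if name == "sgd":
        return SGD(params, lr)
    if name == "adadelta":
        return AdaDelta(params, lr)
    raise ValueError(f"unknown optimizer {name!r}")


def train_dnn1d(
    spectra: np.ndarray, labels: np.ndarray, config: TrainConfig | None = None
) -> Dnn1DModel:
    """Train the spectral classifier (two hidden layers, 28 and 40 ReLU nodes)."""
    cfg = config or TrainConfig(batch_size=128)
    spectra = np.asarray(spectra, dtype=np.float32)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("need at least two classes")
    y = np.searchsorted(classes, labels)
    n_bands = spectra.shape[1]
    rng = np.random.default_rng([cfg.seed, 11])
    net = Sequential(
        [
            Dense(n_bands, 28, rng),
            ReLU(),
            Dense(28, 40, rng),
            ReLU(),
            Dense(40, classes.size, rng),
        ]
    )
    opt = _make_optimizer(cfg.optimizer_name, net.params(), cfg.learning_rate)
    batch_rng = np.random.default_rng([cfg.seed, 12])
    n = spectra.shape[0]
    # At the printed learning rate (0.1) small batches make plain SGD prone
    # to dying-ReLU collapse; a wide batch keeps the gradient estimate tame.
    bs = cfg.batch_size
    for _ in range(cfg.epochs):
        order = batch_rng.permutation(n)
        for start in range(0, n, bs):
            idx = order[start : start + bs]
            logits = net.forward(spectra[idx], train=True)
            _, dlogits = softmax_cross_entropy(logits, y[idx])
            net.backward(dlogits)
            opt.step()
    return Dnn1DModel(net=net, classes=classes, n_bands=n_bands, config=cfg)


def predict_dnn1d(model: Dnn1DModel, cube: ProcessedCube) -> ProbabilityCube:
    """Classify every pixel spectrum of a processed cube."""
    rows, cols, bands = cube.shape
    probs = model.predict_proba(cube.data.reshape(-1, bands))
    return ProbabilityCube(probs.reshape(rows, cols, -1), model.classes)


# ---------------------------------------------------------------------------
# 2D patch CNN
# ---------------------------------------------------------------------------


@dataclass
class Cnn2DModel:
    net: Sequential
    classes: np.ndarray
    patch_size: int
    n_channels: int
    mean: float
    std: float
    config: TrainConfig

    def predict_proba(self, patches: np.ndarray) -> np.ndarray:
        patches = np.asarray(patches, dtype=np.float32)
        if patches.ndim == 3:
            patches = patches[..., None]
        if patches.shape[1:] != (self.patch_size, self.patch_size, self.n_channels):
            raise ValueError(
                f"patch geometry {patches.shape[1:]} does not match "
                f"({self.patch_size}, {self.patch_size}, {self.n_channels})"
            )
        x = (patches - self.mean) / self.std
        return softmax(self.net.forward(x)).astype(float)

    def weights_hash(self) -> str:
        return _nn.weights_hash(self.net.params())


def build_cnn2d(
    patch_size: int, n_channels: int, n_classes: int, cfg: TrainConfig
) -> Sequential:
    """Three 'same' convolutions + 3x3 'valid' average pool + FC head.

    With the default widths and an 11x11x128 input the flattened pool
    output is 9*9*128 = 10368 features.
    """
    rng = np.random.default_rng([cfg.seed, 21])
    drop_rng = np.random.default_rng([cfg.seed, 22])
    act = Sigmoid if cfg.conv_activation == "sigmoid" else ReLU
    f1, f2, f3 = cfg.conv_filters
    layers: list = []
    for c_in, c_out in ((n_channels, f1), (f1, f2), (f2, f3)):
        layers += [Conv2D(c_in, c_out, rng), act(), Dropout(cfg.dropout_rate, drop_rng)]
    layers += [AvgPool3x3Valid(), Flatten()]
    flat = (patch_size - 2) ** 2 * f3
    layers += [Dense(flat, cfg.fc_width, rng), ReLU(), Dense(cfg.fc_width, n_classes, rng)]
    return Sequential(layers)


def train_cnn2d(
    patches: np.ndarray, labels: np.ndarray, config: TrainConfig | None = None
) -> Cnn2DModel:
    """Train the patch CNN; every batch is augmented 8x before the update."""
    cfg = config or TrainConfig(
        optimizer_name="adadelta", learning_rate=1.0, dropout_rate=0.4, epochs=50
    )
    patches = np.asarray(patches, dtype=np.float32)
    if patches.ndim == 3:
        patches = patches[..., None]
    n, ph, pw, ch = patches.shape
    if ph != pw:
        raise ValueError("patches must be square")
    labels = np.asarray(labels)
    classes = np.unique(labels)
    y = np.searchsorted(classes, labels)

    mean = float(patches.mean())
    std = float(patches.std()) or 1.0
    x = (patches - mean) / std

    net = build_cnn2d(ph, ch, classes.size, cfg)
    opt = _make_optimizer(cfg.optimizer_name, net.params(), cfg.learning_rate)
    batch_rng = np.random.default_rng([cfg.seed, 23])
    for _ in range(cfg.epochs):
        order = batch_rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb = augment_batch(x[idx])
            yb = np.repeat(y[idx], 8)
            logits = net.forward(xb, train=True)
            _, dlogits = softmax_cross_entropy(logits, yb)
            net.backward(dlogits)
            opt.step()
    return Cnn2DModel(
        net=net,
        classes=classes,
        patch_size=ph,
        n_channels=ch,
        mean=mean,
        std=std,
        config=cfg,
    )


def predict_cnn2d(
    model: Cnn2DModel, image: np.ndarray, batch_size: int = 256
) -> np.ndarray:
    """Per-pixel class probabilities by sliding the patch CNN over an image."""
    rows, cols = image.shape[:2]
    centers = np.argwhere(np.ones((rows, cols), dtype=bool))
    probs = np.empty((rows * cols, model.classes.size))
    for start in range(0, len(centers), batch_size):
        chunk = centers[start : start + batch_size]
        patches = extract_patches(image, chunk, model.patch_size)
        probs[start : start + len(chunk)] = model.predict_proba(patches)
    return probs.reshape(rows, cols, -1)


# ---------------------------------------------------------------------------
# Parenchyma segmenter (U-Net-style encoder/decoder)
# ---------------------------------------------------------------------------


class _UNet:
    """Depth-3 encoder/decoder with skip connections, one 3x3 conv per block."""

    def __init__(self, base_filters: int, rng: np.random.Generator):
        f = base_filters
        self.e1 = [Conv2D(1, f, rng), ReLU()]
        self.e2 = [Conv2D(f, 2 * f, rng), ReLU()]
        self.bott = [Conv2D(2 * f, 4 * f, rng), ReLU()]
        self.d2 = [Conv2D(6 * f, 2 * f, rng), ReLU()]
        self.d1 = [Conv2D(3 * f, f, rng), ReLU()]
        self.out = Conv2D(f, 1, rng, k=1)
        self.pool1, self.pool2 = MaxPool2x2(), MaxPool2x2()
        self.up2, self.up1 = Upsample2x(), Upsample2x()
        self.f = f

    def _blocks(self):
        return [*self.e1, *self.e2, *self.bott, *self.d2, *self.d1, self.out]

    def params(self):
        return [p for layer in self._blocks() for p in layer.params()]

    @staticmethod
    def _run(block, x, train):
        for layer in block:
            x = layer.forward(x, train)
        return x

    @staticmethod
    def _back(block, dy):
        for layer in reversed(block):
            dy = layer.backward(dy)
        return dy

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        a1 = self._run(self.e1, x.astype(np.float32), train)
        a2 = self._run(self.e2, self.pool1.forward(a1, train), train)
        b = self._run(self.bott, self.pool2.forward(a2, train), train)
        u2 = np.concatenate([self.up2.forward(b, train), a2], axis=3)
        c2 = self._run(self.d2, u2, train)
        u1 = np.concatenate([self.up1.forward(c2, train), a1], axis=3)
        c1 = self._run(self.d1, u1, train)
        return self.out.forward(c1, train)  # logits

    def backward(self, dy: np.ndarray) -> None:
        f = self.f
        dc1 = self.out.backward(dy)
        du1 = self._back(self.d1, dc1)
        dc2 = self.up1.backward(du1[..., : 2 * f])
        da1_skip = du1[..., 2 * f :]
        du2 = self._back(self.d2, dc2)
        db = self.up2.backward(du2[..., : 4 * f])
        da2_skip = du2[..., 4 * f :]
        da2 = self.pool2.backward(self._back(self.bott, db)) + da2_skip
        da1 = self.pool1.backward(self._back(self.e2, da2)) + da1_skip
        self._back(self.e1, da1)


@dataclass
class ParenchymaModel:
    net: _UNet
    mean: float
    std: float
    config: TrainConfig

    def weights_hash(self) -> str:
        return _nn.weights_hash(self.net.params())


def train_parenchyma_net(
    gray_images: np.ndarray, masks: np.ndarray, config: TrainConfig | None = None
) -> ParenchymaModel:
    """Train the foreground segmenter on (image, binary mask) pairs.

    The training set is augmented by exactly a factor of eight (dihedral
    rotations and reflections) before seeded mini-batch training with
    binary cross-entropy.  Images must be square with side divisible by 4
    (two 2x pooling stages).
    """
    cfg = config or TrainConfig(epochs=34, optimizer_name="adadelta", learning_rate=1.0)
    gray_images = np.asarray(gray_images, dtype=np.float32)
    masks = np.asarray(masks, dtype=np.float32)
    if gray_images.shape != masks.shape:
        raise ValueError("images and masks must have the same shape")
    if gray_images.shape[1] % 4 or gray_images.shape[2] % 4:
        raise ValueError("image side must be divisible by 4")

    x = augment_batch(gray_images)
    t = augment_batch(masks)
    mean = float(x.mean())
    std = float(x.std()) or 1.0
    x = (x - mean) / std

    rng = np.random.default_rng([cfg.seed, 31])
    net = _UNet(cfg.base_filters, rng)
    opt = _make_optimizer(cfg.optimizer_name, net.params(), cfg.learning_rate)
    batch_rng = np.random.default_rng([cfg.seed, 32])
    n = x.shape[0]
    bs = max(2, cfg.batch_size // 3)
    for _ in range(cfg.epochs):
        order = batch_rng.permutation(n)
        for start in range(0, n, bs):
            idx = order[start : start + bs]
            logits = net.forward(x[idx][..., None], train=True)
            _, dlogits = sigmoid_bce(logits, t[idx][..., None])
            net.backward(dlogits)
            opt.step()
    return ParenchymaModel(net=net, mean=mean, std=std, config=cfg)


def predict_parenchyma(model: ParenchymaModel, gray: np.ndarray) -> np.ndarray:
    """Per-pixel foreground probability in [0, 1]."""
    x = (np.asarray(gray, dtype=np.float32) - model.mean) / model.std
    logits = model.net.forward(x[None, ..., None])
    return (1.0 / (1.0 + np.exp(-logits)))[0, :, :, 0].astype(float)


# ---------------------------------------------------------------------------
# Checkpoints: single-file archives with architecture + weights
# ---------------------------------------------------------------------------

import dataclasses as _dc
import json as _json


def save_model(model, path) -> None:
    """Serialize any of the three model types to a single ``.npz`` archive."""
    if isinstance(model, Dnn1DModel):
        kind, net = "dnn1d", model.net
        meta = {"classes": model.classes.tolist(), "n_bands": model.n_bands}
    elif isinstance(model, Cnn2DModel):
        kind, net = "cnn2d", model.net
        meta = {
            "classes": model.classes.tolist(),
            "patch_size": model.patch_size,
            "n_channels": model.n_channels,
            "mean": model.mean,
            "std": model.std,
        }
    elif isinstance(model, ParenchymaModel):
        kind, net = "parenchyma", model.net
        meta = {"mean": model.mean, "std": model.std}
    else:
        raise TypeError(f"cannot serialize {type(model).__name__}")
    params = net.params()
    arrays = {f"p{i}": p.value for i, p in enumerate(params)}
    header = _json.dumps(
        {"kind": kind, "meta": meta, "config": _dc.asdict(model.config)}
    )
    np.savez(path, header=np.frombuffer(header.encode(), dtype=np.uint8), **arrays)


def load_model(path):
    with np.load(path) as archive:
        header = _json.loads(bytes(archive["header"]).decode())
        weights = [archive[f"p{i}"] for i in range(len(archive.files) - 1)]
    cfg_d = header["config"]
    cfg_d["conv_filters"] = tuple(cfg_d["conv_filters"])
    cfg = TrainConfig(**cfg_d)
    meta = header["meta"]
    kind = header["kind"]
    rng = np.random.default_rng(0)
    if kind == "dnn1d":
        net = Sequential(
            [
                Dense(meta["n_bands"], 28, rng),
                ReLU(),
                Dense(28, 40, rng),
                ReLU(),
                Dense(40, len(meta["classes"]), rng),
            ]
        )
        model = Dnn1DModel(net, np.array(meta["classes"]), meta["n_bands"], cfg)
    elif kind == "cnn2d":
        net = build_cnn2d(meta["patch_size"], meta["n_channels"], len(meta["classes"]), cfg)
        model = Cnn2DModel(
            net,
            np.array(meta["classes"]),
            meta["patch_size"],
            meta["n_channels"],
            meta["mean"],
            meta["std"],
            cfg,
        )
    elif kind == "parenchyma":
        net = _UNet(cfg.base_filters, rng)
        model = ParenchymaModel(net, meta["mean"], meta["std"], cfg)
    else:
        raise ValueError(f"unknown checkpoint kind {kind!r}")
    params = net.params()
    if len(params) != len(weights):
        raise ValueError("checkpoint weight count mismatch")
    for p, w in zip(params, weights):
        p.value = w.astype(np.float32)
    return model
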