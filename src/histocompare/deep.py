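"""A VGG-19-style network with six-block partitioning and block-wise
fine-tuning, implemented as a compact pure-numpy CNN.

Architecture (weight-bearing layers only): sixteen 3x3 same-padding
convolutions arranged in five blocks of 2-2-4-4-4 layers, each block closed
by a 2x2 max-pool, followed by three fully-connected layers (4096, 4096,
num_classes at scale 1) — 19 weight layers in total.  The six-block
partition groups the five conv blocks as B1..B5 and the dense head as B6.
Block-wise fine-tuning freezes all blocks before ``tune_from`` and trains
the rest; ``tune_from="B1"`` is full training, ``tune_from="B6"`` trains
only the dense head.

An integer ``scale_factor`` divides every channel/unit width (minimum 1)
while leaving the layer count and pattern untouched, giving miniature
instances that train in seconds on a CPU; the structural contracts
(19 weight layers, block pattern, partition) hold at every scale.

Block-wise fine-tuning presumes a pretrained source network.  At desk scale
the source is produced in-package: :func:`pretrain_backbone` trains a
miniature instance on the synthetic eight-subclass morphology task (all four
magnifications), and :func:`transfer_weights` copies every layer except the
final classifier into a target network, mirroring how an externally
pretrained backbone would be adapted.  Externally pretrained weights can be
loaded the same way when available.

Training follows the fixed protocol: SGD with momentum 0.9, learning rate
1e-3, weight decay 1e-3 (weights only), dropout 0.5 on the two hidden dense
layers, batch size 32, softmax cross-entropy, a stratified 70/30
train/test split, and online augmentation drawing one of {identity,
horizontal flip, vertical flip, rotation by 90/180/270 degrees} per sample
per epoch.  Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import Metrics, compute_metrics

__all__ = [
    "BLOCK_IDS",
    "TrainConfig",
    "VGG19Network",
    "BlockPartition",
    "apply_blockwise_schedule",
    "trainable_parameter_count",
    "AUGMENT_NAMES",
    "augment",
    "FineTuneModel",
    "TrainResults",
    "extract_deep_features",
    "preprocess_images",
    "pretrain_backbone",
    "transfer_weights",
]

BLOCK_IDS = ("B1", "B2", "B3", "B4", "B5", "B6")
_CONV_PLAN = ((64, 2), (128, 2), (256, 4), (512, 4), (512, 4))  # (width, n_conv)


@dataclass
class Param:
    name: str
    value: np.ndarray
    block: int                    # 1..6
    is_weight: bool               # True for weight matrices, False for biases
    trainable: bool = True
    grad: np.ndarray | None = None
    velocity: np.ndarray | None = None


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class _Layer:
    params: list[Param] = []

    def forward(self, x, train=False, rng=None):
        raise NotImplementedError

    def backward(self, g):
        raise NotImplementedError


class Conv3x3(_Layer):
    """3x3 same-padding convolution via im2col."""

    def __init__(self, c_in, c_out, block, name, rng, dtype=np.float32):
        fan_in = 9 * c_in
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), (c_out, fan_in)).astype(dtype)
        b = np.zeros(c_out, dtype=dtype)
        self.c_in, self.c_out = c_in, c_out
        self.W = Param(f"{name}.W", w, block, True)
        self.b = Param(f"{name}.b", b, block, False)
        self.params = [self.W, self.b]

    @staticmethod
    def _im2col(xp, h, w):
        # xp: (N, C, h+2, w+2) padded -> (N, 9C, h*w)
        n, c = xp.shape[:2]
        cols = np.empty((n, 9, c, h * w), dtype=xp.dtype)
        k = 0
        for dy in range(3):
            for dx in range(3):
                cols[:, k] = xp[:, :, dy:dy + h, dx:dx + w].reshape(n, c, h * w)
                k += 1
        return cols.reshape(n, 9 * c, h * w)

    def forward(self, x, train=False, rng=None):
        n, c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        cols = self._im2col(xp, h, w)
        self._cache = (cols, (n, c, h, w))
        out = np.matmul(self.W.value, cols) + self.b.value[:, None]
        return out.reshape(n, self.c_out, h, w)

    def backward(self, g):
        cols, (n, c, h, w) = self._cache
        g2 = g.reshape(n, self.c_out, h * w)
        self.W.grad += np.einsum("nox,nkx->ok", g2, cols, optimize=True)
        self.b.grad += g2.sum(axis=(0, 2))
        gcols = np.matmul(self.W.value.T, g2).reshape(n, 9, c, h, w)
        gxp = np.zeros((n, c, h + 2, w + 2), dtype=g.dtype)
        k = 0
        for dy in range(3):
            for dx in range(3):
                gxp[:, :, dy:dy + h, dx:dx + w] += gcols[:, k]
                k += 1
        return gxp[:, :, 1:-1, 1:-1]


class ReLU(_Layer):
    def forward(self, x, train=False, rng=None):
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, g):
        return np.where(self._mask, g, 0)


class MaxPool2(_Layer):
    def forward(self, x, train=False, rng=None):
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"max-pool needs even spatial dims, got {(h, w)}")
        xr = (x.reshape(n, c, h // 2, 2, w // 2, 2)
               .transpose(0, 1, 2, 4, 3, 5)
               .reshape(n, c, h // 2, w // 2, 4))
        self._idx = xr.argmax(axis=-1)
        self._shape = (n, c, h, w)
        return np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, g):
        n, c, h, w = self._shape
        gr = np.zeros((n, c, h // 2, w // 2, 4), dtype=g.dtype)
        np.put_along_axis(gr, self._idx[..., None], g[..., None], axis=-1)
        return (gr.reshape(n, c, h // 2, w // 2, 2, 2)
                  .transpose(0, 1, 2, 4, 3, 5)
                  .reshape(n, c, h, w))


class Flatten(_Layer):
    def forward(self, x, train=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g):
        return g.reshape(self._shape)


class Linear(_Layer):
    def __init__(self, d_in, d_out, block, name, rng, dtype=np.float32):
        w = rng.normal(0.0, np.sqrt(2.0 / d_in), (d_out, d_in)).astype(dtype)
        b = np.zeros(d_out, dtype=dtype)
        self.W = Param(f"{name}.W", w, block, True)
        self.b = Param(f"{name}.b", b, block, False)
        self.params = [self.W, self.b]

    def forward(self, x, train=False, rng=None):
        self._x = x
        return x @ self.W.value.T + self.b.value

    def backward(self, g):
        self.W.grad += g.T @ self._x
        self.b.grad += g.sum(axis=0)
        return g @ self.W.value


class Dropout(_Layer):
    def __init__(self, p):
        self.p = p

    def forward(self, x, train=False, rng=None):
        if not train or self.p <= 0:
            self._mask = None
            return x
        self._mask = (rng.random(x.shape) >= self.p).astype(x.dtype) / (1.0 - self.p)
        return x * self._mask

    def backward(self, g):
        return g if self._mask is None else g * self._mask


# ---------------------------------------------------------------------------
# network
# ---------------------------------------------------------------------------

class VGG19Network:
    """VGG-19-style network; see module docstring.

    Parameters
    ----------
    num_classes : output width (>= 2).
    scale_factor : integer channel-width divisor for miniature instances.
    input_size : square input side, must be a multiple of 32.
    seed : initialization seed (He-style normal init).
    """

    def __init__(self, num_classes: int, scale_factor: int = 1,
                 input_size: int = 224, seed: int = 0, dropout: float = 0.5):
        if num_classes < 2:
            raise ValueError("num_classes must be >= 2")
        if scale_factor < 1 or int(scale_factor) != scale_factor:
            raise ValueError("scale_factor must be a positive integer")
        if input_size % 32 or input_size < 32:
            raise ValueError("input_size must be a multiple of 32 (five 2x2 pools)")
        self.num_classes = num_classes
        self.scale_factor = int(scale_factor)
        self.input_size = input_size
        self.seed = seed
        rng = np.random.default_rng(seed)

        s = self.scale_factor
        layers: list[_Layer] = []
        c_in = 3
        conv_i = 0
        for block, (width, n_conv) in enumerate(_CONV_PLAN, start=1):
            c_out = max(1, width // s)
            for _ in range(n_conv):
                conv_i += 1
                layers.append(Conv3x3(c_in, c_out, block, f"conv{conv_i}", rng))
                layers.append(ReLU())
                c_in = c_out
            layers.append(MaxPool2())
        self._last_conv_relu_index = len(layers) - 2  # ReLU after conv16
        layers.append(Flatten())
        spatial = input_size // 32
        d_in = c_in * spatial * spatial
        fc_width = max(1, 4096 // s)
        layers.append(Linear(d_in, fc_width, 6, "fc1", rng))
        layers.append(ReLU())
        layers.append(Dropout(dropout))
        layers.append(Linear(fc_width, fc_width, 6, "fc2", rng))
        self._fc2_relu_index = len(layers)
        layers.append(ReLU())
        layers.append(Dropout(dropout))
        layers.append(Linear(fc_width, num_classes, 6, "fc_out", rng))
        self.layers = layers
        self.fc_width = fc_width
        self.activations: dict[str, np.ndarray] = {}
        self.captured_gradients: dict[str, np.ndarray] = {}
        #: per-channel (mean, std) used to standardize inputs; set when the
        #: network is (pre)trained so downstream passes see the same scaling
        self.input_stats: tuple[np.ndarray, np.ndarray] | None = None

    # -- structure ---------------------------------------------------------
    @property
    def weight_layers(self) -> list[_Layer]:
        return [l for l in self.layers if isinstance(l, (Conv3x3, Linear))]

    def parameters(self) -> list[Param]:
        return [p for l in self.layers for p in getattr(l, "params", [])]

    # -- execution ---------------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        """Forward pass on (N, 3, H, W) float input; records the post-ReLU
        activations of the last convolution and of the second dense layer."""
        for i, layer in enumerate(self.layers):
            x = layer.forward(x, train=train, rng=rng)
            if i == self._last_conv_relu_index:
                self.activations["last_conv"] = x
            elif i == self._fc2_relu_index:
                self.activations["fc2"] = x
        return x

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = np.zeros_like(p.value)

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        """Backward pass; accumulates parameter gradients and records the
        gradient at the last convolution's activation."""
        g = dlogits
        for i in range(len(self.layers) - 1, -1, -1):
            if i == self._last_conv_relu_index:
                self.captured_gradients["last_conv"] = g
            g = self.layers[i].backward(g)
        return g

    def last_conv_activation_and_gradient(self, x: np.ndarray, class_index: int
                                          ) -> tuple[np.ndarray, np.ndarray]:
        """Feature maps A of the last conv layer and d(score)/dA for one
        image (3, H, W); the score is the pre-softmax logit of the class."""
        logits = self.forward(x[None], train=False)
        if not 0 <= class_index < logits.shape[1]:
            raise ValueError(f"class index {class_index} out of range")
        self.zero_grad()
        d = np.zeros_like(logits)
        d[0, class_index] = 1.0
        self.backward(d)
        return (self.activations["last_conv"][0],
                self.captured_gradients["last_conv"][0])


@dataclass
class BlockPartition:
    """Mapping of the 19 weight layers onto blocks B1..B6."""

    blocks: dict[str, list[int]]  # block id -> indices into weight_layers

    @classmethod
    def from_network(cls, net: VGG19Network) -> "BlockPartition":
        blocks: dict[str, list[int]] = {b: [] for b in BLOCK_IDS}
        for i, layer in enumerate(net.weight_layers):
            blocks[f"B{layer.params[0].block}"].append(i)
        return cls(blocks=blocks)

    @property
    def conv_counts(self) -> tuple[int, ...]:
        return tuple(len(self.blocks[b]) for b in BLOCK_IDS[:5])


def apply_blockwise_schedule(net: VGG19Network, tune_from: str) -> dict[str, bool]:
    """Freeze blocks before ``tune_from``, train ``tune_from``..B6.

    Returns the per-parameter trainability mask (also applied in place)."""
    if tune_from not in BLOCK_IDS:
        raise ValueError(f"tune_from must be one of {BLOCK_IDS}, got {tune_from!r}")
    first = int(tune_from[1])
    mask = {}
    for p in net.parameters():
        p.trainable = p.block >= first
        mask[p.name] = p.trainable
    return mask


def trainable_parameter_count(net: VGG19Network) -> int:
    return int(sum(p.value.size for p in net.parameters() if p.trainable))


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

AUGMENT_NAMES = ("identity", "hflip", "vflip", "rot90", "rot180", "rot270")


def _apply_augment(x: np.ndarray, which: int, axes: tuple[int, int]) -> np.ndarray:
    """Apply one of the six transforms on the two spatial axes given."""
    if which == 0:
        return x
    if which == 1:
        return np.flip(x, axis=axes[1])
    if which == 2:
        return np.flip(x, axis=axes[0])
    k = which - 2
    if x.shape[axes[0]] != x.shape[axes[1]]:
        raise ValueError("rotation augmentation requires a square image")
    return np.rot90(x, k=k, axes=axes)


def augment(image, seed_or_rng=0, which: int | None = None) -> np.ndarray:
    """Draw one of the six augmentations uniformly (seeded) and apply it.

    ``image`` is (H, W[, C]); rotations require a square image.  The pixel
    multiset is always preserved.
    """
    px = image.pixels if hasattr(image, "pixels") else np.asarray(image)
    rng = (seed_or_rng if isinstance(seed_or_rng, np.random.Generator)
           else np.random.default_rng(seed_or_rng))
    if which is None:
        which = int(rng.integers(6))
    return _apply_augment(px, which, axes=(0, 1))


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrainConfig:
    """The fixed optimization protocol."""

    learning_rate: float = 0.001
    momentum: float = 0.9
    weight_decay: float = 0.001
    dropout: float = 0.5
    batch_size: int = 32
    epochs: int = 70
    seed: int = 0

    def __post_init__(self):
        if min(self.learning_rate, self.momentum, self.weight_decay,
               self.dropout, self.batch_size, self.epochs) < 0 or self.epochs < 1:
            raise ValueError("all training settings must be positive; epochs >= 1")


def preprocess_images(images: np.ndarray,
                      stats: tuple[np.ndarray, np.ndarray] | None = None
                      ) -> np.ndarray:
    """uint8 (N, H, W, 3) -> standardized float32 (N, 3, H, W).

    With ``stats`` = (mean, std) per channel on the [0, 1] scale, inputs are
    standardized by those dataset statistics; otherwise the fixed
    mean 0.5 / std 0.5 scaling is applied."""
    x = np.asarray(images, dtype=np.float32) / 255.0
    if stats is None:
        mu, sd = np.float32(0.5), np.float32(0.5)
    else:
        mu = np.asarray(stats[0], dtype=np.float32)
        sd = np.asarray(stats[1], dtype=np.float32)
    return np.ascontiguousarray(((x - mu) / sd).transpose(0, 3, 1, 2))


def _channel_stats(images: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(images, dtype=np.float32) / 255.0
    return x.mean(axis=(0, 1, 2)), x.std(axis=(0, 1, 2)) + np.float32(1e-6)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


@dataclass
class TrainResults:
    """Fitted network plus the training record: per-epoch history, final
    test metrics, the freeze mask and the class coding."""

    network: VGG19Network
    history: pd.DataFrame       # epoch, train_loss, train_accuracy, test_accuracy
    test_metrics: Metrics
    class_names: list
    tune_from: str
    config: TrainConfig
    freeze_mask: dict[str, bool]
    test_indices: np.ndarray

    @property
    def final_test_accuracy(self) -> float:
        return self.test_metrics.accuracy

    def summary(self) -> str:
        n_train = len(self.freeze_mask) - sum(self.freeze_mask.values())
        lines = [
            f"VGG-19-style network (scale 1/{self.network.scale_factor}, "
            f"input {self.network.input_size}), schedule "
            f"{'B6' if self.tune_from == 'B6' else 'B6-' + self.tune_from} "
            f"({sum(self.freeze_mask.values())} trainable / {n_train} frozen tensors)",
            f"epochs {self.config.epochs}, batch {self.config.batch_size}, "
            f"lr {self.config.learning_rate}, momentum {self.config.momentum}, "
            f"weight decay {self.config.weight_decay}, seed {self.config.seed}",
            f"final train loss {self.history['train_loss'].iloc[-1]:.4f}, "
            f"train accuracy {self.history['train_accuracy'].iloc[-1]:.2f}%",
            f"test accuracy {self.test_metrics.accuracy:.2f}%, "
            f"macro recall {self.test_metrics.recall:.2f}%, "
            f"macro precision {self.test_metrics.precision:.2f}%",
        ]
        return "\n".join(lines)


class FineTuneModel:
    """A network bound to an image set under a block-wise schedule.

    Parameters
    ----------
    network : the (possibly miniature) VGG-19-style network.
    images : (N, H, W, 3) uint8 array, H = W = network.input_size.
    labels : sequence of class labels, any hashable type.
    config : TrainConfig.
    tune_from : first trainable block, "B1".."B6".
    augment_online : draw one augmentation per sample per epoch.
    """

    def __init__(self, network: VGG19Network, images, labels,
                 config: TrainConfig = TrainConfig(), tune_from: str = "B6",
                 augment_online: bool = True):
        self.network = network
        self.images = np.asarray(images)
        self.class_names = sorted(set(labels))
        lut = {c: i for i, c in enumerate(self.class_names)}
        self.y = np.array([lut[c] for c in labels])
        if len(self.class_names) != network.num_classes:
            raise ValueError(
                f"network has {network.num_classes} outputs but labels contain "
                f"{len(self.class_names)} classes")
        self.config = config
        self.tune_from = tune_from
        self.augment_online = augment_online

    def _evaluate(self, x: np.ndarray, batch: int = 64) -> np.ndarray:
        preds = [np.argmax(self.network.forward(x[i:i + batch]), axis=1)
                 for i in range(0, len(x), batch)]
        return np.concatenate(preds) if preds else np.empty(0, dtype=int)

    def fit(self, train_frac: float = 0.7) -> TrainResults:
        cfg = self.config
        ss = np.random.SeedSequence([cfg.seed, 17])
        rng_split, rng_shuffle, rng_aug, rng_drop = (
            np.random.default_rng(c) for c in ss.spawn(4))

        # stratified train/test split
        train_idx, test_idx = [], []
        for c in range(len(self.class_names)):
            idx = np.where(self.y == c)[0]
            idx = idx[rng_split.permutation(len(idx))]
            n_tr = int(round(train_frac * len(idx)))
            train_idx.append(idx[:n_tr])
            test_idx.append(idx[n_tr:])
        train_idx = np.concatenate(train_idx)
        test_idx = np.concatenate(test_idx)
        if train_idx.size == 0 or test_idx.size == 0:
            raise ValueError("empty train or test split")

        # standardize by training-set channel statistics; a transferred
        # backbone keeps the statistics it was pretrained with
        if self.network.input_stats is None:
            self.network.input_stats = _channel_stats(self.images[train_idx])
        x_all = preprocess_images(self.images, self.network.input_stats)
        x_test, y_test = x_all[test_idx], self.y[test_idx]
        y_train = self.y[train_idx]

        freeze_mask = apply_blockwise_schedule(self.network, self.tune_from)
        params = self.network.parameters()
        for p in params:
            p.velocity = np.zeros_like(p.value)

        rows = []
        for epoch in range(cfg.epochs):
            order = rng_shuffle.permutation(len(train_idx))
            losses, correct = [], 0
            for start in range(0, len(order), cfg.batch_size):
                sel = train_idx[order[start:start + cfg.batch_size]]
                xb = x_all[sel]
                if self.augment_online:
                    which = rng_aug.integers(6, size=len(sel))
                    xb = np.stack([_apply_augment(xb[j], int(which[j]), axes=(1, 2))
                                   for j in range(len(sel))])
                yb = self.y[sel]
                self.network.zero_grad()
                logits = self.network.forward(xb, train=True, rng=rng_drop)
                p = _softmax(logits)
                losses.append(float(-np.log(p[np.arange(len(yb)), yb] + 1e-12).mean()))
                correct += int((np.argmax(logits, axis=1) == yb).sum())
                dlogits = (p - np.eye(self.network.num_classes,
                                      dtype=p.dtype)[yb]) / len(yb)
                self.network.backward(dlogits.astype(np.float32))
                for prm in params:
                    if not prm.trainable:
                        continue
                    g = prm.grad
                    if prm.is_weight and cfg.weight_decay:
                        g = g + cfg.weight_decay * prm.value
                    prm.velocity = cfg.momentum * prm.velocity - cfg.learning_rate * g
                    prm.value += prm.velocity
            test_pred = self._evaluate(x_test)
            rows.append({
                "epoch": epoch,
                "train_loss": float(np.mean(losses)),
                "train_accuracy": 100.0 * correct / len(train_idx),
                "test_accuracy": 100.0 * float(np.mean(test_pred == y_test)),
            })
        test_pred = self._evaluate(x_test)
        metrics = compute_metrics(y_test, test_pred,
                                  class_set=range(len(self.class_names)))
        return TrainResults(
            network=self.network, history=pd.DataFrame(rows),
            test_metrics=metrics, class_names=self.class_names,
            tune_from=self.tune_from, config=cfg, freeze_mask=freeze_mask,
            test_indices=test_idx)


def transfer_weights(source: VGG19Network, target: VGG19Network,
                     skip_final: bool = True) -> None:
    """Copy every matching parameter from a (pre)trained source network into
    a target network; the final classifier layer is skipped by default so a
    new class count can be attached.  Input statistics travel along."""
    src = {p.name: p.value for p in source.parameters()}
    for p in target.parameters():
        if skip_final and p.name.startswith("fc_out"):
            continue
        if p.name in src and src[p.name].shape == p.value.shape:
            p.value[...] = src[p.name]
    target.input_stats = source.input_stats


def pretrain_backbone(scale_factor: int = 8, input_size: int = 64,
                      seed: int = 0, epochs: int = 40,
                      learning_rate: float = 0.01, dropout: float = 0.2,
                      images_per_cell: int = 20) -> tuple[VGG19Network, "TrainResults"]:
    """Train a miniature backbone on the synthetic source task.

    The source task is eight-way tumor sub-class recognition over all four
    magnification scales (``images_per_cell`` patches per sub-class and
    magnification) — related to, but distinct from, the binary target task.
    The source protocol (higher learning rate, lighter dropout, more epochs)
    is the package's own choice; the target fine-tuning protocol stays the
    fixed one in :class:`TrainConfig`.
    """
    from .synthetic import MAGNIFICATION_SCALE, generate_image, subclass_specs

    rng = np.random.default_rng(np.random.SeedSequence([seed, 2027]))
    images, labels = [], []
    for lab, spec in subclass_specs().items():
        for mag in sorted(MAGNIFICATION_SCALE):
            for _ in range(images_per_cell):
                patch, _ = generate_image(spec, (input_size, input_size),
                                          int(rng.integers(2 ** 31)),
                                          magnification=mag)
                images.append(patch.pixels)
                labels.append(lab)
    images = np.stack(images)
    net = VGG19Network(num_classes=len(set(labels)), scale_factor=scale_factor,
                       input_size=input_size, seed=seed, dropout=dropout)
    cfg = TrainConfig(learning_rate=learning_rate, dropout=dropout,
                      epochs=epochs, seed=seed)
    results = FineTuneModel(net, images, labels, cfg, tune_from="B1").fit()
    return net, results


def extract_deep_features(network: VGG19Network, images,
                          batch: int = 64) -> np.ndarray:
    """Post-ReLU activations of the second dense layer (4096-d at scale 1),
    dropout disabled, one row per image."""
    x = preprocess_images(np.asarray(images), network.input_stats)
    if x.shape[2] != network.input_size or x.shape[3] != network.input_size:
        raise ValueError(
            f"images are {x.shape[2]}x{x.shape[3]} but the network expects "
            f"{network.input_size}x{network.input_size}")
    out = []
    for i in range(0, len(x), batch):
        network.forward(x[i:i + batch], train=False)
        out.append(network.activations["fc2"].copy())
    return np.concatenate(out, axis=0)
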