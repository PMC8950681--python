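"""The per-residue disorder classifier: MLP -> VGG19-style CNN -> MLP.

Architecture, per residue (one 35-feature column of the feature matrix):

1. MLP1 with hidden layers of 35 and 3675 ReLU units; its 3675-vector
   output is reshaped to a 35 x 35 x 3 "image".
2. A VGG19-style convolutional backbone: five blocks of (2, 2, 4, 4, 4)
   3x3 same-padding ReLU convolutions with (64, 128, 256, 512, 512)
   channels, each block followed by 2x2 max pooling, taking the spatial
   side 35 -> 17 -> 8 -> 4 -> 2 -> 1.  The fully connected head of VGG19
   is absent.
3. The flattened backbone output is linearly projected to width 3675 and
   summed with MLP1's 3675-vector (skip connection).
4. MLP2 with one 3675-unit ReLU hidden layer and 50% dropout, then a
   single sigmoid output: the probability that the residue is disordered.

Training minimises the mean binary cross-entropy over "packages"
(mini-batches) of 128 residues pooled across all proteins, by plain SGD at
learning rate 1e-4, until the epoch loss stops moving or a maximum epoch
count is reached.

Everything is implemented directly in numpy (float32) with hand-written
backpropagation; forward passes in eval mode are pure functions of the
input.  A ``small`` configuration divides the backbone channel widths by 8
for desk-scale experiments.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import DataError, NumericalError

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "PredictionResult",
    "DisorderNet",
    "build_model",
    "bce_loss",
    "train",
    "predict_protein",
    "save_checkpoint",
    "load_checkpoint",
]

_EPS = 1e-7


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    The invariant ``mlp1 output width = image_side**2 * image_channels``
    (3675 = 35*35*3 at defaults) ties the first MLP to the backbone input.
    """

    input_width: int = 35
    mlp1_hidden: int = 35
    image_side: int = 35
    image_channels: int = 3
    block_channels: tuple[int, ...] = (64, 128, 256, 512, 512)
    convs_per_block: tuple[int, ...] = (2, 2, 4, 4, 4)
    mlp2_hidden: int = 3675
    dropout: float = 0.5
    threshold: float = 0.5
    pretrained_backbone: bool = False
    pretrained_path: str | None = None

    @property
    def projection_width(self) -> int:
        return self.image_side * self.image_side * self.image_channels

    def validate(self) -> None:
        if len(self.block_channels) != len(self.convs_per_block):
            raise DataError("block_channels and convs_per_block must align")
        if not 0.0 < self.threshold < 1.0:
            raise DataError("threshold must lie in (0, 1)")
        if not 0.0 <= self.dropout < 1.0:
            raise DataError("dropout must lie in [0, 1)")

    @classmethod
    def small(cls, **overrides) -> "ModelConfig":
        """Desk-scale variant: backbone channel widths divided by 8."""
        cfg = cls(block_channels=(8, 16, 32, 64, 64), **overrides)
        return cfg


@dataclass
class TrainConfig:
    package_size: int = 128
    learning_rate: float = 1e-4
    max_epochs: int = 30
    seed: int = 0
    convergence_tol: float = 0.0
    pos_weight: float | None = None

    def validate(self) -> None:
        if self.package_size < 1:
            raise DataError("package_size must be >= 1")
        if self.learning_rate < 0:
            raise DataError("learning_rate must be >= 0")


@dataclass
class PredictionResult:
    probabilities: np.ndarray
    calls: np.ndarray
    logits: np.ndarray


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class _Dense:
    def __init__(self, rng: np.random.Generator, n_in: int, n_out: int):
        std = np.sqrt(2.0 / n_in)
        self.W = rng.normal(0.0, std, size=(n_in, n_out)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.W + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.dW = self._x.T @ dy
        self.db = dy.sum(axis=0)
        return dy @ self.W.T

    def params(self):
        yield self.W, self.dW
        yield self.b, self.db


class _Relu:
    def __init__(self):
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask

    def params(self):
        return iter(())


class _Conv3x3:
    """3x3 convolution with same padding, NHWC layout.

    Implemented as nine shifted matmul accumulations, which keeps both the
    forward and backward passes as large GEMMs.
    """

    def __init__(self, rng: np.random.Generator, c_in: int, c_out: int):
        std = np.sqrt(2.0 / (9 * c_in))
        self.W = rng.normal(0.0, std, size=(3, 3, c_in, c_out)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._xpad: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        m, H, Wd, C = x.shape
        xpad = np.zeros((m, H + 2, Wd + 2, C), dtype=np.float32)
        xpad[:, 1:-1, 1:-1, :] = x
        if train:
            self._xpad = xpad
        y = np.empty((m, H, Wd, self.W.shape[3]), dtype=np.float32)
        y[:] = self.b
        for di in range(3):
            for dj in range(3):
                y += np.tensordot(
                    xpad[:, di : di + H, dj : dj + Wd, :], self.W[di, dj], axes=([3], [0])
                )
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        m, H, Wd, _ = dy.shape
        xpad = self._xpad
        dxpad = np.zeros_like(xpad)
        for di in range(3):
            for dj in range(3):
                xs = xpad[:, di : di + H, dj : dj + Wd, :]
                self.dW[di, dj] = np.tensordot(xs, dy, axes=([0, 1, 2], [0, 1, 2]))
                dxpad[:, di : di + H, dj : dj + Wd, :] += np.tensordot(
                    dy, self.W[di, dj], axes=([3], [1])
                )
        self.db = dy.sum(axis=(0, 1, 2))
        return dxpad[:, 1:-1, 1:-1, :]

    def params(self):
        yield self.W, self.dW
        yield self.b, self.db


class _MaxPool2:
    """2x2 max pooling, stride 2, floor semantics (odd trailing row/col dropped)."""

    def __init__(self):
        self._shape: tuple | None = None
        self._argmax: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        m, H, Wd, C = x.shape
        He, We = (H // 2) * 2, (Wd // 2) * 2
        xc = x[:, :He, :We, :]
        r = xc.reshape(m, He // 2, 2, We // 2, 2, C)
        r = r.transpose(0, 1, 3, 5, 2, 4).reshape(m, He // 2, We // 2, C, 4)
        if train:
            self._shape = x.shape
            self._argmax = r.argmax(axis=4)
        return r.max(axis=4)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        m, H, Wd, C = self._shape
        h2, w2 = H // 2, Wd // 2
        scatter = np.zeros((m, h2, w2, C, 4), dtype=np.float32)
        np.put_along_axis(scatter, self._argmax[..., None], dy[..., None], axis=4)
        scatter = scatter.reshape(m, h2, w2, C, 2, 2).transpose(0, 1, 4, 2, 5, 3)
        dx = np.zeros((m, H, Wd, C), dtype=np.float32)
        dx[:, : h2 * 2, : w2 * 2, :] = scatter.reshape(m, h2 * 2, w2 * 2, C)
        return dx

    def params(self):
        return iter(())


# ---------------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------------

class DisorderNet:
    """MLP -> convolutional backbone -> MLP with a skip connection."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        config.validate()
        self.config = config
        rng = np.random.default_rng(seed)
        c = config
        self.mlp1 = [
            _Dense(rng, c.input_width, c.mlp1_hidden),
            _Relu(),
            _Dense(rng, c.mlp1_hidden, c.projection_width),
            _Relu(),
        ]
        self.backbone: list = []
        c_in = c.image_channels
        for c_out, reps in zip(c.block_channels, c.convs_per_block):
            for _ in range(reps):
                self.backbone.append(_Conv3x3(rng, c_in, c_out))
                self.backbone.append(_Relu())
                c_in = c_out
            self.backbone.append(_MaxPool2())
        side = c.image_side
        for _ in c.block_channels:
            side //= 2
        self._flat_width = side * side * c.block_channels[-1]
        self.projection = _Dense(rng, self._flat_width, c.projection_width)
        self.mlp2_hidden = _Dense(rng, c.projection_width, c.mlp2_hidden)
        self.mlp2_relu = _Relu()
        self.mlp2_out = _Dense(rng, c.mlp2_hidden, 1)
        self._drop_mask: np.ndarray | None = None
        self._flat_shape: tuple | None = None
        if c.pretrained_backbone:
            self.load_backbone_weights(c.pretrained_path)

    # -- weight I/O ---------------------------------------------------------

    def load_backbone_weights(self, path: str | None) -> None:
        """Initialise conv weights from a published VGG19 checkpoint (npz).

        Expects arrays ``conv{i}_W`` (3,3,c_in,c_out) and ``conv{i}_b``
        matching this configuration's channel widths.
        """
        if path is None or not Path(path).exists():
            raise DataError(
                "pretrained backbone requested but no weight file is available; "
                "provide pretrained_path (an .npz of conv weights) or build with "
                "pretrained_backbone=False for random initialisation"
            )
        data = np.load(path)
        convs = [l for l in self.backbone if isinstance(l, _Conv3x3)]
        for i, layer in enumerate(convs):
            W, b = data[f"conv{i}_W"], data[f"conv{i}_b"]
            if W.shape != layer.W.shape:
                raise DataError(
                    f"pretrained conv{i} shape {W.shape} != expected {layer.W.shape}"
                )
            layer.W = W.astype(np.float32)
            layer.b = b.astype(np.float32)

    # -- forward / backward -------------------------------------------------

    def forward(
        self,
        X: np.ndarray,
        train: bool = False,
        rng: np.random.Generator | None = None,
    ) -> np.ndarray:
        """Probabilities for a batch of 35-feature residue vectors."""
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 2 or X.shape[1] != self.config.input_width:
            raise DataError(
                f"expected (m, {self.config.input_width}) input, got {X.shape}"
            )
        m = X.shape[0]
        h = X
        for layer in self.mlp1:
            h = layer.forward(h, train)
        skip = h  # (m, 3675)
        img = h.reshape(m, self.config.image_side, self.config.image_side,
                        self.config.image_channels)
        for layer in self.backbone:
            img = layer.forward(img, train)
        self._flat_shape = img.shape
        flat = img.reshape(m, self._flat_width)
        proj = self.projection.forward(flat, train)
        s = proj + skip
        h2 = self.mlp2_relu.forward(self.mlp2_hidden.forward(s, train), train)
        if train and self.config.dropout > 0.0:
            if rng is None:
                raise DataError("training forward pass needs an rng for dropout")
            keep = 1.0 - self.config.dropout
            self._drop_mask = (rng.random(h2.shape) < keep).astype(np.float32) / keep
            h2 = h2 * self._drop_mask
        else:
            self._drop_mask = None
        z = self.mlp2_out.forward(h2, train)[:, 0]
        self._logits = z
        return 1.0 / (1.0 + np.exp(-z))

    def backward(self, dz: np.ndarray) -> None:
        """Backpropagate d(loss)/d(logit) through the whole network."""
        dh2 = self.mlp2_out.backward(dz[:, None].astype(np.float32))
        if self._drop_mask is not None:
            dh2 = dh2 * self._drop_mask
        ds = self.mlp2_hidden.backward(self.mlp2_relu.backward(dh2))
        dflat = self.projection.backward(ds)
        dimg = dflat.reshape(self._flat_shape)
        for layer in reversed(self.backbone):
            dimg = layer.backward(dimg)
        dskip = dimg.reshape(ds.shape[0], -1) + ds  # skip connection
        dh = dskip
        for layer in reversed(self.mlp1):
            dh = layer.backward(dh)

    def step(self, lr: float) -> None:
        for layer in self._layers():
            for p, g in layer.params():
                p -= lr * g

    def _layers(self):
        yield from self.mlp1
        yield from self.backbone
        yield self.projection
        yield self.mlp2_hidden
        yield self.mlp2_relu
        yield self.mlp2_out

    def n_parameters(self) -> int:
        return sum(p.size for layer in self._layers() for p, _ in layer.params())

    def predict_proba(self, X: np.ndarray, batch: int = 512) -> np.ndarray:
        """Eval-mode probabilities (dropout off); pure function of X."""
        X = np.asarray(X, dtype=np.float32)
        out = np.empty(X.shape[0], dtype=np.float64)
        for i in range(0, X.shape[0], batch):
            out[i : i + batch] = self.forward(X[i : i + batch], train=False)
        return out


def build_model(config: ModelConfig | None = None, seed: int = 0) -> DisorderNet:
    """Construct a deterministically seeded network."""
    return DisorderNet(config or ModelConfig(), seed=seed)


# ---------------------------------------------------------------------------
# loss, training, prediction
# ---------------------------------------------------------------------------

def bce_loss(probabilities: np.ndarray, labels: np.ndarray, pos_weight: float | None = None) -> float:
    """Mean binary cross-entropy (natural log), probabilities clipped to
    [1e-7, 1 - 1e-7] for numerical safety."""
    a = np.asarray(probabilities, dtype=np.float64)
    y = np.asarray(labels, dtype=np.float64)
    if a.shape != y.shape:
        raise DataError(f"probabilities shape {a.shape} != labels shape {y.shape}")
    a = np.clip(a, _EPS, 1.0 - _EPS)
    w = 1.0 if pos_weight is None else pos_weight
    return float(np.mean(-(w * y * np.log(a) + (1.0 - y) * np.log(1.0 - a))))


def train(
    model: DisorderNet,
    features: np.ndarray,
    labels: np.ndarray,
    tc: TrainConfig,
) -> list[float]:
    """SGD training on residues pooled across proteins; returns per-epoch mean loss.

    Residues are shuffled once (seeded) and divided into fixed packages of
    ``package_size``; each epoch sweeps all packages with one SGD update
    per package.  The dropout stream is re-seeded identically at the start
    of each epoch, so a zero learning rate yields a constant loss history.
    Training stops when the epoch mean loss moves by less than
    ``convergence_tol`` or after ``max_epochs`` epochs.
    """
    tc.validate()
    X = np.asarray(features, dtype=np.float32)
    y = np.asarray(labels, dtype=np.float32)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise DataError("features and labels must align")
    if X.shape[0] == 0:
        raise DataError("no training residues")
    if len(np.unique(y)) < 2:
        import warnings

        warnings.warn("training labels contain a single class; MCC will be undefined",
                      stacklevel=2)

    rng = np.random.default_rng(tc.seed)
    order = rng.permutation(X.shape[0])
    packages = [
        order[i : i + tc.package_size]
        for i in range(0, len(order), tc.package_size)
    ]
    history: list[float] = []
    for epoch in range(tc.max_epochs):
        drop_rng = np.random.default_rng(tc.seed + 1)
        losses = []
        for pkg in packages:
            Xb, yb = X[pkg], y[pkg]
            a = model.forward(Xb, train=True, rng=drop_rng)
            losses.append(bce_loss(a, yb, pos_weight=tc.pos_weight))
            ac = np.clip(a, _EPS, 1.0 - _EPS)
            if tc.pos_weight is None:
                dz = (ac - yb) / len(yb)
            else:
                dz = (ac * (tc.pos_weight * yb + (1 - yb)) - tc.pos_weight * yb) / len(yb)
            model.backward(dz.astype(np.float32))
            model.step(tc.learning_rate)
        mean_loss = float(np.mean(losses))
        if not np.isfinite(mean_loss):
            raise NumericalError(f"training diverged at epoch {epoch + 1}")
        history.append(mean_loss)
        if len(history) >= 2 and abs(history[-1] - history[-2]) < tc.convergence_tol:
            break
    return history


def predict_protein(
    model: DisorderNet, F: np.ndarray, threshold: float | None = None
) -> PredictionResult:
    """Per-residue probabilities and calls for one 35 x L feature matrix.

    The call rule is ``probability >= threshold`` (default: the model
    config threshold, 0.5).
    """
    F = np.asarray(F, dtype=np.float64)
    if F.ndim != 2 or F.shape[0] != model.config.input_width:
        raise DataError(f"expected ({model.config.input_width}, L) matrix, got {F.shape}")
    thr = model.config.threshold if threshold is None else float(threshold)
    probs = model.predict_proba(F.T.astype(np.float32))
    logits = np.log(np.clip(probs, _EPS, 1 - _EPS) / np.clip(1 - probs, _EPS, 1 - _EPS))
    calls = (probs >= thr).astype(np.int8)
    return PredictionResult(probabilities=probs, calls=calls, logits=logits)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: DisorderNet, path: str | Path) -> None:
    """Single-file checkpoint: serialized weights plus the config as JSON."""
    arrays: dict[str, np.ndarray] = {}
    for i, layer in enumerate(model._layers()):
        for j, (p, _) in enumerate(layer.params()):
            arrays[f"p_{i}_{j}"] = p
    cfg = asdict(model.config)
    cfg["block_channels"] = list(cfg["block_channels"])
    cfg["convs_per_block"] = list(cfg["convs_per_block"])
    arrays["config_json"] = np.frombuffer(json.dumps(cfg).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path: str | Path) -> DisorderNet:
    data = np.load(path)
    cfg_dict = json.loads(bytes(data["config_json"]).decode())
    cfg_dict["block_channels"] = tuple(cfg_dict["block_channels"])
    cfg_dict["convs_per_block"] = tuple(cfg_dict["convs_per_block"])
    pretrained = cfg_dict.pop("pretrained_backbone", False)
    cfg_dict.pop("pretrained_path", None)
    cfg = ModelConfig(**cfg_dict)
    cfg.pretrained_backbone = False  # weights come from the checkpoint itself
    model = DisorderNet(cfg, seed=0)
    model.config.pretrained_backbone = pretrained
    for i, layer in enumerate(model._layers()):
        for j, (p, _) in enumerate(layer.params()):
            p[...] = data[f"p_{i}_{j}"]
    return model
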