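"""HemNet: a shallow 19-layer convolutional classifier for lesion patches.

The network takes a 256x256x3 patch (green / HSV-value / Lab-L channels)
and emits two softmax probabilities (hemorrhage vs. not).  Architecture,
in order, with one skip branch:

    input (256,256,3)
    conv 11x11, 16 filters, stride 3, same padding   -> (86,86,16)
    ReLU, batch norm, avg pool 2x2 (stride 1, same)  -> (86,86,16)   [a]
    conv 5x5, 16, stride 2, same                     -> (43,43,16)
    ReLU, batch norm, avg pool 2x2 (stride 1, same)  -> (43,43,16)   [b]
    skip from [a]: avg pool 5x5 stride 2, batch norm -> (43,43,16)   [c]
    addition b + c                                   -> (43,43,16)
    conv 11x11, 16, stride 2, same                   -> (22,22,16)
    ReLU, batch norm, avg pool 2x2 (stride 1, same)  -> (22,22,16)
    fully connected -> 2, softmax, cross-entropy output

Counting input, every conv/ReLU/batch-norm/pool, the addition junction, the
fully-connected, softmax and classification output gives 19 individual
layers.  Same padding is the only convolution padding reproducing these
shapes (e.g. 256 -> 86 at stride 3 needs 5 pixels of padding per side).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .nn import F32


class ArchitectureError(ValueError):
    """Realized layer shapes deviate from the reference architecture."""


#: (layer name, layer type, expected output shape or None where unspecified)
REFERENCE_LAYOUT: list[tuple[str, str, tuple[int, ...] | None]] = [
    ("input", "Image input", (256, 256, 3)),
    ("conv_1", "Convolution", (86, 86, 16)),
    ("relu_1", "ReLU", (86, 86, 16)),
    ("batchnorm_1", "Batch normalization", (86, 86, 16)),
    ("avgpool2d_1", "Average pooling", (86, 86, 16)),
    ("conv_2", "Convolution", (43, 43, 16)),
    ("relu_2", "ReLU", (43, 43, 16)),
    ("batchnorm_2", "Batch normalization", (43, 43, 16)),
    ("avgpool2d_2", "Average pooling", (43, 43, 16)),
    ("avgpool2d_3", "Average pooling", (43, 43, 16)),
    ("batchnorm_3", "Batch normalization", (43, 43, 16)),
    ("addition", "Addition", (43, 43, 16)),
    ("conv_4", "Convolution", (22, 22, 16)),
    ("relu_4", "ReLU", (22, 22, 16)),
    ("batchnorm_4", "Batch normalization", (22, 22, 16)),
    ("avgpool2d_4", "Average pooling", (22, 22, 16)),
    ("fc", "Fully connected", (1, 1, 2)),
    ("softmax", "SoftMax", (1, 1, 2)),
    ("classoutput", "Classification output", (1, 1, 2)),
]


@dataclass
class TrainingHistory:
    epochs: list[int] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)


class HemNet:
    """The shallow hemorrhage classifier (NumPy backend)."""

    INPUT_SHAPE = (256, 256, 3)

    def __init__(self, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.conv1 = nn.Conv2D(3, 16, 11, 3, rng, input_grad=False)
        self.relu1 = nn.ReLU()
        self.bn1 = nn.BatchNorm(16)
        self.pool1 = nn.AvgPool2D(2, 1)
        self.conv2 = nn.Conv2D(16, 16, 5, 2, rng)
        self.relu2 = nn.ReLU()
        self.bn2 = nn.BatchNorm(16)
        self.pool2 = nn.AvgPool2D(2, 1)
        self.pool_skip = nn.AvgPool2D(5, 2)
        self.bn_skip = nn.BatchNorm(16)
        self.conv3 = nn.Conv2D(16, 16, 11, 2, rng)
        self.relu3 = nn.ReLU()
        self.bn3 = nn.BatchNorm(16)
        self.pool3 = nn.AvgPool2D(2, 1)
        self.fc = nn.Dense(22 * 22 * 16, 2, rng)
        self._param_layers = [
            self.conv1, self.bn1, self.conv2, self.bn2, self.bn_skip,
            self.conv3, self.bn3, self.fc,
        ]
        self._audit()

    # -- architecture ------------------------------------------------------

    def _audit(self) -> None:
        summary = self.layer_summary()
        if len(summary) != len(REFERENCE_LAYOUT):
            raise ArchitectureError(
                f"{len(summary)} layers realized, expected {len(REFERENCE_LAYOUT)}"
            )
        for (name, _ltype, shape), (rname, _rtype, rshape) in zip(
            summary, REFERENCE_LAYOUT
        ):
            if rshape is not None and shape != rshape:
                raise ArchitectureError(
                    f"layer {rname}: realized shape {shape}, expected {rshape}"
                )

    def layer_summary(self) -> list[tuple[str, str, tuple[int, ...]]]:
        """Walk the graph symbolically and report every layer's output shape."""
        h, w, c = self.INPUT_SHAPE

        def conv_shape(hw: tuple[int, int], k: int, s: int) -> tuple[int, int]:
            return (nn.same_pad(hw[0], k, s)[0], nn.same_pad(hw[1], k, s)[0])

        rows: list[tuple[str, str, tuple[int, ...]]] = []
        rows.append(("input", "Image input", (h, w, c)))
        hw = conv_shape((h, w), 11, 3)
        rows.append(("conv_1", "Convolution", (*hw, 16)))
        rows.append(("relu_1", "ReLU", (*hw, 16)))
        rows.append(("batchnorm_1", "Batch normalization", (*hw, 16)))
        hw_a = conv_shape(hw, 2, 1)
        rows.append(("avgpool2d_1", "Average pooling", (*hw_a, 16)))
        hw2 = conv_shape(hw_a, 5, 2)
        rows.append(("conv_2", "Convolution", (*hw2, 16)))
        rows.append(("relu_2", "ReLU", (*hw2, 16)))
        rows.append(("batchnorm_2", "Batch normalization", (*hw2, 16)))
        hw_b = conv_shape(hw2, 2, 1)
        rows.append(("avgpool2d_2", "Average pooling", (*hw_b, 16)))
        hw_c = conv_shape(hw_a, 5, 2)
        rows.append(("avgpool2d_3", "Average pooling", (*hw_c, 16)))
        rows.append(("batchnorm_3", "Batch normalization", (*hw_c, 16)))
        if hw_b != hw_c:
            raise ArchitectureError(
                f"addition branches disagree: {hw_b} vs {hw_c}"
            )
        rows.append(("addition", "Addition", (*hw_b, 16)))
        hw3 = conv_shape(hw_b, 11, 2)
        rows.append(("conv_4", "Convolution", (*hw3, 16)))
        rows.append(("relu_4", "ReLU", (*hw3, 16)))
        rows.append(("batchnorm_4", "Batch normalization", (*hw3, 16)))
        hw4 = conv_shape(hw3, 2, 1)
        rows.append(("avgpool2d_4", "Average pooling", (*hw4, 16)))
        rows.append(("fc", "Fully connected", (1, 1, 2)))
        rows.append(("softmax", "SoftMax", (1, 1, 2)))
        rows.append(("classoutput", "Classification output", (1, 1, 2)))
        return rows

    @property
    def n_layers(self) -> int:
        return len(self.layer_summary())

    # -- forward/backward --------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Logits for a batch (N,256,256,3) of float32 patches in [0,1]."""
        if x.ndim != 4 or x.shape[1:] != self.INPUT_SHAPE:
            raise ValueError(
                f"expected (N, {self.INPUT_SHAPE}), got {x.shape}"
            )
        x = np.ascontiguousarray(x, dtype=F32)
        a = self.pool1.forward(
            self.bn1.forward(
                self.relu1.forward(self.conv1.forward(x, train), train), train
            ),
            train,
        )
        b = self.pool2.forward(
            self.bn2.forward(
                self.relu2.forward(self.conv2.forward(a, train), train), train
            ),
            train,
        )
        c = self.bn_skip.forward(self.pool_skip.forward(a, train), train)
        added = b + c
        d = self.pool3.forward(
            self.bn3.forward(
                self.relu3.forward(self.conv3.forward(added, train), train),
                train,
            ),
            train,
        )
        return self.fc.forward(d, train)

    def backward(self, dlogits: np.ndarray) -> None:
        dd = self.fc.backward(dlogits)
        dadded = self.conv3.backward(
            self.relu3.backward(self.bn3.backward(self.pool3.backward(dd)))
        )
        da_skip = self.pool_skip.backward(self.bn_skip.backward(dadded))
        da_main = self.conv2.backward(
            self.relu2.backward(self.bn2.backward(self.pool2.backward(dadded)))
        )
        da = da_skip + da_main
        self.conv1.backward(
            self.relu1.backward(self.bn1.backward(self.pool1.backward(da)))
        )

    # -- persistence -------------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for i, layer in enumerate(self._param_layers):
            for k, v in layer.params.items():
                state[f"{i}.{k}"] = v
            if isinstance(layer, nn.BatchNorm):
                state[f"{i}.running_mean"] = layer.running_mean
                state[f"{i}.running_var"] = layer.running_var
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self._param_layers):
            for k in layer.params:
                layer.params[k][...] = state[f"{i}.{k}"]
            if isinstance(layer, nn.BatchNorm):
                layer.running_mean = state[f"{i}.running_mean"].copy()
                layer.running_var = state[f"{i}.running_var"].copy()

    def save(self, path: str | Path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        np.savez_compressed(path, **self.state_dict())

    @classmethod
    def load(cls, path: str | Path) -> "HemNet":
        model = cls()
        with np.load(path) as data:
            model.load_state_dict(dict(data))
        return model


def build_hemnet(seed: int = 0) -> HemNet:
    """Construct HemNet; raises ArchitectureError on any shape mismatch."""
    return HemNet(seed=seed)


def _as_batches(n: int, batch_size: int) -> list[np.ndarray]:
    idx = np.arange(n)
    return [idx[i: i + batch_size] for i in range(0, n, batch_size)]


class _BatchFeeder:
    """Reusable uint8 -> float32 staging buffers for batched passes."""

    def __init__(self, batch_size: int, shape: tuple[int, ...]):
        self._u8 = np.zeros((batch_size, *shape), dtype=np.uint8)
        self._f32 = np.zeros((batch_size, *shape), dtype=F32)

    def load(self, patches: np.ndarray, idx: np.ndarray) -> np.ndarray:
        m = len(idx)
        if patches.dtype == np.uint8:
            np.take(patches, idx, axis=0, out=self._u8[:m])
            np.divide(self._u8[:m], 255.0, out=self._f32[:m], casting="unsafe")
        else:
            np.take(patches, idx, axis=0, out=self._f32[:m])
        return self._f32[:m]


def predict(model: HemNet, patches: np.ndarray, batch_size: int = 32) -> np.ndarray:
    """p(hemorrhage) for one patch (256,256,3) or a batch (N,256,256,3)."""
    x = np.asarray(patches)
    single = x.ndim == 3
    if single:
        x = x[None]
    feeder = _BatchFeeder(batch_size, x.shape[1:])
    probs = []
    for idx in _as_batches(x.shape[0], batch_size):
        probs.append(nn.softmax(model.forward(feeder.load(x, idx), train=False)))
    p = np.concatenate(probs)[:, 1]
    return float(p[0]) if single else p


def train(
    model: HemNet,
    patches: np.ndarray,
    labels: np.ndarray,
    lr: float = 0.01,
    epochs: int = 15,
    batch_size: int = 32,
    momentum: float = 0.9,
    val_fraction: float = 0.1,
    seed: int = 0,
) -> TrainingHistory:
    """Minimize softmax cross-entropy with momentum SGD; returns the history.

    The data are shuffled once with the given seed and the batch partition
    is then fixed across epochs, so runs with the same seed are bitwise
    reproducible and a zero learning rate yields an exactly flat training
    loss.  The trailing val_fraction of the shuffle becomes the validation
    split, evaluated in inference mode after each epoch.
    """
    y = np.asarray(labels, dtype=np.int64)
    if np.unique(y).size < 2:
        raise ValueError("training set must contain both classes")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(y))
    n_val = int(round(val_fraction * len(y)))
    train_idx = order[: len(y) - n_val]
    val_idx = order[len(y) - n_val:]
    batches = _as_batches(len(train_idx), batch_size)
    opt = nn.SGD(
        [l for l in model._param_layers], lr=lr, momentum=momentum
    )
    feeder = _BatchFeeder(batch_size, patches.shape[1:])
    history = TrainingHistory()
    for epoch in range(epochs):
        losses, accs = [], []
        for bidx in batches:
            idx = train_idx[bidx]
            xb = feeder.load(patches, idx)
            yb = y[idx]
            logits = model.forward(xb, train=True)
            probs = nn.softmax(logits)
            losses.append(nn.cross_entropy(probs, yb))
            accs.append(float((probs.argmax(axis=1) == yb).mean()))
            model.backward(nn.softmax_ce_grad(probs, yb))
            opt.step()
        history.epochs.append(epoch)
        history.train_loss.append(float(np.mean(losses)))
        history.train_acc.append(float(np.mean(accs)))
        if n_val:
            vprobs = predict(model, patches[val_idx], batch_size)
            vfull = np.stack([1 - vprobs, vprobs], axis=1)
            history.val_loss.append(nn.cross_entropy(vfull, y[val_idx]))
            history.val_acc.append(
                float(((vprobs >= 0.5).astype(int) == y[val_idx]).mean())
            )
    return history
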