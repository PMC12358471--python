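"""The customized 1-D CNN: architecture, verification, training, features.

The network is a five-stage convolutional stack — 32/64/128/256/512 filters
of size 3 (valid padding, stride 1) with leaky-ReLU activations, max
pooling after the first two convolutions and average pooling after the next
two, batch normalization after the first convolution and 0.5 dropout after
the second and third pooling stages — closed by a global average pool and a
one-unit sigmoid dense head.  The 512-wide global-average-pool activations
are the "automated" features fused with the handcrafted ones.

Two architecture verification helpers, :func:`count_parameters` and
:func:`output_shapes`, derive every per-layer parameter count and output
length symbolically, without instantiating weights.  Batch-normalization
parameters are counted as 4 per channel (scale, shift and the two running
statistics); with 6 input channels and input length 5120 the stack totals
524,449 parameters.  The prediction pipeline itself runs the same stack on
the 1-channel surrogate signal (15 s at 256 Hz = 3840 samples), optionally
with proportionally narrower filter banks for CPU-scale training.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import _nn
from .io import Segment

__all__ = [
    "LayerSpec",
    "ArchitectureSpec",
    "TrainConfig",
    "TABLE_FILTERS",
    "REDUCED_FILTERS",
    "build_architecture",
    "count_parameters",
    "output_shapes",
    "architecture_report",
    "Cnn1DModel",
    "train",
    "extract_features",
]

TABLE_FILTERS = (32, 64, 128, 256, 512)
#: 1/8-width filter banks for CPU-scale experiments (64-wide features)
REDUCED_FILTERS = (4, 8, 16, 32, 64)

_KINDS = {
    "conv1d", "batchnorm", "leaky_relu", "maxpool", "avgpool",
    "dropout", "global_avgpool", "dense",
}


@dataclass(frozen=True)
class LayerSpec:
    kind: str
    filters: int = 0            # conv / dense output width
    kernel: int = 3             # conv
    pool: int = 2               # max/avg pool
    dropout_rate: float = 0.5
    negative_slope: float = 0.01

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown layer kind {self.kind!r}")
        if self.kind == "conv1d" and self.kernel < 1:
            raise ValueError("conv kernel must be >= 1")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")


@dataclass(frozen=True)
class ArchitectureSpec:
    in_channels: int
    input_length: int
    layers: tuple[LayerSpec, ...]

    @property
    def feature_width(self) -> int:
        """Width of the global-average-pool feature vector."""
        ch = self.in_channels
        for l in self.layers:
            if l.kind == "conv1d":
                ch = l.filters
            if l.kind == "global_avgpool":
                return ch
        raise ValueError("architecture has no global_avgpool layer")


@dataclass
class TrainConfig:
    """Binary cross-entropy + Adam training settings."""

    epochs: int = 50
    batch_size: int = 32
    learning_rate: float = 1e-3
    validation_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not 0 <= self.validation_fraction < 1:
            raise ValueError("validation_fraction must be in [0, 1)")


def build_architecture(
    in_channels: int = 6,
    input_length: int = 5120,
    filters: tuple[int, ...] = TABLE_FILTERS,
    kernel: int = 3,
    dropout_rate: float = 0.5,
    negative_slope: float = 0.01,
) -> ArchitectureSpec:
    """The 19-layer stack; shapes are validated at build time.

    Defaults (6 channels x 5120 samples, 32..512 filters) are the exact
    published configuration; the pipeline uses ``in_channels=1,
    input_length=3840`` and optionally :data:`REDUCED_FILTERS`.
    """
    if in_channels < 1:
        raise ValueError("in_channels must be >= 1")
    if len(filters) != 5:
        raise ValueError("the architecture takes exactly 5 convolution widths")
    f1, f2, f3, f4, f5 = filters
    ls = [
        LayerSpec("conv1d", filters=f1, kernel=kernel),
        LayerSpec("batchnorm"),
        LayerSpec("leaky_relu", negative_slope=negative_slope),
        LayerSpec("maxpool"),
        LayerSpec("conv1d", filters=f2, kernel=kernel),
        LayerSpec("leaky_relu", negative_slope=negative_slope),
        LayerSpec("maxpool"),
        LayerSpec("dropout", dropout_rate=dropout_rate),
        LayerSpec("conv1d", filters=f3, kernel=kernel),
        LayerSpec("leaky_relu", negative_slope=negative_slope),
        LayerSpec("avgpool"),
        LayerSpec("dropout", dropout_rate=dropout_rate),
        LayerSpec("conv1d", filters=f4, kernel=kernel),
        LayerSpec("leaky_relu", negative_slope=negative_slope),
        LayerSpec("avgpool"),
        LayerSpec("conv1d", filters=f5, kernel=kernel),
        LayerSpec("leaky_relu", negative_slope=negative_slope),
        LayerSpec("global_avgpool"),
        LayerSpec("dense", filters=1),
    ]
    spec = ArchitectureSpec(in_channels, input_length, tuple(ls))
    output_shapes(spec)  # raises if any layer underflows
    return spec


def output_shapes(spec: ArchitectureSpec) -> list[dict]:
    """Per-layer output (length, channels); valid-conv L-k+1, pools floor(L/2).

    Raises with the failing layer named if any length underflows.
    """
    length: int | None = spec.input_length
    ch = spec.in_channels
    rows = []
    for i, l in enumerate(spec.layers):
        if l.kind == "conv1d":
            if length is None:
                raise ValueError(f"layer {i} (conv1d): no time axis left")
            length = length - l.kernel + 1
            ch = l.filters
        elif l.kind in ("maxpool", "avgpool"):
            if length is None:
                raise ValueError(f"layer {i} ({l.kind}): no time axis left")
            length = length // l.pool
        elif l.kind == "global_avgpool":
            length = None
        elif l.kind == "dense":
            ch = l.filters
        if length is not None and length < 1:
            raise ValueError(
                f"layer {i} ({l.kind}) underflows: output length {length} "
                f"for input_length={spec.input_length}"
            )
        rows.append({"layer": i, "kind": l.kind, "length": length, "channels": ch})
    return rows


def count_parameters(spec: ArchitectureSpec) -> tuple[list[int], int]:
    """Per-layer parameter counts and their total.

    conv: filters x (in_channels x kernel + 1); batchnorm: 4 x channels
    (scale, shift, running mean/variance); dense: filters x (in + 1);
    activations, pooling and dropout are parameter-free.
    """
    ch = spec.in_channels
    counts = []
    for l in spec.layers:
        if l.kind == "conv1d":
            counts.append(l.filters * (ch * l.kernel + 1))
            ch = l.filters
        elif l.kind == "batchnorm":
            counts.append(4 * ch)
        elif l.kind == "dense":
            counts.append(l.filters * (ch + 1))
            ch = l.filters
        else:
            counts.append(0)
    return counts, sum(counts)


def architecture_report(spec: ArchitectureSpec) -> pd.DataFrame:
    """Layer-by-layer shape/parameter table (the printable verification)."""
    shapes = output_shapes(spec)
    counts, total = count_parameters(spec)
    df = pd.DataFrame(
        {
            "layer": [s["kind"] for s in shapes],
            "output_length": [s["length"] for s in shapes],
            "output_channels": [s["channels"] for s in shapes],
            "parameters": counts,
        }
    )
    df.attrs["total_parameters"] = total
    return df


# ---------------------------------------------------------------------------
# runnable model
# ---------------------------------------------------------------------------

class Cnn1DModel:
    """Instantiated network for an :class:`ArchitectureSpec`."""

    def __init__(self, spec: ArchitectureSpec, seed: int = 0):
        self.spec = spec
        self.seed = seed
        rng = np.random.default_rng(seed)
        self._dropout_rng = np.random.default_rng(rng.integers(2**31))
        self.layers: list[_nn.Layer] = []
        self._gap_index = None
        ch = spec.in_channels
        for i, l in enumerate(spec.layers):
            if l.kind == "conv1d":
                self.layers.append(_nn.Conv1D(ch, l.filters, l.kernel, rng))
                ch = l.filters
            elif l.kind == "batchnorm":
                self.layers.append(_nn.BatchNorm1D(ch))
            elif l.kind == "leaky_relu":
                self.layers.append(_nn.LeakyReLU(l.negative_slope))
            elif l.kind == "maxpool":
                self.layers.append(_nn.MaxPool1D(l.pool))
            elif l.kind == "avgpool":
                self.layers.append(_nn.AvgPool1D(l.pool))
            elif l.kind == "dropout":
                self.layers.append(_nn.Dropout(l.dropout_rate, self._dropout_rng))
            elif l.kind == "global_avgpool":
                self.layers.append(_nn.GlobalAvgPool1D())
                self._gap_index = i
            elif l.kind == "dense":
                self.layers.append(_nn.Dense(ch, l.filters, rng))
                ch = l.filters
        if self._gap_index is None:
            raise ValueError("architecture must contain a global_avgpool layer")
        self.history: dict[str, list[float]] = {}
        # global input standardization (volt-scale EEG would otherwise give
        # vanishing activations); fit from the training set
        self.input_mean_: float = 0.0
        self.input_scale_: float = 1.0

    def _forward(self, x: np.ndarray, train: bool,
                 stop_at_gap: bool = False) -> np.ndarray:
        h = ((x - self.input_mean_) / self.input_scale_).astype(_nn.F)
        for i, layer in enumerate(self.layers):
            h = layer.forward(h, train)
            if stop_at_gap and i == self._gap_index:
                return h
        return h

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        logits = self._forward(np.asarray(x), train=False)
        return _nn.sigmoid(logits[:, 0])

    def predict(self, x: np.ndarray) -> np.ndarray:
        return (self.predict_proba(x) >= 0.5).astype(int)

    def features(self, x: np.ndarray) -> np.ndarray:
        """Global-average-pool activations (pre-dense), dropout disabled."""
        return self._forward(np.asarray(x), train=False, stop_at_gap=True)

    def fit(self, x: np.ndarray, y: np.ndarray, config: TrainConfig) -> "Cnn1DModel":
        x = np.asarray(x, dtype=_nn.F)
        y = np.asarray(y, dtype=_nn.F).ravel()
        classes = np.unique(y)
        if classes.size < 2:
            raise ValueError("training data must contain both classes")
        self.input_mean_ = float(x.mean())
        self.input_scale_ = float(x.std()) or 1.0
        rng = np.random.default_rng(config.seed)
        n = x.shape[0]
        # stratified validation split
        val_idx = []
        if config.validation_fraction > 0:
            for c in classes:
                rows = np.flatnonzero(y == c)
                rng.shuffle(rows)
                n_val = max(1, int(round(config.validation_fraction * rows.size)))
                val_idx.extend(rows[:n_val])
        val_idx = np.sort(np.array(val_idx, dtype=int))
        train_idx = np.setdiff1d(np.arange(n), val_idx)
        xt, yt = x[train_idx], y[train_idx]
        xv, yv = x[val_idx], y[val_idx]

        opt = _nn.Adam(self.layers, lr=config.learning_rate)
        # history entries are end-of-epoch evaluations of the current model
        # (dropout off, running batchnorm statistics), on train and val sets
        hist = {"loss": [], "accuracy": [], "val_loss": [], "val_accuracy": []}
        for _ in range(config.epochs):
            order = rng.permutation(len(xt))
            for i0 in range(0, len(xt), config.batch_size):
                idx = order[i0 : i0 + config.batch_size]
                xb, yb = xt[idx], yt[idx]
                logits = self._forward(xb, train=True)[:, 0]
                p = _nn.sigmoid(logits)
                g = ((p - yb) / len(idx)).astype(_nn.F)[:, None]
                for layer in reversed(self.layers):
                    g = layer.backward(g)
                opt.step()
            pt = self.predict_proba(xt)
            hist["loss"].append(_nn.bce_loss(pt, yt))
            hist["accuracy"].append(float(((pt >= 0.5) == (yt >= 0.5)).mean()))
            if len(xv):
                pv = self.predict_proba(xv)
                hist["val_loss"].append(_nn.bce_loss(pv, yv))
                hist["val_accuracy"].append(float(((pv >= 0.5) == (yv >= 0.5)).mean()))
        self.history = hist
        return self

    # -- checkpointing ------------------------------------------------------

    def save(self, path: str | Path) -> None:
        arrays = {}
        for i, layer in enumerate(self.layers):
            for k, v in layer.params.items():
                arrays[f"{i}:{k}"] = v
            if isinstance(layer, _nn.BatchNorm1D):
                arrays[f"{i}:running_mean"] = layer.running_mean
                arrays[f"{i}:running_var"] = layer.running_var
        spec_json = json.dumps(
            {
                "in_channels": self.spec.in_channels,
                "input_length": self.spec.input_length,
                "layers": [asdict(l) for l in self.spec.layers],
                "seed": self.seed,
                "input_mean": self.input_mean_,
                "input_scale": self.input_scale_,
            }
        )
        np.savez(path, __spec__=np.array(spec_json), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "Cnn1DModel":
        data = np.load(path, allow_pickle=False)
        meta = json.loads(str(data["__spec__"]))
        spec = ArchitectureSpec(
            meta["in_channels"], meta["input_length"],
            tuple(LayerSpec(**l) for l in meta["layers"]),
        )
        model = cls(spec, seed=meta["seed"])
        model.input_mean_ = meta.get("input_mean", 0.0)
        model.input_scale_ = meta.get("input_scale", 1.0)
        for i, layer in enumerate(model.layers):
            for k in layer.params:
                layer.params[k][...] = data[f"{i}:{k}"]
            if isinstance(layer, _nn.BatchNorm1D):
                layer.running_mean[...] = data[f"{i}:running_mean"]
                layer.running_var[...] = data[f"{i}:running_var"]
        return model


def _to_batch(segments, spec: ArchitectureSpec) -> np.ndarray:
    if isinstance(segments, np.ndarray):
        arr = segments
        if arr.ndim == 2:
            arr = arr[None]
    else:
        arr = np.stack([s.samples for s in segments])
    if arr.shape[1] != spec.in_channels or arr.shape[2] != spec.input_length:
        raise ValueError(
            f"segments of shape {arr.shape[1:]} do not match architecture "
            f"({spec.in_channels}, {spec.input_length})"
        )
    return arr


def train(
    spec: ArchitectureSpec,
    segments,
    labels: np.ndarray,
    config: TrainConfig | None = None,
) -> tuple[Cnn1DModel, dict[str, list[float]]]:
    """Train the network on labeled segments; returns (model, history)."""
    config = config or TrainConfig()
    x = _to_batch(segments, spec)
    model = Cnn1DModel(spec, seed=config.seed)
    model.fit(x, np.asarray(labels), config)
    return model, model.history


def extract_features(model: Cnn1DModel, segment: Segment | np.ndarray) -> np.ndarray:
    """Global-average-pool feature vector(s); (F,) for one segment, (n, F) for a batch."""
    if isinstance(segment, Segment):
        return model.features(segment.samples[None])[0]
    arr = np.asarray(segment)
    if arr.ndim == 2:
        return model.features(arr[None])[0]
    return model.features(arr)
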