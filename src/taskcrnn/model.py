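"""The CRNN classifier and its analytic inspectors.

Architecture, front to back, for input ``[20, 78, 93, 76, 1]``:

* four time-distributed 3D conv blocks (conv -> batch-norm -> ReLU, valid
  padding): 7x7x7/32 stride 2, 3x3x3/64 stride 2, 3x3x3/64 stride 2, and a
  final *full* convolution 8x10x8/64 whose kernel exactly covers the
  incoming feature map, ending at ``[20, 1, 1, 1, 64]``;
* squeeze to a ``[20, 64]`` feature sequence and run a single bidirectional
  LSTM with 64 units per direction (concatenated to 128), dropout 0.2 on its
  outputs during training;
* additive attention pooling over the 20 time steps to one 128-vector;
* dense 64 with ReLU, dense 7 with softmax.

``count_parameters`` and ``shape_chain`` compute the per-layer parameter
tally and the stage-by-stage shape chain analytically, without allocating
any tensors, so the full-size architecture can be audited instantly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterator

import numpy as np

from taskcrnn.errors import ConfigError, ShapeError
from taskcrnn import nn
from taskcrnn.nn import DTYPE, conv_output_size


@dataclass(frozen=True)
class ConvBlockConfig:
    """One conv block: kernel extents, output channels, isotropic stride."""

    kernel: tuple[int, int, int]
    out_channels: int
    stride: int = 1

    def __post_init__(self) -> None:
        if any(k < 1 for k in self.kernel):
            raise ConfigError(f"kernel dims must be >= 1, got {self.kernel}")
        if self.stride < 1 or self.out_channels < 1:
            raise ConfigError("stride and out_channels must be >= 1")


DEFAULT_CONV_BLOCKS: tuple[ConvBlockConfig, ...] = (
    ConvBlockConfig((7, 7, 7), 32, 2),
    ConvBlockConfig((3, 3, 3), 64, 2),
    ConvBlockConfig((3, 3, 3), 64, 2),
    ConvBlockConfig((8, 10, 8), 64, 1),
)


@dataclass(frozen=True)
class CrnnConfig:
    """Full hyperparameter set of the CRNN."""

    conv_blocks: tuple[ConvBlockConfig, ...] = DEFAULT_CONV_BLOCKS
    lstm_units: int = 64
    lstm_dropout: float = 0.2
    attention: str = "additive"  # "additive" | "elementwise"
    attention_dim: int = 64
    dense_units: int = 64
    n_classes: int = 7
    input_shape: tuple[int, int, int, int, int] = (20, 78, 93, 76, 1)
    bn_eps: float = 1e-3
    bn_momentum: float = 0.99

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ConfigError("n_classes must be >= 2")
        if len(self.input_shape) != 5:
            raise ConfigError("input_shape must be [T, X, Y, Z, C]")
        if self.attention not in ("additive", "elementwise"):
            raise ConfigError("attention must be 'additive' or 'elementwise'")
        if not self.conv_blocks:
            raise ConfigError("at least one conv block is required")

    @property
    def feature_dim(self) -> int:
        """Width of the pooled feature entering the classifier (2 x LSTM units)."""
        return 2 * self.lstm_units

    def to_dict(self) -> dict:
        d = asdict(self)
        d["conv_blocks"] = [
            {"kernel": list(b.kernel), "out_channels": b.out_channels, "stride": b.stride}
            for b in self.conv_blocks
        ]
        d["input_shape"] = list(self.input_shape)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CrnnConfig":
        d = dict(d)
        if "conv_blocks" in d:
            d["conv_blocks"] = tuple(
                ConvBlockConfig(tuple(b["kernel"]), b["out_channels"], b.get("stride", 1))
                for b in d["conv_blocks"]
            )
        if "input_shape" in d:
            d["input_shape"] = tuple(d["input_shape"])
        return cls(**d)


@dataclass(frozen=True)
class ShapeChainReport:
    """Ordered per-stage output shapes from input to class probabilities."""

    stages: tuple[tuple[str, tuple[int, ...]], ...]

    @property
    def final_cnn_shape(self) -> tuple[int, ...]:
        conv_stages = [s for name, s in self.stages if name.startswith("conv")]
        return conv_stages[-1]

    def as_table(self) -> str:
        width = max(len(name) for name, _ in self.stages)
        return "\n".join(f"{name:<{width}}  {list(shape)}" for name, shape in self.stages)

    def to_dict(self) -> dict:
        return {name: list(shape) for name, shape in self.stages}


@dataclass(frozen=True)
class LayerParamCount:
    name: str
    trainable: int
    non_trainable: int = 0

    @property
    def total(self) -> int:
        return self.trainable + self.non_trainable


@dataclass(frozen=True)
class ParamCountReport:
    """Per-layer and total trainable / non-trainable parameter tallies."""

    entries: tuple[LayerParamCount, ...]

    @property
    def trainable(self) -> int:
        return sum(e.trainable for e in self.entries)

    @property
    def non_trainable(self) -> int:
        return sum(e.non_trainable for e in self.entries)

    @property
    def total(self) -> int:
        return self.trainable + self.non_trainable

    def as_table(self) -> str:
        width = max(len(e.name) for e in self.entries)
        lines = [f"{'layer':<{width}}  {'trainable':>10}  {'non-train':>10}"]
        for e in self.entries:
            lines.append(f"{e.name:<{width}}  {e.trainable:>10,}  {e.non_trainable:>10,}")
        lines.append(
            f"{'TOTAL':<{width}}  {self.trainable:>10,}  {self.non_trainable:>10,}"
            f"  (all: {self.total:,})"
        )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "layers": [
                {"name": e.name, "trainable": e.trainable, "non_trainable": e.non_trainable}
                for e in self.entries
            ],
            "trainable": self.trainable,
            "non_trainable": self.non_trainable,
            "total": self.total,
        }


def shape_chain(config: CrnnConfig) -> ShapeChainReport:
    """Stage-by-stage output shapes under valid-convolution arithmetic.

    Raises a ConfigError naming the offending conv block if any spatial
    dimension would collapse below 1.
    """
    t, *spatial, c = config.input_shape
    stages: list[tuple[str, tuple[int, ...]]] = [("input", tuple(config.input_shape))]
    for idx, block in enumerate(config.conv_blocks, start=1):
        new_spatial = []
        for n, k in zip(spatial, block.kernel):
            if k > n:
                raise ConfigError(
                    f"conv{idx}: kernel {block.kernel} exceeds incoming feature map "
                    f"{tuple(spatial)}"
                )
            new_spatial.append(conv_output_size(n, k, block.stride))
        spatial = new_spatial
        c = block.out_channels
        stages.append((f"conv{idx}", (t, *spatial, c)))
    last = config.conv_blocks[-1]
    if tuple(last.kernel) != tuple(stages[-2][1][1:4]):
        raise ConfigError(
            f"last conv block must be a full convolution: kernel {last.kernel} != "
            f"incoming feature map {tuple(stages[-2][1][1:4])}"
        )
    stages.append(("sequence", (t, c)))
    stages.append(("bilstm", (t, 2 * config.lstm_units)))
    stages.append(("attention", (config.feature_dim,)))
    stages.append(("dense", (config.dense_units,)))
    stages.append(("softmax", (config.n_classes,)))
    return ShapeChainReport(tuple(stages))


def count_parameters(config: CrnnConfig) -> ParamCountReport:
    """Analytic parameter tally; no tensor is allocated.

    Conventions (matching the implementation): conv = k^3*Cin*Cout + Cout;
    batch-norm = 2C trainable (scale, shift) + 2C non-trainable (moving mean
    and variance); LSTM per direction = 4*((in+H)*H + H) with one bias
    vector per gate; additive attention = D*A + A + A; dense = in*out + out.
    """
    shape_chain(config)  # validates the stack
    entries: list[LayerParamCount] = []
    c_in = config.input_shape[4]
    for idx, block in enumerate(config.conv_blocks, start=1):
        kvol = int(np.prod(block.kernel))
        entries.append(LayerParamCount(f"conv{idx}", kvol * c_in * block.out_channels + block.out_channels))
        entries.append(
            LayerParamCount(f"bn{idx}", 2 * block.out_channels, non_trainable=2 * block.out_channels)
        )
        c_in = block.out_channels
    h = config.lstm_units
    per_direction = 4 * ((c_in + h) * h + h)
    entries.append(LayerParamCount("bilstm", 2 * per_direction))
    d = config.feature_dim
    if config.attention == "additive":
        a = config.attention_dim
        entries.append(LayerParamCount("attention", d * a + a + a))
    else:
        entries.append(LayerParamCount("attention", 0))
    entries.append(LayerParamCount("dense1", d * config.dense_units + config.dense_units))
    entries.append(
        LayerParamCount("dense2", config.dense_units * config.n_classes + config.n_classes)
    )
    return ParamCountReport(tuple(entries))


def reduced_config(
    input_shape: tuple[int, int, int, int, int] = (20, 20, 24, 20, 1),
    channels: tuple[int, int, int] = (16, 32, 32),
    lstm_units: int = 32,
    attention_dim: int = 32,
    dense_units: int = 32,
) -> CrnnConfig:
    """A small CRNN with the same topology for desk-scale experiments.

    Two strided blocks (5x5x5 then 3x3x3, stride 2) followed by a full
    convolution sized to whatever feature map remains, mirroring the
    full-size stack's large-receptive-field -> conventional -> full-conv
    progression at a fraction of the cost.
    """
    spatial = list(input_shape[1:4])
    blocks = []
    for kernel, ch, stride in (((5, 5, 5), channels[0], 2), ((3, 3, 3), channels[1], 2)):
        for n, k in zip(spatial, kernel):
            if k > n:
                raise ConfigError(f"input {input_shape} too small for the reduced stack")
        blocks.append(ConvBlockConfig(kernel, ch, stride))
        spatial = [conv_output_size(n, k, stride) for n, k in zip(spatial, kernel)]
    blocks.append(ConvBlockConfig(tuple(spatial), channels[2], 1))  # full conv
    return CrnnConfig(
        conv_blocks=tuple(blocks),
        lstm_units=lstm_units,
        attention_dim=attention_dim,
        dense_units=dense_units,
        input_shape=tuple(input_shape),
    )


class CRNN:
    """The convolutional-recurrent classifier, built from a CrnnConfig.

    All computation is NumPy; ``forward`` accepts a batch
    ``[B, T, X, Y, Z, C]`` and returns logits ``[B, n_classes]``.  Gradients
    accumulate in each layer's ``grads`` dict via ``backward``.
    """

    def __init__(self, config: CrnnConfig, seed: int = 0) -> None:
        self.config = config
        self.seed = seed
        chain = shape_chain(config)  # validates
        rng = np.random.default_rng(seed)
        self.conv_blocks: list[tuple[nn.TimeDistributedConv3d, nn.BatchNorm, nn.ReLU]] = []
        c_in = config.input_shape[4]
        for block in config.conv_blocks:
            conv = nn.TimeDistributedConv3d(c_in, block.out_channels, block.kernel, block.stride, rng)
            bn = nn.BatchNorm(block.out_channels, eps=config.bn_eps, momentum=config.bn_momentum)
            self.conv_blocks.append((conv, bn, nn.ReLU()))
            c_in = block.out_channels
        self.bilstm = nn.BiLSTM(c_in, config.lstm_units, rng)
        self.dropout = nn.Dropout(config.lstm_dropout, np.random.default_rng(rng.integers(2**31)))
        if config.attention == "additive":
            self.attention: nn.Layer = nn.AdditiveAttention(config.feature_dim, config.attention_dim, rng)
        else:
            self.attention = nn.ElementwiseSoftmaxAttention()
        self.dense1 = nn.Dense(config.feature_dim, config.dense_units, relu=True, rng=rng)
        self.dense2 = nn.Dense(config.dense_units, config.n_classes, relu=False, rng=rng)
        self._chain = chain

    # -- plumbing ---------------------------------------------------------

    def layers(self) -> Iterator[nn.Layer]:
        for conv, bn, relu in self.conv_blocks:
            yield conv
            yield bn
            yield relu
        yield self.bilstm
        yield self.dropout
        yield self.attention
        yield self.dense1
        yield self.dense2

    def named_params(self) -> Iterator[tuple[str, nn.Layer, str]]:
        """(unique name, owning layer, key) for every trainable array."""
        for i, layer in enumerate(self.layers()):
            for key in layer.params:
                yield f"L{i:02d}.{type(layer).__name__}.{key}", layer, key

    def zero_grads(self) -> None:
        for layer in self.layers():
            layer.zero_grads()

    def n_parameters(self) -> tuple[int, int]:
        """(trainable, non_trainable) counted from the allocated arrays."""
        trainable = sum(int(l.params[k].size) for _, l, k in self.named_params())
        non_trainable = sum(
            int(bn.moving_mean.size + bn.moving_var.size) for _, bn, _relu in self.conv_blocks
        )
        return trainable, non_trainable

    # -- computation ------------------------------------------------------

    def cnn_forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Conv stack then squeeze of the unit spatial dims: ``[B, T, C]``."""
        x = np.asarray(x, dtype=DTYPE)
        if x.ndim == 5:  # single sample
            x = x[None]
        if x.shape[1:] != tuple(self.config.input_shape):
            raise ShapeError(
                f"expected input {self.config.input_shape} (plus batch axis), got {x.shape[1:]}"
            )
        for conv, bn, relu in self.conv_blocks:
            x = relu.forward(bn.forward(conv.forward(x, training), training), training)
        b, t = x.shape[:2]
        if x.shape[2:5] != (1, 1, 1):
            raise ShapeError(f"conv stack did not collapse spatial dims: {x.shape}")
        self._pre_squeeze_shape = x.shape
        return x.reshape(b, t, x.shape[5])

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        seq = self.cnn_forward(x, training)
        h = self.dropout.forward(self.bilstm.forward(seq, training), training)
        ctx = self.attention.forward(h, training)
        return self.dense2.forward(self.dense1.forward(ctx, training), training)

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.dense1.backward(self.dense2.backward(dlogits))
        d = self.bilstm.backward(self.dropout.backward(self.attention.backward(d)))
        d = d.reshape(self._pre_squeeze_shape)
        for conv, bn, relu in reversed(self.conv_blocks):
            d = conv.backward(bn.backward(relu.backward(d)))

    def loss_and_grads(self, x: np.ndarray, labels: np.ndarray) -> float:
        """One training step's loss; gradients accumulate in the layers."""
        self.zero_grads()
        logits = self.forward(x, training=True)
        loss, dlogits = nn.cross_entropy(logits, labels)
        self.backward(dlogits)
        return loss

    def predict_proba(self, x: np.ndarray, batch_size: int = 8) -> np.ndarray:
        x = np.asarray(x, dtype=DTYPE)
        if x.ndim == 5:
            x = x[None]
        out = [
            nn.softmax(self.forward(x[i : i + batch_size], training=False), axis=-1)
            for i in range(0, x.shape[0], batch_size)
        ]
        return np.concatenate(out, axis=0)

    def predict(self, x: np.ndarray, batch_size: int = 8) -> np.ndarray:
        return self.predict_proba(x, batch_size).argmax(axis=1)

    # -- state ------------------------------------------------------------

    def get_state(self) -> dict[str, np.ndarray]:
        state = {name: layer.params[key].copy() for name, layer, key in self.named_params()}
        for i, (conv, bn, relu) in enumerate(self.conv_blocks):
            state[f"bn{i}.moving_mean"] = bn.moving_mean.copy()
            state[f"bn{i}.moving_var"] = bn.moving_var.copy()
        return state

    def set_state(self, state: dict[str, np.ndarray]) -> None:
        for name, layer, key in self.named_params():
            layer.params[key] = np.array(state[name], dtype=DTYPE)
        for i, (conv, bn, relu) in enumerate(self.conv_blocks):
            bn.moving_mean = np.array(state[f"bn{i}.moving_mean"], dtype=DTYPE)
            bn.moving_var = np.array(state[f"bn{i}.moving_var"], dtype=DTYPE)


def save_checkpoint(model: CRNN, path) -> None:
    """One-file checkpoint: parameters + embedded config and seed."""
    meta = json.dumps({"config": model.config.to_dict(), "seed": model.seed})
    np.savez(path, __meta__=np.array(meta), **model.get_state())


def load_checkpoint(path) -> CRNN:
    with np.load(path, allow_pickle=False) as archive:
        meta = json.loads(str(archive["__meta__"]))
        state = {k: archive[k] for k in archive.files if k != "__meta__"}
    model = CRNN(CrnnConfig.from_dict(meta["config"]), seed=meta["seed"])
    model.set_state(state)
    return model
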