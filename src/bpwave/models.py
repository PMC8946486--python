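"""Network definitions: context aggregation network and LSTM baseline.

The context aggregation network (CAN) regresses the 250-sample
time-domain pressure waveform from the 4 x 250 spectral input.  Its
body is a ladder of same-size dilated convolutions whose dilation
doubles each block (1, 2, 4, ..., 128 along the time axis), so the
temporal receptive field covers the whole 2 s window without pooling.
Each block is convolution -> batch normalization -> adaptive
normalization -> leaky rectifier (slope 0.2).  A plain 3 x 3
convolution block follows the ladder, and a regression head collapses
the 4-row feature image to the length-250 output — ten layer groups in
total.

The baseline is a sequence-to-sequence LSTM taking the two raw
time-domain channels (ECG, PPG) and emitting one output channel
through a linear head.

Dilation is applied along the time axis only: the signal-channel axis
has just 4 rows, on which the printed paddings (2, 4, ..., 128) would
be geometrically impossible, so they are read as time-axis paddings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._nn import (
    LSTM,
    AdaptiveNorm,
    BatchNorm2D,
    Conv2D,
    LeakyReLU,
    RowCollapse,
    Sequential,
    TimeLinear,
)

__all__ = [
    "CANSpec",
    "LSTMSpec",
    "AdaptiveNormSpec",
    "CANNetwork",
    "LSTMNetwork",
    "build_can",
    "build_lstm",
    "half_mse_loss",
]

_DEFAULT_DILATIONS = (1, 2, 4, 8, 16, 32, 64, 128)


@dataclass
class CANSpec:
    """Architecture of the context aggregation network.

    Defaults give the full-size network: 4 x 250 inputs, 32 feature
    channels, eight dilated blocks with dilation 2^(k-1) in block k
    (block 1 is the 2 x 2 entry convolution at dilation 1), a plain
    3 x 3 convolution block, and a regression head reducing the
    ``pre_regression_channels`` feature image to 250 outputs.
    """

    in_rows: int = 4
    in_cols: int = 250
    channels: int = 32
    n_dilated_blocks: int = 8
    dilation_schedule: tuple = _DEFAULT_DILATIONS
    first_kernel: tuple = (2, 2)
    body_kernel: tuple = (3, 3)
    leaky_slope: float = 0.2
    pre_regression_channels: int = 3
    out_len: int = field(default=0)  # 0 -> same as in_cols

    def __post_init__(self) -> None:
        if self.out_len == 0:
            self.out_len = self.in_cols
        if len(self.dilation_schedule) != self.n_dilated_blocks:
            raise ValueError(
                f"dilation schedule has {len(self.dilation_schedule)} entries "
                f"for {self.n_dilated_blocks} blocks"
            )
        for k, d in enumerate(self.dilation_schedule, start=1):
            if d != 2 ** (k - 1):
                raise ValueError(
                    f"dilation of block {k} must be 2^{k - 1}={2 ** (k - 1)}, got {d}"
                )
        if self.out_len != self.in_cols:
            raise ValueError("output length must equal the input column count")
        if self.channels < 1 or self.in_rows < 1 or self.in_cols < 2:
            raise ValueError("invalid CAN dimensions")


@dataclass
class LSTMSpec:
    """Architecture of the time-domain baseline."""

    input_dims: int = 2
    hidden_units: int = 400
    out_dims: int = 1

    def __post_init__(self) -> None:
        if self.input_dims < 1 or self.hidden_units < 1 or self.out_dims != 1:
            raise ValueError("invalid LSTM spec")

    @property
    def gate_rows(self) -> int:
        """Rows of the gate-stacked weight matrices (4 x hidden)."""
        return 4 * self.hidden_units

    @property
    def recurrent_layer_parameters(self) -> int:
        """Learnables of the recurrent layer: Wx + Wh + bias."""
        return (self.gate_rows * self.input_dims
                + self.gate_rows * self.hidden_units
                + self.gate_rows)


@dataclass
class AdaptiveNormSpec:
    """Initialization of the adaptive normalization blend (identity map)."""

    lambda_init: float = 1.0
    mu_init: float = 0.0


class CANNetwork:
    """Constructed context aggregation network (numpy backend)."""

    def __init__(self, spec: CANSpec, net: Sequential) -> None:
        self.spec = spec
        self.net = net

    @property
    def n_layer_groups(self) -> int:
        return self.net.n_layer_groups

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Map (N, 4, L) or (N, 4, L, 1) inputs to (N, L) waveforms."""
        x = np.asarray(x, dtype=np.float64)
        if x.ndim == 3:
            x = x[..., None]
        if x.shape[1:] != (self.spec.in_rows, self.spec.in_cols, 1):
            raise ValueError(
                f"expected input (N, {self.spec.in_rows}, {self.spec.in_cols}[, 1]), "
                f"got {x.shape}"
            )
        return self.net.forward(x, training)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return self.net.backward(dy)

    def zero_grad(self) -> None:
        self.net.zero_grad()

    def parameters(self):
        return self.net.parameters()

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x, training=False)

    def describe(self) -> list[tuple[str, int]]:
        """(group name, learnable count) per layer group."""
        rows = []
        for gname, block in self.net.groups:
            count = sum(p.size for layer in block for p in layer.params.values())
            rows.append((gname, count))
        return rows


class LSTMNetwork:
    """Sequence-to-sequence LSTM regressor (numpy backend)."""

    def __init__(self, spec: LSTMSpec, lstm: LSTM, head: TimeLinear) -> None:
        self.spec = spec
        self.lstm = lstm
        self.head = head
        self.net = Sequential([("lstm", [lstm]), ("linear", [head])])

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Map (N, T, input_dims) sequences to (N, T) outputs."""
        x = np.asarray(x, dtype=np.float64)
        if x.ndim != 3 or x.shape[2] != self.spec.input_dims:
            raise ValueError(
                f"expected input (N, T, {self.spec.input_dims}), got {x.shape}"
            )
        return self.net.forward(x, training)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return self.net.backward(dy)

    def zero_grad(self) -> None:
        self.net.zero_grad()

    def parameters(self):
        return self.net.parameters()

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x, training=False)

    def describe(self) -> list[tuple[str, int]]:
        return [
            ("lstm", sum(p.size for p in self.lstm.params.values())),
            ("linear", sum(p.size for p in self.head.params.values())),
        ]


def build_can(spec: CANSpec | None = None, seed: int = 0,
              adaptive: AdaptiveNormSpec | None = None) -> CANNetwork:
    """Construct the ten-layer-group context aggregation network."""
    spec = spec or CANSpec()
    adaptive = adaptive or AdaptiveNormSpec()
    rng = np.random.default_rng(seed)
    ch = spec.channels
    groups: list[tuple[str, list]] = []
    in_c = 1
    for k, dil in enumerate(spec.dilation_schedule, start=1):
        kernel = spec.first_kernel if k == 1 else spec.body_kernel
        block = [
            Conv2D(in_c, ch, kernel=kernel, dilation=dil, rng=rng),
            BatchNorm2D(ch),
            AdaptiveNorm(ch, adaptive.lambda_init, adaptive.mu_init),
            LeakyReLU(spec.leaky_slope),
        ]
        groups.append((f"dilated_{dil}", block))
        in_c = ch
    # plain convolution block (no dilation)
    groups.append(("plain_conv", [
        Conv2D(ch, ch, kernel=spec.body_kernel, dilation=1, rng=rng),
        BatchNorm2D(ch),
        AdaptiveNorm(ch, adaptive.lambda_init, adaptive.mu_init),
        LeakyReLU(spec.leaky_slope),
    ]))
    # regression head: 3x3 reduction to pre_regression_channels, then a
    # learnable row/channel collapse to the length-L waveform
    groups.append(("regression", [
        Conv2D(ch, spec.pre_regression_channels, kernel=spec.body_kernel,
               dilation=1, rng=rng),
        RowCollapse(spec.in_rows, spec.pre_regression_channels, rng=rng),
    ]))
    return CANNetwork(spec, Sequential(groups))


def build_lstm(spec: LSTMSpec | None = None, seed: int = 0) -> LSTMNetwork:
    """Construct the sequence-to-sequence LSTM baseline."""
    spec = spec or LSTMSpec()
    rng = np.random.default_rng(seed)
    lstm = LSTM(spec.input_dims, spec.hidden_units, rng=rng)
    head = TimeLinear(spec.hidden_units, rng=rng)
    return LSTMNetwork(spec, lstm, head)


def half_mse_loss(targets: np.ndarray, predictions: np.ndarray) -> float:
    """Half sum of squared errors per sequence; batch mean over sequences.

    For one length-L pair this is ``0.5 * sum_p (t_p - y_p)^2``; for a
    batch (N, L) it is the mean of the per-sequence values.
    """
    targets = np.asarray(targets, dtype=np.float64)
    predictions = np.asarray(predictions, dtype=np.float64)
    if targets.shape != predictions.shape:
        raise ValueError(
            f"shape mismatch: targets {targets.shape} vs predictions {predictions.shape}"
        )
    sq = 0.5 * np.sum((targets - predictions) ** 2, axis=-1)
    return float(np.mean(sq))
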