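"""Spatial stride-geometry regression from single gait cycles.

From each pair of consecutive ipsilateral ICs, the acceleration spanning
the cycle is standardized and linearly resampled to a fixed 200-sample
segment.  Two independent networks regress stride length and stride width
(cm) from such segments: a stack of causal residual TCN blocks (two
chomped dilated convolutions per block, each with ReLU and dropout, plus
an additive bypass), temporal average pooling, and a linear head.

Regression targets are z-scored on the training split and de-standardized
at prediction time.  The shared model handles both feet; the foot side is
injected as a constant auxiliary input channel (on by default), and the
cycle's original duration can optionally be injected the same way.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from . import nn
from .io import SAMPLE_RATE, AccelRecording, GaitEvent, ScalerParams, apply_scaler
from .temporal import _train_loop

MIN_CYCLE_S = 0.5
MAX_CYCLE_S = 4.0


@dataclass
class GaitCycleSegment:
    """One gait cycle's standardized acceleration, resampled to length 200.

    ``magnitude`` is the resampled Euclidean norm of the *raw* (unscaled)
    acceleration minus 1 g: it is invariant to the unknown sensor
    orientation, which varies between ears, and is offered to the
    regressors as an auxiliary input channel.
    """

    data: np.ndarray  # (3, target_len)
    foot: str
    ic_time: float
    duration: float  # original duration, s
    magnitude: np.ndarray | None = None  # (target_len,)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.data)):
            raise ValueError("segment contains non-finite values")


def extract_gait_cycles(
    recording: AccelRecording,
    ic_events: list[GaitEvent],
    scaler: ScalerParams,
    target_len: int = 200,
    min_duration: float = MIN_CYCLE_S,
    max_duration: float = MAX_CYCLE_S,
) -> tuple[list[GaitCycleSegment], int]:
    """Cut one segment per consecutive ipsilateral IC pair.

    Cycles with duration outside [min_duration, max_duration] are outside
    the human walking range (and would stress the resampler); they are
    discarded and counted.  Returns (segments, n_discarded).
    """
    fs = recording.sample_rate
    scaled = apply_scaler(recording.samples, scaler)
    magnitude = np.linalg.norm(recording.samples, axis=1) - 1.0  # g, gravity off
    segments: list[GaitCycleSegment] = []
    discarded = 0
    for foot in ("left", "right"):
        ics = sorted(e.time for e in ic_events if e.foot == foot and e.kind == "IC")
        for t0, t1 in zip(ics, ics[1:]):
            duration = t1 - t0
            if not (min_duration <= duration <= max_duration):
                discarded += 1
                continue
            i0 = int(round((t0 - recording.t0) * fs))
            i1 = int(round((t1 - recording.t0) * fs))
            i0 = max(0, i0)
            i1 = min(recording.n_samples, i1)
            if i1 - i0 < 2:
                discarded += 1
                continue
            raw = scaled[i0:i1]  # (m, 3)
            src = np.linspace(0.0, 1.0, raw.shape[0])
            dst = np.linspace(0.0, 1.0, target_len)
            data = np.stack([np.interp(dst, src, raw[:, c]) for c in range(3)])
            mag = np.interp(dst, src, magnitude[i0:i1])
            segments.append(
                GaitCycleSegment(data=data, foot=foot, ic_time=t0,
                                 duration=duration, magnitude=mag)
            )
    return segments, discarded


def segments_to_array(
    segments: list[GaitCycleSegment],
    use_magnitude_channel: bool = True,
    use_side_channel: bool = True,
    use_duration_channel: bool = False,
) -> np.ndarray:
    """Stack segments into the (n, C, 200) network input.

    Channel order: 3 standardized acceleration channels, then the
    orientation-invariant magnitude channel, then the configured constant
    auxiliary channels (side: ±0.5; duration: s)."""
    xs = []
    for seg in segments:
        chans = [seg.data]
        length = seg.data.shape[1]
        if use_magnitude_channel:
            if seg.magnitude is None:
                raise ValueError("segment lacks a magnitude channel")
            chans.append(seg.magnitude[None, :])
        if use_side_channel:
            chans.append(np.full((1, length), 0.5 if seg.foot == "left" else -0.5))
        if use_duration_channel:
            chans.append(np.full((1, length), seg.duration))
        xs.append(np.concatenate(chans, axis=0))
    return np.stack(xs)


@dataclass(frozen=True)
class SpatialModelConfig:
    """Architecture of a spatial regression network.

    Sized for amplitude/waveform regression from a single cycle: 3 residual
    blocks of 16 channels give a receptive field beyond the 200-sample
    segment while keeping CPU training cheap.
    """

    n_blocks: int = 3
    channels: int = 16
    kernel_size: int = 3
    dilation_growth: int = 2
    dropout: float = 0.2
    in_channels: int = 5  # 3 acc + magnitude + side channel

    def __post_init__(self) -> None:
        if self.n_blocks < 1 or self.channels < 1 or self.dilation_growth < 1:
            raise ValueError("invalid architecture config")


def build_spatial_model(
    config: SpatialModelConfig, rng: np.random.Generator | None = None
) -> nn.Sequential:
    """Residual causal blocks -> temporal average pooling -> linear scalar."""
    rng = rng or np.random.default_rng()
    layers: list[nn.Layer] = []
    c_in = config.in_channels
    for i in range(config.n_blocks):
        layers.append(
            nn.ResidualBlock1d(
                c_in,
                config.channels,
                config.kernel_size,
                dilation=config.dilation_growth**i,
                dropout=config.dropout,
                rng=rng,
            )
        )
        c_in = config.channels
    layers.append(nn.GlobalAvgPool1d())
    layers.append(nn.Linear(c_in, 1, rng))
    return nn.Sequential(*layers)


class StrideRegressor(BaseEstimator, RegressorMixin):
    """Scikit-learn style regressor for one spatial stride characteristic.

    ``fit(X, y)`` takes (n, in_channels, 200) segment arrays and targets in
    cm; training minimizes MSE on z-scored targets with Adam, and
    ``predict`` returns values back on the cm scale.  Instantiate one
    regressor for stride length and an independent one for stride width.
    """

    def __init__(
        self,
        n_blocks: int = 3,
        channels: int = 16,
        kernel_size: int = 3,
        dilation_growth: int = 2,
        dropout: float = 0.2,
        in_channels: int = 5,
        learning_rate: float = 1e-3,
        batch_size: int = 64,
        epochs: int = 30,
        random_state: int | None = None,
    ) -> None:
        self.n_blocks = n_blocks
        self.channels = channels
        self.kernel_size = kernel_size
        self.dilation_growth = dilation_growth
        self.dropout = dropout
        self.in_channels = in_channels
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.random_state = random_state

    def _config(self) -> SpatialModelConfig:
        return SpatialModelConfig(
            n_blocks=self.n_blocks,
            channels=self.channels,
            kernel_size=self.kernel_size,
            dilation_growth=self.dilation_growth,
            dropout=self.dropout,
            in_channels=self.in_channels,
        )

    def fit(self, X, y, X_val=None, y_val=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 3 or X.shape[1] != self.in_channels:
            raise ValueError(f"X must be (n, {self.in_channels}, L)")
        if len(y) != X.shape[0]:
            raise ValueError("X and y lengths differ")
        self.y_mean_ = float(np.mean(y))
        self.y_std_ = float(np.std(y))
        if self.y_std_ == 0.0:
            self.y_std_ = 1.0
        yz = (y - self.y_mean_) / self.y_std_
        rng = np.random.default_rng(self.random_state)
        self.config_ = self._config()
        self.model_ = build_spatial_model(self.config_, rng)

        yv = None if y_val is None else (np.asarray(y_val).ravel() - self.y_mean_) / self.y_std_

        def scalar_mse(pred, target):
            # model emits (n, 1); gradient reshaped to match
            loss, d = nn.mse_loss(pred[:, 0], target)
            return loss, d[:, None]

        self.history_ = _train_loop(
            self.model_, X, yz, scalar_mse, rng,
            lr=self.learning_rate, batch_size=self.batch_size, epochs=self.epochs,
            X_val=X_val, y_val=yv,
        )
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "model_"):
            raise RuntimeError("estimator is not fitted")
        out = self.model_.forward(np.asarray(X, dtype=float), training=False)
        return out[:, 0] * self.y_std_ + self.y_mean_


__all__ = [
    "MIN_CYCLE_S",
    "MAX_CYCLE_S",
    "GaitCycleSegment",
    "SpatialModelConfig",
    "StrideRegressor",
    "extract_gait_cycles",
    "segments_to_array",
    "build_spatial_model",
]
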