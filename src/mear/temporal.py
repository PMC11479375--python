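"""Temporal event segmentation network and event extraction.

The temporal network maps standardized 3x200 acceleration windows to
per-sample IC/FC probability traces: a stack of length-preserving dilated
convolution blocks (conv -> batch norm -> ReLU -> dropout, dilation growing
exponentially across blocks) followed by a position-wise fully connected
projection to two channels.  The network emits raw logits; the sigmoid is
applied only at inference, matching BCE-with-logits training.

Discrete events are read off the probability traces by thresholded peak
picking with a refractory period, then assigned alternating left/right
sides (a single ear sensor cannot observe the feet directly).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy.signal import find_peaks
from sklearn.base import BaseEstimator

from . import nn
from .io import SAMPLE_RATE, AccelRecording, GaitEvent, ScalerParams, apply_scaler


@dataclass(frozen=True)
class TemporalModelConfig:
    """Architecture of the temporal network.

    Defaults (5 blocks, 32 channels, kernel 3, dilation growth 2) give a
    receptive field of 63 samples = 0.63 s, at least half a gait cycle.
    """

    n_blocks: int = 5
    channels: int = 32
    kernel_size: int = 3
    dilation_growth: int = 2
    dropout: float = 0.2
    in_channels: int = 3
    out_channels: int = 2  # IC, FC
    window: int = 200

    def __post_init__(self) -> None:
        if self.kernel_size % 2 == 0:
            raise ValueError("kernel size must be odd (length-preserving padding)")
        if self.n_blocks < 1 or self.channels < 1 or self.dilation_growth < 1:
            raise ValueError("invalid architecture config")

    @property
    def receptive_field(self) -> int:
        g, k = self.dilation_growth, self.kernel_size
        dil_sum = self.n_blocks if g == 1 else (g**self.n_blocks - 1) // (g - 1)
        return 1 + (k - 1) * dil_sum


def build_temporal_model(
    config: TemporalModelConfig, rng: np.random.Generator | None = None
) -> nn.Sequential:
    """Assemble the block stack; output is (n, 2, window) logits."""
    rng = rng or np.random.default_rng()
    layers: list[nn.Layer] = []
    c_in = config.in_channels
    for i in range(config.n_blocks):
        layers += [
            nn.Conv1d(c_in, config.channels, config.kernel_size,
                      dilation=config.dilation_growth**i, padding="same", rng=rng),
            nn.BatchNorm1d(config.channels),
            nn.ReLU(),
            nn.Dropout(config.dropout, rng),
        ]
        c_in = config.channels
    layers.append(nn.ChannelLinear(c_in, config.out_channels, rng))
    return nn.Sequential(*layers)


def make_windows(
    samples: np.ndarray, window: int = 200, hop: int = 100
) -> list[tuple[np.ndarray, int]]:
    """Cut an (n, channels) sample block into (channels, window) blocks.

    Windows start every ``hop`` samples; if the tail is not covered a final
    right-aligned window at offset n - window is appended.
    """
    n = samples.shape[0]
    if n < window:
        raise ValueError(f"recording too short: {n} < window {window}")
    offsets = list(range(0, n - window + 1, hop))
    if offsets[-1] != n - window:
        offsets.append(n - window)
    return [(samples[o : o + window].T.copy(), o) for o in offsets]


def make_label_traces(
    event_samples: dict[str, np.ndarray],
    offset: int,
    window: int = 200,
    sigma: float = 5.0,
) -> np.ndarray:
    """Gaussian-bump target traces for one window.

    ``event_samples`` maps 'IC'/'FC' to event positions in recording
    samples.  Each event contributes a Gaussian with peak 1 at its sample
    (sigma in samples, truncated at 4 sigma); overlaps combine by max.
    """
    target = np.zeros((2, window))
    idx = np.arange(offset, offset + window)
    for ch, kind in enumerate(("IC", "FC")):
        for s in np.atleast_1d(event_samples.get(kind, ())):
            d = np.abs(idx - s)
            bump = np.where(d <= 4 * sigma, np.exp(-(d**2) / (2 * sigma**2)), 0.0)
            target[ch] = np.maximum(target[ch], bump)
    return target


def predict_traces(
    model: nn.Sequential,
    recording: AccelRecording,
    scaler: ScalerParams,
    window: int = 200,
    hop: int = 100,
    batch_size: int = 256,
) -> np.ndarray:
    """Score a whole recording: 50%-overlap windows, per-sample averaging.

    Returns a (2, n_samples) probability trace aligned to the recording
    time base.
    """
    scaled = apply_scaler(recording.samples, scaler)
    wins = make_windows(scaled, window, hop)
    x = np.stack([w for w, _ in wins])
    probs = []
    for i in range(0, len(x), batch_size):
        logits = model.forward(x[i : i + batch_size], training=False)
        probs.append(nn.sigmoid(logits))
    probs = np.concatenate(probs, axis=0)
    acc = np.zeros((2, recording.n_samples))
    cnt = np.zeros(recording.n_samples)
    for (w, off), p in zip(wins, probs):
        acc[:, off : off + window] += p
        cnt[off : off + window] += 1
    return acc / cnt


def extract_events(
    trace: np.ndarray,
    threshold: float = 0.5,
    refractory: float = 0.30,
    sample_rate: float = SAMPLE_RATE,
    t0: float = 0.0,
) -> tuple[list[GaitEvent], list[GaitEvent]]:
    """Pick IC/FC events from a probability trace.

    Local maxima above ``threshold``; within any refractory span only the
    highest peak survives (scipy's ``distance`` rule).  Returns (ics, fcs)
    with foot='unknown'.
    """
    out = []
    dist = max(1, int(round(refractory * sample_rate)))
    for ch, kind in enumerate(("IC", "FC")):
        peaks, _ = find_peaks(trace[ch], height=threshold, distance=dist)
        out.append([GaitEvent(time=t0 + p / sample_rate, kind=kind) for p in peaks])
    return out[0], out[1]


def assign_foot_side(
    ic_events: list[GaitEvent],
    fc_events: list[GaitEvent],
    ear_side: str,
    anchor: str | None = None,
    gap_factor: float = 1.6,
) -> list[GaitEvent]:
    """Assign alternating L/R sides to side-agnostic events.

    ICs alternate starting from the anchor foot (default: the foot
    ipsilateral to the sensor ear).  When the interval between successive
    ICs exceeds ``gap_factor`` x the median step interval, the number of
    missed steps is estimated and the parity advanced accordingly, so
    downstream strides spanning the gap are flagged by the metrics layer
    instead of every later stride being mis-sided.  Each FC takes the side
    contralateral to the nearest preceding IC (an FC of foot X falls just
    after the contralateral IC in normal gait phasing).
    """
    ics = sorted(ic_events)
    fcs = sorted(fc_events)
    anchor = anchor or ear_side
    if anchor not in ("left", "right"):
        raise ValueError("anchor must be 'left' or 'right'")
    other = {"left": "right", "right": "left"}
    sided: list[GaitEvent] = []
    if ics:
        intervals = np.diff([e.time for e in ics])
        med = float(np.median(intervals)) if len(intervals) else 0.5
        side = anchor
        parity_steps = [1] + [
            max(1, int(round(dt / med))) if dt > gap_factor * med else 1
            for dt in intervals
        ]
        for e, adv in zip(ics, parity_steps):
            if adv % 2 == 1 and e is not ics[0]:
                side = other[side]
            sided.append(GaitEvent(time=e.time, kind="IC", foot=side))
    ic_times = [e.time for e in sided]
    for fc in fcs:
        j = int(np.searchsorted(ic_times, fc.time)) - 1
        if j < 0:
            continue  # FC before any IC: side unresolvable, dropped
        sided.append(GaitEvent(time=fc.time, kind="FC", foot=other[sided[j].foot]))
    return sorted(sided)


class TemporalEventSegmenter(BaseEstimator):
    """Scikit-learn style estimator for the temporal event network.

    ``fit(X, y)`` takes standardized windows X of shape (n, 3, window) and
    Gaussian-bump targets y of shape (n, 2, window); training minimizes
    BCE-with-logits with Adam.  ``predict_proba(X)`` returns per-sample
    event probabilities.  Higher-level recording-in / events-out flows are
    provided by :func:`predict_traces`, :func:`extract_events` and
    :func:`assign_foot_side` on the fitted ``model_``.
    """

    def __init__(
        self,
        n_blocks: int = 5,
        channels: int = 32,
        kernel_size: int = 3,
        dilation_growth: int = 2,
        dropout: float = 0.2,
        window: int = 200,
        learning_rate: float = 1e-3,
        batch_size: int = 64,
        epochs: int = 30,
        threshold: float = 0.5,
        refractory: float = 0.30,
        random_state: int | None = None,
    ) -> None:
        self.n_blocks = n_blocks
        self.channels = channels
        self.kernel_size = kernel_size
        self.dilation_growth = dilation_growth
        self.dropout = dropout
        self.window = window
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.threshold = threshold
        self.refractory = refractory
        self.random_state = random_state

    def _config(self) -> TemporalModelConfig:
        return TemporalModelConfig(
            n_blocks=self.n_blocks,
            channels=self.channels,
            kernel_size=self.kernel_size,
            dilation_growth=self.dilation_growth,
            dropout=self.dropout,
            window=self.window,
        )

    def fit(self, X, y, X_val=None, y_val=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 3 or X.shape[1] != 3 or X.shape[2] != self.window:
            raise ValueError(f"X must be (n, 3, {self.window})")
        if y.shape != (X.shape[0], 2, self.window):
            raise ValueError(f"y must be (n, 2, {self.window})")
        rng = np.random.default_rng(self.random_state)
        self.config_ = self._config()
        self.model_ = build_temporal_model(self.config_, rng)
        self.history_ = _train_loop(
            self.model_, X, y, nn.bce_with_logits, rng,
            lr=self.learning_rate, batch_size=self.batch_size, epochs=self.epochs,
            X_val=X_val, y_val=y_val,
        )
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X) -> np.ndarray:
        self._check_fitted()
        logits = self.model_.forward(np.asarray(X, dtype=float), training=False)
        return nn.sigmoid(logits)

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X) >= self.threshold).astype(int)

    def _check_fitted(self) -> None:
        if not hasattr(self, "model_"):
            raise RuntimeError("estimator is not fitted")

    # -- persistence -------------------------------------------------------

    def save(self, path: str | Path, scaler: ScalerParams | None = None) -> Path:
        self._check_fitted()
        return save_model(self.model_, self.config_, path, scaler)


def _train_loop(model, X, y, loss_fn, rng, lr, batch_size, epochs,
                X_val=None, y_val=None):
    """Mini-batch Adam training with best-validation-epoch weight keeping."""
    layers = model.parameters()
    opt = nn.Adam(layers, lr=lr)
    n = X.shape[0]
    history = {"train_loss": [], "val_loss": []}
    best_val, best_state = np.inf, None
    for epoch in range(epochs):
        order = rng.permutation(n)
        losses = []
        for i in range(0, n, batch_size):
            idx = order[i : i + batch_size]
            out = model.forward(X[idx], training=True)
            loss, dout = loss_fn(out, y[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}: {loss}"
                )
            model.backward(dout)
            opt.step()
            losses.append(loss)
        history["train_loss"].append(float(np.mean(losses)))
        if X_val is not None:
            out = model.forward(X_val, training=False)
            vloss, _ = loss_fn(out, y_val)
            history["val_loss"].append(float(vloss))
            if vloss < best_val:
                best_val = vloss
                best_state = [
                    {k: v.copy() for k, v in layer.params.items()} for layer in layers
                ]
    if best_state is not None:
        for layer, state in zip(layers, best_state):
            for k in layer.params:
                layer.params[k][...] = state[k]
    return history


# ---------------------------------------------------------------------------
# weight persistence: npz of flattened params + JSON config sidecar


def save_model(model: nn.Sequential, config, path: str | Path,
               scaler: ScalerParams | None = None) -> Path:
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(path.suffix + ".npz")
    arrays = {}
    for li, layer in enumerate(model.parameters()):
        for k, v in layer.params.items():
            arrays[f"{li}:{k}"] = v
    for li, layer in enumerate(_bn_layers(model)):
        arrays[f"bn{li}:mean"] = layer.running_mean
        arrays[f"bn{li}:var"] = layer.running_var
    np.savez(path, **arrays)
    meta = {"config": asdict(config), "kind": type(config).__name__}
    if scaler is not None:
        meta["scaler"] = {"median": scaler.median.tolist(), "iqr": scaler.iqr.tolist()}
    Path(str(path) + ".json").write_text(json.dumps(meta, indent=2))
    return path


def load_temporal_model(path: str | Path):
    """Load (model, config, scaler-or-None) written by :func:`save_model`."""
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(path.suffix + ".npz")
    meta = json.loads(Path(str(path) + ".json").read_text())
    config = TemporalModelConfig(**meta["config"])
    model = build_temporal_model(config, np.random.default_rng(0))
    _restore(model, path)
    scaler = None
    if "scaler" in meta:
        scaler = ScalerParams(
            median=np.array(meta["scaler"]["median"]),
            iqr=np.array(meta["scaler"]["iqr"]),
        )
    return model, config, scaler


def _restore(model, path) -> None:
    p = Path(path)
    if p.suffix != ".npz":
        p = p.with_suffix(p.suffix + ".npz")
    data = np.load(p)
    for li, layer in enumerate(model.parameters()):
        for k in layer.params:
            layer.params[k][...] = data[f"{li}:{k}"]
    for li, layer in enumerate(_bn_layers(model)):
        layer.running_mean[...] = data[f"bn{li}:mean"]
        layer.running_var[...] = data[f"bn{li}:var"]


def _bn_layers(model):
    out = []

    def walk(layer):
        if isinstance(layer, nn.Sequential):
            for sub in layer.layers:
                walk(sub)
        elif isinstance(layer, nn.ResidualBlock1d):
            walk(layer.body)
            if layer.shortcut is not None:
                walk(layer.shortcut)
        elif isinstance(layer, nn.BatchNorm1d):
            out.append(layer)

    walk(model)
    return out


__all__ = [
    "TemporalModelConfig",
    "TemporalEventSegmenter",
    "build_temporal_model",
    "make_windows",
    "make_label_traces",
    "predict_traces",
    "extract_events",
    "assign_foot_side",
    "save_model",
    "load_temporal_model",
]
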