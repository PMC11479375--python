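"""Shared data model and on-disk artifact formats.

All artifacts are plain columnar text:

* recording CSV — ``t,acc_ml,acc_ap,acc_is`` (seconds, g)
* events CSV    — ``time,kind,foot`` (kind IC/FC, foot L/R/U)
* strides CSV   — ``foot,ic_time,stride_time,swing_time,dsupp_time,
  stride_length_cm,stride_width_cm``
* sidecar metadata — ``key=value`` lines (subject_id, ear_side,
  speed_condition, sample_rate)

Times are seconds as floats, decimal point '.', comma separator, one header
row.  Acceleration stays in sensor-native g everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

SAMPLE_RATE = 100.0  # Hz, fixed by the sensor
ACC_RANGE_G = 16.0  # ±16 g accelerometer range

EVENT_KINDS = ("IC", "FC")
FEET = ("left", "right")
SPEEDS = ("slow", "preferred", "fast")

_FOOT_CODE = {"left": "L", "right": "R", "unknown": "U"}
_CODE_FOOT = {v: k for k, v in _FOOT_CODE.items()}


class FormatError(ValueError):
    """Raised when an on-disk artifact violates its documented dialect."""


@dataclass
class AccelRecording:
    """One continuous triaxial ear-acceleration time series.

    samples has shape (n, 3) with columns (acc_ml, acc_ap, acc_is) in g;
    sample i is at time t0 + i / sample_rate.
    """

    subject_id: str
    ear_side: str
    samples: np.ndarray
    t0: float = 0.0
    sample_rate: float = SAMPLE_RATE

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sample_rate != SAMPLE_RATE:
            raise ValueError(f"sample_rate must be {SAMPLE_RATE} Hz")
        if self.ear_side not in FEET:
            raise ValueError(f"ear_side must be one of {FEET}")
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise ValueError("samples must have shape (n, 3)")
        if self.samples.shape[0] < 1:
            raise ValueError("recording must contain at least one sample")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if np.any(np.abs(self.samples) > ACC_RANGE_G):
            raise ValueError(f"|acc| exceeds sensor range ±{ACC_RANGE_G} g")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.sample_rate

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate


@dataclass(frozen=True, order=True)
class GaitEvent:
    """A single IC (heel strike) or FC (toe off)."""

    time: float
    kind: str
    foot: str = "unknown"

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"kind must be one of {EVENT_KINDS}")
        if self.foot not in (*FEET, "unknown"):
            raise ValueError("foot must be left/right/unknown")
        if self.time < 0:
            raise ValueError("event time must be >= 0")


@dataclass
class StrideRecord:
    """One gait cycle's temporal and spatial parameters for one foot.

    Temporal fields in seconds, spatial fields in cm.  NaN marks a field
    that could not be derived; ``valid`` is False when the cycle overlaps a
    detected gap in the event sequence (reason in ``reason``).
    """

    foot: str
    ic_time: float
    stride_time: float
    swing_time: float = float("nan")
    double_support_time: float = float("nan")
    stride_length: float = float("nan")
    stride_width: float = float("nan")
    valid: bool = True
    reason: str = ""

    def __post_init__(self) -> None:
        if self.foot not in FEET:
            raise ValueError("stride foot must be left or right")
        if self.valid:
            if not self.stride_time > 0:
                raise ValueError("stride_time must be > 0")
            if np.isfinite(self.swing_time) and not (
                0 <= self.swing_time < self.stride_time
            ):
                raise ValueError("swing_time must be in [0, stride_time)")
            if np.isfinite(self.double_support_time) and not (
                0 <= self.double_support_time < self.stride_time
            ):
                raise ValueError("double_support_time must be in [0, stride_time)")
            for name in ("stride_length", "stride_width"):
                v = getattr(self, name)
                if np.isfinite(v) and v < 0:
                    raise ValueError(f"{name} must be >= 0")


@dataclass
class WalkBout:
    """One walk across the walkway at a single instructed speed."""

    recording: AccelRecording
    speed_condition: str
    events: list[GaitEvent] = field(default_factory=list)
    strides: list[StrideRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.speed_condition not in SPEEDS:
            raise ValueError(f"speed_condition must be one of {SPEEDS}")
        self.events = sorted(self.events)

    @property
    def subject_id(self) -> str:
        return self.recording.subject_id


@dataclass(frozen=True)
class ScalerParams:
    """Robust-scaler parameters: per-channel median and interquartile range."""

    median: np.ndarray
    iqr: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "median", np.asarray(self.median, dtype=float))
        object.__setattr__(self, "iqr", np.asarray(self.iqr, dtype=float))
        if self.median.shape != self.iqr.shape:
            raise ValueError("median and iqr must have matching shapes")
        if np.any(self.iqr <= 0):
            raise ValueError("IQR must be > 0 on every channel")


# ---------------------------------------------------------------------------
# readers / writers


def write_recording(recording: AccelRecording, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        {
            "t": recording.times,
            "acc_ml": recording.samples[:, 0],
            "acc_ap": recording.samples[:, 1],
            "acc_is": recording.samples[:, 2],
        }
    )
    df.to_csv(path, index=False)
    _write_sidecar(
        path,
        subject_id=recording.subject_id,
        ear_side=recording.ear_side,
        sample_rate=recording.sample_rate,
    )
    return path


def read_recording(path: str | Path) -> AccelRecording:
    path = Path(path)
    df = _read_csv(path, required=("t", "acc_ml", "acc_ap", "acc_is"))
    meta = _read_sidecar(path)
    rate = float(meta.get("sample_rate", SAMPLE_RATE))
    if rate != SAMPLE_RATE:
        raise FormatError(f"{path}: sample_rate {rate} != {SAMPLE_RATE}")
    samples = df[["acc_ml", "acc_ap", "acc_is"]].to_numpy(dtype=float)
    return AccelRecording(
        subject_id=meta.get("subject_id", path.stem),
        ear_side=meta.get("ear_side", "left"),
        samples=samples,
        t0=float(df["t"].iloc[0]) if len(df) else 0.0,
    )


def write_events(events: list[GaitEvent], path: str | Path) -> Path:
    path = Path(path)
    events = sorted(events)
    df = pd.DataFrame(
        {
            "time": [e.time for e in events],
            "kind": [e.kind for e in events],
            "foot": [_FOOT_CODE[e.foot] for e in events],
        }
    )
    df.to_csv(path, index=False)
    return path


def read_events(path: str | Path) -> list[GaitEvent]:
    df = _read_csv(Path(path), required=("time", "kind", "foot"))
    events = []
    for i, row in df.iterrows():
        try:
            events.append(
                GaitEvent(
                    time=float(row["time"]),
                    kind=str(row["kind"]),
                    foot=_CODE_FOOT[str(row["foot"])],
                )
            )
        except (KeyError, ValueError) as exc:
            raise FormatError(f"{path}: line {i + 2}: {exc}") from exc
    return sorted(events)


_STRIDE_COLS = (
    "foot",
    "ic_time",
    "stride_time",
    "swing_time",
    "dsupp_time",
    "stride_length_cm",
    "stride_width_cm",
)


def write_strides(strides: list[StrideRecord], path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        {
            "foot": [_FOOT_CODE[s.foot] for s in strides],
            "ic_time": [s.ic_time for s in strides],
            "stride_time": [s.stride_time for s in strides],
            "swing_time": [s.swing_time for s in strides],
            "dsupp_time": [s.double_support_time for s in strides],
            "stride_length_cm": [s.stride_length for s in strides],
            "stride_width_cm": [s.stride_width for s in strides],
            "valid": [int(s.valid) for s in strides],
            "reason": [s.reason for s in strides],
        },
        columns=[*_STRIDE_COLS, "valid", "reason"],
    )
    df.to_csv(path, index=False)
    return path


def read_strides(path: str | Path) -> list[StrideRecord]:
    df = _read_csv(Path(path), required=_STRIDE_COLS)
    out = []
    for i, row in df.iterrows():
        try:
            out.append(
                StrideRecord(
                    foot=_CODE_FOOT[str(row["foot"])],
                    ic_time=float(row["ic_time"]),
                    stride_time=float(row["stride_time"]),
                    swing_time=float(row["swing_time"]),
                    double_support_time=float(row["dsupp_time"]),
                    stride_length=float(row["stride_length_cm"]),
                    stride_width=float(row["stride_width_cm"]),
                    valid=bool(int(row["valid"])) if "valid" in df.columns else True,
                    reason=str(row["reason"])
                    if "reason" in df.columns and not pd.isna(row["reason"])
                    else "",
                )
            )
        except (KeyError, ValueError) as exc:
            raise FormatError(f"{path}: line {i + 2}: {exc}") from exc
    return out


def _read_csv(path: Path, required: tuple[str, ...]) -> pd.DataFrame:
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # malformed CSV
        raise FormatError(f"{path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing} (header line 1)")
    numeric = [c for c in required if c not in ("kind", "foot")]
    for col in numeric:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
            raise FormatError(f"{path}: non-numeric value in '{col}' at line {line}")
        df[col] = coerced
    return df


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta")


def _write_sidecar(path: Path, **kv) -> None:
    lines = [f"{k}={v}" for k, v in kv.items()]
    _sidecar_path(path).write_text("\n".join(lines) + "\n")


def _read_sidecar(path: Path) -> dict[str, str]:
    sp = _sidecar_path(path)
    if not sp.exists():
        return {}
    meta = {}
    for line in sp.read_text().splitlines():
        line = line.strip()
        if line and "=" in line:
            k, _, v = line.partition("=")
            meta[k.strip()] = v.strip()
    return meta


# ---------------------------------------------------------------------------
# robust scaling


def fit_robust_scaler(recordings: list[AccelRecording]) -> ScalerParams:
    """Fit per-channel median/IQR over all pooled samples.

    Quartiles use linear interpolation between order statistics (NumPy's
    default, the 'type 7' rule).  Fit once on the training split and freeze.
    """
    if not recordings:
        raise ValueError("need at least one recording")
    pooled = np.concatenate([r.samples for r in recordings], axis=0)
    median = np.median(pooled, axis=0)
    q75, q25 = np.percentile(pooled, [75, 25], axis=0)
    iqr = q75 - q25
    if np.any(iqr <= 0):
        raise ValueError("degenerate data: zero IQR on at least one channel")
    return ScalerParams(median=median, iqr=iqr)


def apply_scaler(samples: np.ndarray, params: ScalerParams) -> np.ndarray:
    """Standardize an (n, 3) sample block: (x - median) / IQR per channel."""
    samples = np.asarray(samples, dtype=float)
    if samples.shape[-1] != params.median.shape[0]:
        raise ValueError(
            f"channel mismatch: data has {samples.shape[-1]}, "
            f"scaler has {params.median.shape[0]}"
        )
    return (samples - params.median) / params.iqr


def invert_scaler(scaled: np.ndarray, params: ScalerParams) -> np.ndarray:
    return np.asarray(scaled, dtype=float) * params.iqr + params.median


__all__ = [
    "SAMPLE_RATE",
    "ACC_RANGE_G",
    "SPEEDS",
    "FEET",
    "FormatError",
    "AccelRecording",
    "GaitEvent",
    "StrideRecord",
    "WalkBout",
    "ScalerParams",
    "read_recording",
    "write_recording",
    "read_events",
    "write_events",
    "read_strides",
    "write_strides",
    "fit_robust_scaler",
    "apply_scaler",
    "invert_scaler",
]
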