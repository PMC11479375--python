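"""Synthetic walking-bout generator.

Emulates the study protocol the downstream stages are built for: short
walks across a ~6.7 m walkway at slow / preferred / fast instructed
speeds, with per-subject cadence and stride-length distributions,
left-right asymmetry, stride-to-stride variability, a sensor-orientation
rotation standing in for ear-anatomy differences, and Gaussian sensor
noise.

The acceleration model is this module's contract (real recordings have no
generative model): head acceleration during gait is synthesized as gravity
plus step- and stride-frequency harmonics locked to the footfall phase
(vertical dominant, AP at step frequency, ML at stride frequency), a
damped-oscillation impact transient at every IC, a smaller transient at
every FC, all rotated into the subject's sensor frame, plus white noise.
Harmonic and transient amplitudes scale with the local stride length /
walking speed, which is what makes stride length recoverable by the
spatial regressor.  This claims learnable IC/FC signatures, not
biomechanical fidelity.

Ground-truth StrideRecords are derived from the emitted events and heel
coordinates with the same machinery users apply to predictions
(:func:`mear.metrics.strides_from_events` plus the perpendicular-distance
stride-width geometry), so events, coordinates and stride parameters are
mutually consistent by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import SAMPLE_RATE, AccelRecording, GaitEvent, WalkBout
from .metrics import strides_from_events

SPEEDS = ("slow", "preferred", "fast")

# stance occupies ~60% of the gait cycle, slightly longer at slow speeds
STANCE_FRACTION = {"slow": 0.62, "preferred": 0.60, "fast": 0.58}


@dataclass
class SubjectParams:
    """Per-subject gait phenotype used by :func:`generate_bout`."""

    subject_id: str
    ear_side: str
    height: float  # m
    cadence: dict[str, float]  # steps/min per speed condition
    stride_length: dict[str, float]  # cm per speed condition (larger foot)
    stride_time_cv: float  # %
    stride_length_cv: float  # %
    temporal_asym: float  # % step-time offset between left and right steps
    spatial_asym: float  # % stride-length offset between feet
    stride_width_mean: float  # cm
    stride_width_cv: float  # %
    spatial_asym_larger: str = "left"  # which foot carries the larger stride
    temporal_asym_larger: str = "left"
    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    noise_std: float = 0.02  # g

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        for cv in (self.stride_time_cv, self.stride_length_cv,
                   self.stride_width_cv):
            if cv < 0:
                raise ValueError("CVs must be >= 0")
        if not (self.cadence["slow"] < self.cadence["preferred"] < self.cadence["fast"]):
            raise ValueError("cadence must increase slow < preferred < fast")
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-8) or not (
            np.linalg.det(self.rotation) > 0
        ):
            raise ValueError("rotation must be a proper rotation matrix")


@dataclass
class CohortConfig:
    """Cohort-level generator configuration.

    Defaults state the emulated protocol: 53 subjects, 6/8/10 walks at
    slow/preferred/fast speed over a 6.7 m walkway.  Subject-level
    hyperparameters are healthy-adult norms (cadence ~110 steps/min and
    stride length ~125 cm at preferred speed, stride-time CV ~2.5%, small
    percent-level asymmetries, stride width ~7 cm with ~20% CV).
    """

    n_subjects: int = 53
    walks_per_speed: dict[str, int] = field(
        default_factory=lambda: {"slow": 6, "preferred": 8, "fast": 10}
    )
    walkway_length: float = 6.7  # m
    seed: int = 0
    # subject-distribution hyperparameters (mean, sd)
    height: tuple[float, float] = (1.73, 0.10)
    cadence_preferred: tuple[float, float] = (110.0, 7.0)
    cadence_slow_factor: tuple[float, float] = (0.82, 0.03)
    cadence_fast_factor: tuple[float, float] = (1.15, 0.04)
    stride_length_preferred: tuple[float, float] = (125.0, 10.0)
    stride_length_slow_factor: tuple[float, float] = (0.80, 0.04)
    stride_length_fast_factor: tuple[float, float] = (1.12, 0.04)
    stride_time_cv: tuple[float, float] = (2.5, 1.0)
    stride_length_cv: tuple[float, float] = (2.7, 1.0)
    temporal_asym: tuple[float, float] = (1.5, 1.0)
    spatial_asym: tuple[float, float] = (0.8, 0.6)
    stride_width: tuple[float, float] = (7.2, 1.4)
    stride_width_cv: tuple[float, float] = (20.0, 8.0)
    rotation_angle_sd_deg: float = 8.0
    noise_std: float = 0.02

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if self.walkway_length <= 0:
            raise ValueError("walkway_length must be > 0")


def _subject_rng(config: CohortConfig, index: int) -> np.random.Generator:
    # counter-derived substream: reproducible under parallel generation
    return np.random.default_rng([config.seed, 1000 + index])


def _bout_rng(config: CohortConfig, subject_index: int, bout_index: int):
    return np.random.default_rng([config.seed, 1000 + subject_index, bout_index])


def random_rotation(rng: np.random.Generator, angle_sd_deg: float) -> np.ndarray:
    """Small proper rotation: random axis, N(0, sd) angle capped at 25°."""
    axis = rng.standard_normal(3)
    axis /= np.linalg.norm(axis)
    angle = np.clip(rng.normal(0.0, math.radians(angle_sd_deg)),
                    -math.radians(25), math.radians(25))
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + math.sin(angle) * k + (1 - math.cos(angle)) * (k @ k)


def draw_subject(config: CohortConfig, index: int,
                 rng: np.random.Generator | None = None) -> SubjectParams:
    """Draw one subject's gait phenotype; deterministic in (seed, index)."""
    rng = rng or _subject_rng(config, index)
    cad_pref = rng.normal(*config.cadence_preferred)
    cadence = {
        "slow": cad_pref * rng.normal(*config.cadence_slow_factor),
        "preferred": cad_pref,
        "fast": cad_pref * rng.normal(*config.cadence_fast_factor),
    }
    # enforce the ordering invariant even in distribution tails
    cadence["slow"] = min(cadence["slow"], cadence["preferred"] * 0.95)
    cadence["fast"] = max(cadence["fast"], cadence["preferred"] * 1.05)
    sl_pref = rng.normal(*config.stride_length_preferred)
    stride_length = {
        "slow": sl_pref * rng.normal(*config.stride_length_slow_factor),
        "preferred": sl_pref,
        "fast": sl_pref * rng.normal(*config.stride_length_fast_factor),
    }
    return SubjectParams(
        subject_id=f"S{index:03d}",
        ear_side="left" if rng.random() < 0.5 else "right",
        height=rng.normal(*config.height),
        cadence=cadence,
        stride_length=stride_length,
        stride_time_cv=abs(rng.normal(*config.stride_time_cv)),
        stride_length_cv=abs(rng.normal(*config.stride_length_cv)),
        temporal_asym=abs(rng.normal(*config.temporal_asym)),
        spatial_asym=abs(rng.normal(*config.spatial_asym)),
        stride_width_mean=max(2.0, rng.normal(*config.stride_width)),
        stride_width_cv=abs(rng.normal(*config.stride_width_cv)),
        spatial_asym_larger="left" if rng.random() < 0.5 else "right",
        temporal_asym_larger="left" if rng.random() < 0.5 else "right",
        rotation=random_rotation(rng, config.rotation_angle_sd_deg),
        noise_std=config.noise_std,
    )


def stride_width_of_contact(
    p: np.ndarray, q1: np.ndarray, q2: np.ndarray
) -> float:
    """Perpendicular distance (cm) of heel contact p to the line through two
    successive contralateral contacts q1, q2 (coordinates in cm)."""
    d = q2 - q1
    norm = np.linalg.norm(d)
    if norm == 0:
        return float(np.linalg.norm(p - q1))
    return float(abs(d[0] * (p[1] - q1[1]) - d[1] * (p[0] - q1[0])) / norm)


def _footfall_sequence(subject: SubjectParams, speed: str, walkway_length: float,
                       rng: np.random.Generator):
    """Build the footfall plan: per-foot IC times and heel coordinates (cm).

    Left-foot IC times accumulate drawn left stride times; each right IC is
    placed a step-time fraction into the current left stride, with the
    fraction set by the temporal asymmetry.  Per-foot stride lengths are
    drawn directly so per-foot means follow the configured spatial
    asymmetry exactly in expectation.
    """
    t_stride = 120.0 / subject.cadence[speed]  # s (stride = 2 steps)
    cv_t = subject.stride_time_cv / 100.0
    cv_l = subject.stride_length_cv / 100.0
    a_sp = subject.spatial_asym / 100.0
    a_tm = subject.temporal_asym / 100.0
    len_mean = {
        subject.spatial_asym_larger: subject.stride_length[speed],
        ("right" if subject.spatial_asym_larger == "left" else "left"):
            subject.stride_length[speed] * (1.0 - a_sp),
    }
    # step-time split: larger side gets fraction 1/(2 - a), smaller (1-a)/(2-a)
    phi_larger = 1.0 / (2.0 - a_tm)
    phi = phi_larger if subject.temporal_asym_larger == "left" else 1.0 - phi_larger

    if walkway_length * 100.0 < max(len_mean.values()):
        raise ValueError("walkway shorter than one stride")

    half_w = subject.stride_width_mean / 2.0
    w_sd = half_w * subject.stride_width_cv / 100.0

    ic_l = [1.0]  # s of lead-in before the first left IC
    ic_r: list[float] = []
    x_l = [0.0]
    x_r: list[float] = []
    y_l = [half_w + rng.normal(0.0, w_sd)]
    y_r: list[float] = []
    target = walkway_length * 100.0
    while min(x_l[-1], x_r[-1] if x_r else 0.0) < target:
        st = max(0.4, rng.normal(t_stride, t_stride * cv_t))
        d = np.clip(phi + rng.normal(0.0, cv_t / 2), 0.15, 0.85) * st
        ic_r.append(ic_l[-1] + d)
        ic_l.append(ic_l[-1] + st)
        if len(x_r) == 0:
            x_r.append(max(5.0, rng.normal(len_mean["right"] / 2.0,
                                           len_mean["right"] * cv_l / 2.0)))
        else:
            x_r.append(x_r[-1] + max(10.0, rng.normal(len_mean["right"],
                                                      len_mean["right"] * cv_l)))
        x_l.append(x_l[-1] + max(10.0, rng.normal(len_mean["left"],
                                                  len_mean["left"] * cv_l)))
        y_r.append(-half_w + rng.normal(0.0, w_sd))
        y_l.append(half_w + rng.normal(0.0, w_sd))
        if len(ic_l) > 200:  # safety against degenerate configs
            break
    return ic_l, ic_r, x_l, x_r, y_l, y_r


def generate_bout(subject: SubjectParams, speed: str,
                  rng: np.random.Generator, walkway_length: float = 6.7) -> WalkBout:
    """Generate one labeled walk at the given instructed speed."""
    if speed not in SPEEDS:
        raise ValueError(f"speed must be one of {SPEEDS}")
    ic_l, ic_r, x_l, x_r, y_l, y_r = _footfall_sequence(
        subject, speed, walkway_length, rng
    )
    stance = STANCE_FRACTION[speed]

    events: list[GaitEvent] = []
    for times, foot in ((ic_l, "left"), (ic_r, "right")):
        for i, t in enumerate(times):
            events.append(GaitEvent(time=t, kind="IC", foot=foot))
            if i + 1 < len(times):
                events.append(
                    GaitEvent(time=t + stance * (times[i + 1] - t), kind="FC", foot=foot)
                )
    events.sort()

    strides = strides_from_events(events)
    # attach spatial ground truth from the heel coordinates
    coords = {"left": (ic_l, x_l, y_l), "right": (ic_r, x_r, y_r)}
    for s in strides:
        times, xs, ys = coords[s.foot]
        c_times, c_xs, c_ys = coords["right" if s.foot == "left" else "left"]
        i = times.index(s.ic_time)
        s.stride_length = xs[i + 1] - xs[i]
        # width at the terminal contact, flanked by contralateral contacts
        t_end = times[i + 1]
        before = [j for j, t in enumerate(c_times) if t < t_end]
        after = [j for j, t in enumerate(c_times) if t > t_end]
        if before and after:
            j1, j2 = before[-1], after[0]
            s.stride_width = stride_width_of_contact(
                np.array([xs[i + 1], ys[i + 1]]),
                np.array([c_xs[j1], c_ys[j1]]),
                np.array([c_xs[j2], c_ys[j2]]),
            )

    samples = _synthesize_acceleration(subject, speed, events, strides, rng)
    recording = AccelRecording(
        subject_id=subject.subject_id,
        ear_side=subject.ear_side,
        samples=samples,
        t0=0.0,
    )
    return WalkBout(recording=recording, speed_condition=speed,
                    events=events, strides=strides)


def _synthesize_acceleration(subject, speed, events, strides, rng) -> np.ndarray:
    fs = SAMPLE_RATE
    ics = sorted(e.time for e in events if e.kind == "IC")
    fcs = sorted(e.time for e in events if e.kind == "FC")
    t_end = max(e.time for e in events) + 1.0
    n = int(round(t_end * fs))
    t = np.arange(n) / fs

    # footfall-locked phase: advances pi per step between successive ICs
    step_phase = np.pi * np.arange(len(ics))
    mean_step = float(np.mean(np.diff(ics))) if len(ics) > 1 else 0.5
    phase = np.interp(t, ics, step_phase)
    phase = np.where(t < ics[0], step_phase[0] - (ics[0] - t) * np.pi / mean_step, phase)
    phase = np.where(
        t > ics[-1], step_phase[-1] + (t - ics[-1]) * np.pi / mean_step, phase
    )

    # smooth standing->walking envelope
    env = np.clip((t - (ics[0] - 0.5)) / 0.5, 0, 1) * np.clip(
        ((ics[-1] + 0.5) - t) / 0.5, 0, 1
    )

    # local stride length (cm) and speed modulate amplitudes
    valid = [s for s in strides if np.isfinite(s.stride_length)]
    if valid:
        s_times = np.array([s.ic_time for s in valid])
        s_len = np.array([s.stride_length for s in valid])
        order = np.argsort(s_times)
        local_len = np.interp(t, s_times[order], s_len[order])
        local_spd = np.interp(
            t,
            s_times[order],
            np.array([s.stride_length / s.stride_time for s in valid])[order] / 100.0,
        )
    else:
        local_len = np.full(n, 120.0)
        local_spd = np.full(n, 1.2)

    amp_v = 0.16 * (local_spd / 1.2)
    amp_ap = 0.10 * (local_spd / 1.2)
    amp_ml = 0.08 * np.ones(n)

    ml = amp_ml * env * np.sin(phase + 0.5)
    ap = amp_ap * env * np.sin(2 * phase + 1.2)
    iz = 1.0 + amp_v * env * np.sin(2 * phase) + 0.35 * amp_v * env * np.sin(4 * phase + 0.7)
    if subject.ear_side == "right":
        ml = -ml

    def add_transient(channel, t0_ev, amp, freq, tau):
        i0 = int(np.ceil(t0_ev * fs))
        i1 = min(n, i0 + int(0.25 * fs))
        if i0 >= n or i1 <= i0:
            return
        dt = t[i0:i1] - t0_ev
        channel[i0:i1] += amp * np.exp(-dt / tau) * np.sin(2 * np.pi * freq * dt)

    for tic in ics:
        a = 0.35 * float(np.interp(tic, t, local_len)) / 120.0
        add_transient(iz, tic, a, 14.0, 0.05)
        add_transient(ap, tic, 0.5 * a, 11.0, 0.05)
    for tfc in fcs:
        add_transient(iz, tfc, 0.12, 8.0, 0.06)
        add_transient(ap, tfc, 0.10, 7.0, 0.06)

    sig = np.stack([ml, ap, iz], axis=1)  # (n, 3)
    sig = sig @ subject.rotation.T
    sig = sig + rng.normal(0.0, subject.noise_std, size=sig.shape)
    return np.clip(sig, -16.0, 16.0)


def generate_cohort(config: CohortConfig) -> tuple[list[WalkBout], pd.DataFrame]:
    """Generate the full cohort plus a bout manifest.

    The manifest (one row per bout: bout_id, subject_id, speed, walk,
    ear_side) carries the grouping needed for subject-level splits.
    """
    bouts: list[WalkBout] = []
    rows = []
    for si in range(config.n_subjects):
        subject = draw_subject(config, si)
        bout_counter = 0
        for speed in SPEEDS:
            for walk in range(config.walks_per_speed[speed]):
                rng = _bout_rng(config, si, bout_counter)
                bout = generate_bout(subject, speed, rng, config.walkway_length)
                bout_id = f"{subject.subject_id}_{speed}_{walk:02d}"
                rows.append(
                    {
                        "bout_id": bout_id,
                        "subject_id": subject.subject_id,
                        "speed": speed,
                        "walk": walk,
                        "ear_side": subject.ear_side,
                    }
                )
                bouts.append(bout)
                bout_counter += 1
    manifest = pd.DataFrame(rows)
    return bouts, manifest


__all__ = [
    "SPEEDS",
    "STANCE_FRACTION",
    "SubjectParams",
    "CohortConfig",
    "draw_subject",
    "generate_bout",
    "generate_cohort",
    "random_rotation",
    "stride_width_of_contact",
]
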