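"""End-to-end orchestration: simulate -> scale -> train -> detect -> regress
-> evaluate.

This is the one place the full recovery experiment lives, shared by the
command-line interface, the acceptance checks and the test suite: generate
a labeled synthetic cohort, split it by subject, train the temporal event
network and the two spatial regressors on the training subjects, and score
event detection and stride-geometry recovery on the held-out subjects.
"""

from __future__ import annotations

import numpy as np

from . import evaluation, metrics, temporal
from .io import ScalerParams, WalkBout, fit_robust_scaler, apply_scaler
from .simulate import CohortConfig, generate_cohort
from .spatial import StrideRegressor, extract_gait_cycles, segments_to_array
from .temporal import (
    TemporalEventSegmenter,
    assign_foot_side,
    extract_events,
    make_label_traces,
    make_windows,
    predict_traces,
)
from .training import build_event_sample_map, make_split_plan


def windows_and_labels(
    bouts: list[WalkBout],
    scaler: ScalerParams,
    window: int = 200,
    hop: int = 100,
    sigma: float = 5.0,
):
    """Training windows and Gaussian-bump label traces for all bouts."""
    xs, ys, groups = [], [], []
    for bout in bouts:
        scaled = apply_scaler(bout.recording.samples, scaler)
        ev = build_event_sample_map(bout)
        for block, off in make_windows(scaled, window, hop):
            xs.append(block)
            ys.append(make_label_traces(ev, off, window, sigma))
            groups.append(bout.subject_id)
    return np.stack(xs), np.stack(ys), np.array(groups)


def cycles_and_targets(
    bouts: list[WalkBout],
    scaler: ScalerParams,
    use_side_channel: bool = True,
    augment_rotations: int = 0,
    rng: np.random.Generator | None = None,
):
    """Gait-cycle segments from ground-truth ICs, with stride-geometry
    targets taken from the matching ground-truth StrideRecords.

    ``augment_rotations`` adds that many extra copies of every training
    bout with a fresh random sensor rotation applied to the raw samples
    (training-time augmentation: the regressors must not key on the
    subject's particular mounting orientation).
    """
    from .io import AccelRecording
    from .simulate import random_rotation

    if augment_rotations and rng is None:
        rng = np.random.default_rng(0)
    segs, y_len, y_wid, groups = [], [], [], []
    for bout in bouts:
        ics = [e for e in bout.events if e.kind == "IC"]
        recordings = [bout.recording]
        for _ in range(augment_rotations):
            rot = random_rotation(rng, angle_sd_deg=10.0)
            recordings.append(
                AccelRecording(
                    subject_id=bout.subject_id,
                    ear_side=bout.recording.ear_side,
                    samples=np.clip(bout.recording.samples @ rot.T, -16, 16),
                    t0=bout.recording.t0,
                )
            )
        by_key = {(s.foot, s.ic_time): s for s in bout.strides}
        for recording in recordings:
            cycles, _ = extract_gait_cycles(recording, ics, scaler)
            for seg in cycles:
                rec = by_key.get((seg.foot, seg.ic_time))
                if rec is None or not np.isfinite(rec.stride_length):
                    continue
                segs.append(seg)
                y_len.append(rec.stride_length)
                y_wid.append(
                    rec.stride_width if np.isfinite(rec.stride_width) else np.nan
                )
                groups.append(bout.subject_id)
    x = segments_to_array(segs, use_side_channel=use_side_channel)
    return x, np.array(y_len), np.array(y_wid), np.array(groups), segs


def detect_bout_events(model, bout: WalkBout, scaler: ScalerParams,
                       threshold: float = 0.5, refractory: float = 0.30):
    """Probability traces -> side-agnostic IC and FC events for one bout."""
    trace = predict_traces(model, bout.recording, scaler)
    return extract_events(trace, threshold=threshold, refractory=refractory,
                          sample_rate=bout.recording.sample_rate,
                          t0=bout.recording.t0)


def run_recovery_experiment(
    n_subjects: int = 12,
    seed: int = 0,
    epochs_temporal: int = 30,
    epochs_spatial: int = 30,
    walks_per_speed: dict[str, int] | None = None,
    noise_std: float = 0.02,
) -> dict:
    """Full held-out recovery experiment on a synthetic cohort.

    Returns a dict with the trained estimators, the detection scores per
    event class at the 250 ms tolerance, and stride length / width
    agreement statistics on the held-out subjects.
    """
    config = CohortConfig(n_subjects=n_subjects, seed=seed, noise_std=noise_std)
    if walks_per_speed is not None:
        config.walks_per_speed = walks_per_speed
    bouts, manifest = generate_cohort(config)
    plan = make_split_plan(manifest, test_fraction=0.2, k=5, seed=seed)

    by_subject: dict[str, list[WalkBout]] = {}
    for b in bouts:
        by_subject.setdefault(b.subject_id, []).append(b)
    train_subj, val_subj = plan.folds[0]
    train_bouts = [b for s in train_subj for b in by_subject[s]]
    val_bouts = [b for s in val_subj for b in by_subject[s]]
    test_bouts = [b for s in plan.test_subjects for b in by_subject[s]]

    scaler = fit_robust_scaler(
        [b.recording for b in train_bouts + val_bouts]
    )

    # --- temporal network -------------------------------------------------
    Xt, yt, _ = windows_and_labels(train_bouts, scaler)
    Xv, yv, _ = windows_and_labels(val_bouts, scaler)
    segmenter = TemporalEventSegmenter(epochs=epochs_temporal, random_state=seed)
    segmenter.fit(Xt, yt, Xv, yv)

    agg = {"IC": [0, 0, 0], "FC": [0, 0, 0]}  # tp, fn, fp
    errors = {"IC": [], "FC": []}
    for bout in test_bouts:
        ics, fcs = detect_bout_events(segmenter.model_, bout, scaler,
                                      segmenter.threshold, segmenter.refractory)
        for kind, pred in (("IC", ics), ("FC", fcs)):
            truth = [e for e in bout.events if e.kind == kind]
            res = evaluation.match_events(pred, truth)
            agg[kind][0] += res.tp
            agg[kind][1] += res.fn
            agg[kind][2] += res.fp
            errors[kind].extend(a - p for a, p in res.pairs)

    detection = {}
    for kind in ("IC", "FC"):
        scores = evaluation.f1_from_counts(*agg[kind])
        detection[kind] = {
            "tp": agg[kind][0], "fn": agg[kind][1], "fp": agg[kind][2],
            "recall": scores.recall, "precision": scores.precision,
            "f1": scores.f1,
            "mean_time_error": float(np.mean(errors[kind])) if errors[kind] else np.nan,
        }

    # --- spatial networks (best-validation-epoch selection) ---------------
    Xc, ylen, ywid, _, _ = cycles_and_targets(
        train_bouts, scaler, augment_rotations=1,
        rng=np.random.default_rng([seed, 777]),
    )
    Xv2, ylen_v, ywid_v, _, _ = cycles_and_targets(val_bouts, scaler)
    Xtest, ylen_t, ywid_t, _, _ = cycles_and_targets(test_bouts, scaler)
    reg_len = StrideRegressor(epochs=epochs_spatial, random_state=seed)
    reg_len.fit(Xc, ylen, Xv2, ylen_v)
    pred_len = reg_len.predict(Xtest)
    length_stats = evaluation.agreement(pred_len, ylen_t)

    wmask = np.isfinite(ywid)
    wmask_v = np.isfinite(ywid_v)
    wmask_t = np.isfinite(ywid_t)
    reg_wid = StrideRegressor(epochs=epochs_spatial, random_state=seed + 1)
    reg_wid.fit(Xc[wmask], ywid[wmask], Xv2[wmask_v], ywid_v[wmask_v])
    pred_wid = reg_wid.predict(Xtest[wmask_t])
    width_stats = evaluation.agreement(pred_wid, ywid_t[wmask_t])

    return {
        "config": config,
        "plan": plan,
        "scaler": scaler,
        "segmenter": segmenter,
        "length_regressor": reg_len,
        "width_regressor": reg_wid,
        "detection": detection,
        "stride_length": length_stats,
        "stride_width": width_stats,
        "n_test_bouts": len(test_bouts),
    }


__all__ = [
    "windows_and_labels",
    "cycles_and_targets",
    "detect_bout_events",
    "run_recovery_experiment",
]
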