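"""Agreement evaluation against the gold standard.

Event-level scoring (TP/FN/FP at a 250 ms tolerance, precision/recall/F1,
signed time errors), parameter-level agreement statistics (absolute and
relative RMSE, Pearson's r, single-rater two-way ICC in both
absolute-agreement and consistency flavors, with the conventional
interpretation bands), and a speed-stratified relative-RMSE table with a
one-way repeated-measures ANOVA across the three instructed speeds.

ICC naming in the gait literature mixes conventions; here the two-way
single-rater coefficients are computed from ANOVA mean squares directly:

    ICC(C,1) = (MSR - MSE) / (MSR + (k-1) MSE)
    ICC(A,1) = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

with MSR/MSC/MSE the row (target), column (method) and residual mean
squares of the n x k table.  The default is absolute agreement, which
penalizes systematic offsets between the methods.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import GaitEvent

DEFAULT_TOLERANCE = 0.250  # s


@dataclass
class MatchResult:
    """TP/FN/FP bookkeeping for one event class."""

    tp: int
    fn: int
    fp: int
    pairs: list[tuple[float, float]]  # (t_annotated, t_predicted)
    tolerance: float

    def __post_init__(self) -> None:
        if self.tp != len(self.pairs):
            raise ValueError("TP count must equal number of matched pairs")


def match_events(
    predicted: list[GaitEvent] | list[float],
    annotated: list[GaitEvent] | list[float],
    tolerance: float = DEFAULT_TOLERANCE,
) -> MatchResult:
    """Greedily pair predicted and annotated events by ascending |Δt|.

    Only pairs with |Δt| strictly below the tolerance are eligible; each
    event is used at most once.  Unmatched annotated events are FNs,
    unmatched predictions FPs.
    """
    tp_times = _times(predicted)
    an_times = _times(annotated)
    cands = [
        (abs(a - p), ai, pi)
        for ai, a in enumerate(an_times)
        for pi, p in enumerate(tp_times)
        if abs(a - p) < tolerance
    ]
    cands.sort()
    used_a: set[int] = set()
    used_p: set[int] = set()
    pairs = []
    for _, ai, pi in cands:
        if ai in used_a or pi in used_p:
            continue
        used_a.add(ai)
        used_p.add(pi)
        pairs.append((an_times[ai], tp_times[pi]))
    pairs.sort()
    return MatchResult(
        tp=len(pairs),
        fn=len(an_times) - len(pairs),
        fp=len(tp_times) - len(pairs),
        pairs=pairs,
        tolerance=tolerance,
    )


def _times(events) -> list[float]:
    return [e.time if isinstance(e, GaitEvent) else float(e) for e in events]


@dataclass
class DetectionScores:
    recall: float
    precision: float
    f1: float
    flags: list[str] = field(default_factory=list)


def detection_scores(result: MatchResult) -> DetectionScores:
    """recall = TP/(TP+FN), precision = TP/(TP+FP), F1 their harmonic mean.

    With no annotated (or no predicted) events the corresponding score is
    undefined and flagged NaN, never silently zero; TP = 0 with both FN
    and FP positive yields the degenerate-but-defined F1 = 0.
    """
    flags = []
    if result.tp + result.fn == 0:
        recall = math.nan
        flags.append("recall_undefined")
    else:
        recall = result.tp / (result.tp + result.fn)
    if result.tp + result.fp == 0:
        precision = math.nan
        flags.append("precision_undefined")
    else:
        precision = result.tp / (result.tp + result.fp)
    if flags:
        f1 = math.nan
        flags.append("f1_undefined")
    elif result.tp == 0:
        f1 = 0.0
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return DetectionScores(recall=recall, precision=precision, f1=f1, flags=flags)


def f1_from_counts(tp: int, fn: int, fp: int) -> DetectionScores:
    """Detection scores straight from printed TP/FN/FP counts."""
    return detection_scores(MatchResult(tp, fn, fp, [(0.0, 0.0)] * tp, DEFAULT_TOLERANCE))


def time_errors(result: MatchResult) -> tuple[np.ndarray, float]:
    """Signed per-match errors, t_annotated - t_predicted, and their mean."""
    if result.tp == 0:
        warnings.warn("no matched pairs: time errors empty", stacklevel=2)
        return np.array([]), math.nan
    errs = np.array([a - p for a, p in result.pairs])
    return errs, float(np.mean(errs))


# ---------------------------------------------------------------------------
# parameter agreement


def icc_two_way(values: np.ndarray, variant: str = "absolute") -> float:
    """Single-rater two-way ICC from the n x k paired-measurement table.

    variant 'absolute' -> ICC(A,1) (penalizes method offsets, the study's
    reading of "ICC(3,1), absolute agreement"); 'consistency' -> ICC(C,1).
    """
    values = np.asarray(values, dtype=float)
    n, k = values.shape
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    grand = values.mean()
    row_means = values.mean(axis=1)
    col_means = values.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sst = np.sum((values - grand) ** 2)
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    if variant == "consistency":
        denom = msr + (k - 1) * mse
    elif variant == "absolute":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
    else:
        raise ValueError("variant must be 'absolute' or 'consistency'")
    if denom == 0:
        raise ValueError("zero variance: ICC undefined")
    return float((msr - mse) / denom)


def icc_band(icc: float) -> str:
    """Conventional interpretation bands for ICC values."""
    if icc < 0.5:
        return "poor"
    if icc < 0.75:
        return "moderate"
    if icc <= 0.9:
        return "good"
    return "excellent"


@dataclass
class AgreementStats:
    rmse_abs: float
    rmse_rel: float  # %
    pearson_r: float
    pearson_p: float
    significant: bool  # two-sided alpha = 0.05
    icc: float
    icc_consistency: float
    band: str
    n: int
    flags: list[str] = field(default_factory=list)


def agreement(
    pred: np.ndarray,
    true: np.ndarray,
    icc_variant: str = "absolute",
    rel_denominator: str = "pooled",
) -> AgreementStats:
    """Agreement statistics between predicted and ground-truth values.

    RMSE_rel = 100 * RMSE_abs / mean(true); with rel_denominator
    'pooled' the mean is over all ground-truth values of the comparison
    group (the convention is configurable because published tables are
    only approximately reproducible either way).
    """
    pred = np.asarray(pred, dtype=float)
    true = np.asarray(true, dtype=float)
    mask = np.isfinite(pred) & np.isfinite(true)
    pred, true = pred[mask], true[mask]
    n = len(pred)
    if n < 3:
        raise ValueError("need at least 3 paired values")
    rmse_abs = float(np.sqrt(np.mean((pred - true) ** 2)))
    if rel_denominator not in ("pooled",):
        raise ValueError("rel_denominator must be 'pooled'")
    denom = float(np.mean(true))
    rmse_rel = 100.0 * rmse_abs / denom if denom != 0 else math.nan
    flags = []
    if np.std(pred) == 0 or np.std(true) == 0:
        r, p, icc_a, icc_c, band = math.nan, math.nan, math.nan, math.nan, "undefined"
        flags.append("zero_variance")
    else:
        r, p = stats.pearsonr(pred, true)
        table = np.column_stack([true, pred])
        icc_a = icc_two_way(table, "absolute")
        icc_c = icc_two_way(table, "consistency")
        band = icc_band(icc_a if icc_variant == "absolute" else icc_c)
    return AgreementStats(
        rmse_abs=rmse_abs,
        rmse_rel=rmse_rel,
        pearson_r=float(r),
        pearson_p=float(p),
        significant=bool(p < 0.05) if np.isfinite(p) else False,
        icc=float(icc_a) if icc_variant == "absolute" else float(icc_c),
        icc_consistency=float(icc_c),
        band=band,
        n=n,
        flags=flags,
    )


# ---------------------------------------------------------------------------
# speed-stratified analysis


def rm_anova_oneway(table: np.ndarray) -> tuple[float, tuple[int, int], float]:
    """One-way repeated-measures ANOVA on an n_subjects x n_conditions table.

    Returns (F, (df1, df2), p) with F = MS_condition / MS_error,
    df = (c-1, (c-1)(n-1)).
    """
    table = np.asarray(table, dtype=float)
    n, c = table.shape
    if n < 2 or c < 2:
        raise ValueError("need >= 2 subjects and >= 2 conditions")
    grand = table.mean()
    ss_cond = n * np.sum((table.mean(axis=0) - grand) ** 2)
    ss_subj = c * np.sum((table.mean(axis=1) - grand) ** 2)
    ss_tot = np.sum((table - grand) ** 2)
    ss_err = ss_tot - ss_cond - ss_subj
    df1 = c - 1
    df2 = (c - 1) * (n - 1)
    ms_cond = ss_cond / df1
    ms_err = ss_err / df2
    if ms_err == 0:
        f = 0.0 if ms_cond == 0 else math.inf
    else:
        f = float(ms_cond / ms_err)
    p = float(stats.f.sf(f, df1, df2)) if np.isfinite(f) else 0.0
    return f, (df1, df2), p


def speed_stratified_rmse(
    df: pd.DataFrame,
    speeds: tuple[str, ...] = ("slow", "preferred", "fast"),
) -> tuple[pd.DataFrame, dict]:
    """Per-subject per-speed relative RMSE plus RM-ANOVA across speeds.

    ``df`` needs columns subject, speed, pred, true — one row per bout.
    Subjects missing any speed condition are excluded with a warning.
    Returns (table indexed by subject with one RMSE_rel column per speed,
    {'F':, 'df':, 'p':}).
    """
    for col in ("subject", "speed", "pred", "true"):
        if col not in df.columns:
            raise ValueError(f"missing column {col!r}")
    rows = {}
    for subject, g in df.groupby("subject"):
        vals = {}
        for speed in speeds:
            gs = g[g["speed"] == speed]
            if len(gs) == 0:
                break
            rmse = float(np.sqrt(np.mean((gs["pred"] - gs["true"]) ** 2)))
            mean_true = float(gs["true"].mean())
            vals[speed] = 100.0 * rmse / mean_true if mean_true != 0 else math.nan
        if len(vals) == len(speeds):
            rows[subject] = vals
        else:
            warnings.warn(f"subject {subject} lacks a speed condition; excluded",
                          stacklevel=2)
    table = pd.DataFrame.from_dict(rows, orient="index")[list(speeds)]
    f, dfree, p = rm_anova_oneway(table.to_numpy())
    return table, {"F": f, "df": dfree, "p": p}


__all__ = [
    "DEFAULT_TOLERANCE",
    "MatchResult",
    "DetectionScores",
    "AgreementStats",
    "match_events",
    "detection_scores",
    "f1_from_counts",
    "time_errors",
    "icc_two_way",
    "icc_band",
    "agreement",
    "rm_anova_oneway",
    "speed_stratified_rmse",
]
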