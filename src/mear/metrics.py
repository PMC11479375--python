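"""Stride-level gait parameters and bout-level summaries.

Turns a sided IC/FC event sequence into per-cycle temporal parameters
(stride time, swing time, double support time) and aggregates strides into
mean / coefficient-of-variation / left-right-asymmetry summaries.

Conventions
-----------
* Stride time of cycle i = IC(i+1) − IC(i) of the same foot.
* Swing time = IC(i+1) − FC(i), the same foot's FC inside the cycle.
* Double support time = initial + terminal double-support intervals of the
  cycle: (contralateral FC − ipsilateral IC) + (ipsilateral FC −
  contralateral IC), the standard two-overlap decomposition.
* CV = 100 · sample std (ddof=1) / mean, in %.
* Asymmetry = 100 · (1 − mean(smaller-foot value) / mean(larger-foot
  value)), in %; symmetric under global left/right relabeling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io import FEET, GaitEvent, StrideRecord

PARAMETERS = (
    "stride_time",
    "swing_time",
    "dsupp_time",
    "stride_length",
    "stride_width",
)

_ATTR = {
    "stride_time": "stride_time",
    "swing_time": "swing_time",
    "dsupp_time": "double_support_time",
    "stride_length": "stride_length",
    "stride_width": "stride_width",
}


def strides_from_events(events: list[GaitEvent]) -> list[StrideRecord]:
    """Derive temporal stride parameters from a sided event sequence.

    One StrideRecord per consecutive ipsilateral IC pair.  A missing or
    ambiguous within-cycle event leaves the affected field NaN with a
    reason code; a cycle with no contralateral IC inside it (a missed step)
    is flagged invalid rather than silently dropped.
    """
    events = sorted(events)
    if any(e.foot == "unknown" for e in events):
        raise ValueError("strides_from_events requires sided events")
    out: list[StrideRecord] = []
    for foot in FEET:
        contra = "right" if foot == "left" else "left"
        ics = [e.time for e in events if e.foot == foot and e.kind == "IC"]
        fcs = [e.time for e in events if e.foot == foot and e.kind == "FC"]
        c_ics = [e.time for e in events if e.foot == contra and e.kind == "IC"]
        c_fcs = [e.time for e in events if e.foot == contra and e.kind == "FC"]
        for t0, t2 in zip(ics, ics[1:]):
            stride_time = t2 - t0
            swing = math.nan
            dsupp = math.nan
            valid, reason = True, ""
            in_fc = [t for t in fcs if t0 < t < t2]
            if len(in_fc) == 1:
                swing = t2 - in_fc[0]
            else:
                reason = "missing_fc" if not in_fc else "extra_fc"
            in_cic = [t for t in c_ics if t0 < t < t2]
            if len(in_cic) == 1:
                t_cic = in_cic[0]
                init_ds = [t for t in c_fcs if t0 < t < t_cic]
                if len(init_ds) == 1 and len(in_fc) == 1 and in_fc[0] >= t_cic:
                    dsupp = (init_ds[0] - t0) + (in_fc[0] - t_cic)
                else:
                    reason = reason or "dsupp_pattern"
            else:
                # contralateral step missing inside the cycle: a gap
                valid, reason = False, "alternation"
            out.append(
                StrideRecord(
                    foot=foot,
                    ic_time=t0,
                    stride_time=stride_time,
                    swing_time=swing,
                    double_support_time=dsupp,
                    valid=valid,
                    reason=reason,
                )
            )
    out.sort(key=lambda s: s.ic_time)
    return out


@dataclass
class ParamSummary:
    """Mean / CV / asymmetry of one gait parameter over a set of strides."""

    parameter: str
    mean: float
    cv: float
    asymmetry: float
    n_left: int
    n_right: int
    flags: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.n_left + self.n_right


def summarize_bout(strides: list[StrideRecord], parameter: str) -> ParamSummary:
    """Aggregate one parameter over all valid strides of a bout.

    Mean pools both feet; CV needs >= 2 valid strides total; asymmetry
    needs >= 2 valid strides per foot.  Undefined summaries are NaN with an
    explanatory flag — never silently zero.
    """
    if parameter not in _ATTR:
        raise ValueError(f"unknown parameter {parameter!r}; one of {PARAMETERS}")
    attr = _ATTR[parameter]
    vals = {
        foot: np.array(
            [
                getattr(s, attr)
                for s in strides
                if s.valid and s.foot == foot and np.isfinite(getattr(s, attr))
            ]
        )
        for foot in FEET
    }
    pooled = np.concatenate([vals["left"], vals["right"]])
    flags: list[str] = []
    if pooled.size == 0:
        return ParamSummary(parameter, math.nan, math.nan, math.nan, 0, 0, ["no_valid_strides"])
    mean = float(np.mean(pooled))
    if pooled.size >= 2 and mean > 0:
        cv = 100.0 * float(np.std(pooled, ddof=1)) / mean
    else:
        cv = math.nan
        flags.append("cv_undefined")
    if vals["left"].size >= 2 and vals["right"].size >= 2:
        ml, mr = float(np.mean(vals["left"])), float(np.mean(vals["right"]))
        lo, hi = min(ml, mr), max(ml, mr)
        if hi == 0.0:
            asym = 0.0  # both feet zero: no asymmetry
        elif lo < 0 or hi < 0:
            asym = math.nan
            flags.append("asym_negative_means")
        else:
            asym = 100.0 * (1.0 - lo / hi)
    else:
        asym = math.nan
        flags.append("asym_undefined")
    return ParamSummary(
        parameter, mean, cv, asym, int(vals["left"].size), int(vals["right"].size), flags
    )


def summarize_all(strides: list[StrideRecord]) -> dict[str, ParamSummary]:
    """BoutSummary: one ParamSummary per gait parameter."""
    return {p: summarize_bout(strides, p) for p in PARAMETERS}


def merge_spatial(
    strides: list[StrideRecord],
    predictions: dict[tuple[str, float], tuple[float, float]],
    time_tol: float = 1e-6,
) -> tuple[list[StrideRecord], list[tuple[str, float]]]:
    """Join predicted (stride_length_cm, stride_width_cm) onto strides.

    Predictions are keyed by (foot, ic_time); keys must be unique.  Returns
    the updated strides and the list of prediction keys that matched no
    stride.  Strides without a prediction keep NaN spatial fields.
    """
    keys = list(predictions.keys())
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate (foot, ic_time) prediction keys")
    used = set()
    for s in strides:
        for key, (length, width) in predictions.items():
            foot, t = key
            if foot == s.foot and abs(t - s.ic_time) <= time_tol and key not in used:
                s.stride_length = float(length)
                s.stride_width = float(width)
                used.add(key)
                break
    unmatched = [k for k in keys if k not in used]
    return strides, unmatched


__all__ = [
    "PARAMETERS",
    "ParamSummary",
    "strides_from_events",
    "summarize_bout",
    "summarize_all",
    "merge_spatial",
]
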