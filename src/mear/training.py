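"""Training protocol: subject-level splits, cross-validated grid search.

Data from one subject must never appear in more than one partition, so all
splitting happens at the subject level: an 80/20 train/test split followed
by k-fold (k = 5) cross-validation of the training subjects.
Stratification balances each subject's speed-condition bout counts across
folds as evenly as subject-level assignment allows.  Hyperparameter search
is a plain grid over batch size, learning rate and epoch count, scored by
mean validation loss across folds.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class SplitPlan:
    """Subject-level test split plus k train/validation folds."""

    test_subjects: list[str]
    folds: list[tuple[list[str], list[str]]]  # (train, validation) per fold

    def __post_init__(self) -> None:
        test = set(self.test_subjects)
        seen_val: set[str] = set()
        for train, val in self.folds:
            if test & set(train) or test & set(val):
                raise ValueError("test subjects leak into a fold")
            if set(train) & set(val):
                raise ValueError("train and validation overlap within a fold")
            if seen_val & set(val):
                raise ValueError("a subject validates in two folds")
            seen_val |= set(val)

    @property
    def train_subjects(self) -> list[str]:
        out: set[str] = set()
        for train, val in self.folds:
            out |= set(train) | set(val)
        return sorted(out)


def make_split_plan(
    manifest: pd.DataFrame,
    test_fraction: float = 0.2,
    k: int = 5,
    seed: int = 0,
) -> SplitPlan:
    """Build the subject-level split from a bout manifest.

    The manifest needs columns subject_id and speed.  Subjects are grouped
    by their speed-mix signature and dealt round-robin so that each fold's
    speed composition is as even as subject-level assignment allows.
    """
    if "subject_id" not in manifest.columns:
        raise ValueError("manifest needs a subject_id column")
    subjects = sorted(manifest["subject_id"].unique())
    if len(subjects) < k + 1:
        raise ValueError(f"need at least {k + 1} subjects, got {len(subjects)}")
    rng = np.random.default_rng(seed)

    if "speed" in manifest.columns:
        sig = {
            s: tuple(sorted(manifest[manifest["subject_id"] == s]["speed"]
                            .value_counts().items()))
            for s in subjects
        }
    else:
        sig = {s: () for s in subjects}
    # shuffle within signature strata, then interleave strata
    strata: dict[tuple, list[str]] = {}
    for s in subjects:
        strata.setdefault(sig[s], []).append(s)
    ordered: list[str] = []
    pools = [list(rng.permutation(v)) for _, v in sorted(strata.items())]
    while any(pools):
        for pool in pools:
            if pool:
                ordered.append(str(pool.pop()))

    n_test = max(1, int(round(test_fraction * len(subjects))))
    test = sorted(ordered[:n_test])
    rest = ordered[n_test:]
    if len(rest) < k:
        raise ValueError(f"too few non-test subjects ({len(rest)}) for k={k}")
    val_folds: list[list[str]] = [[] for _ in range(k)]
    for i, s in enumerate(rest):
        val_folds[i % k].append(s)
    folds = [
        (sorted(set(rest) - set(val)), sorted(val)) for val in val_folds
    ]
    return SplitPlan(test_subjects=test, folds=folds)


@dataclass
class GridSpec:
    """Candidate hyperparameter axes for the grid search."""

    batch_sizes: list[int] = field(default_factory=lambda: [32, 64, 128])
    learning_rates: list[float] = field(default_factory=lambda: [1e-4, 1e-3, 1e-2])
    epoch_counts: list[int] = field(default_factory=lambda: [30, 50, 100])

    def __post_init__(self) -> None:
        if not (self.batch_sizes and self.learning_rates and self.epoch_counts):
            raise ValueError("all grid axes must be non-empty")

    def points(self):
        return list(itertools.product(self.batch_sizes, self.learning_rates,
                                      self.epoch_counts))


def grid_search(grid: GridSpec, fold_data, make_estimator):
    """Exhaustive grid search scored by mean validation loss across folds.

    ``fold_data`` is a list of (X_train, y_train, X_val, y_val) tuples, one
    per fold; ``make_estimator(batch_size, lr, epochs)`` returns an
    unfitted estimator whose ``fit(X, y, X_val, y_val)`` records
    ``history_['val_loss']``.  Ties break toward smaller batch size, lower
    learning rate, fewer epochs.  Returns (best_point, cv_table) with one
    table row per grid point x fold.
    """
    rows = []
    means = {}
    for batch, lr, epochs in grid.points():
        losses = []
        for fi, (xt, yt, xv, yv) in enumerate(fold_data):
            est = make_estimator(batch, lr, epochs)
            est.fit(xt, yt, xv, yv)
            vloss = float(min(est.history_["val_loss"]))
            losses.append(vloss)
            rows.append(
                {"batch_size": batch, "learning_rate": lr, "epochs": epochs,
                 "fold": fi, "val_loss": vloss}
            )
        means[(batch, lr, epochs)] = float(np.mean(losses))
    best = min(means, key=lambda p: (means[p], p[0], p[1], p[2]))
    return best, pd.DataFrame(rows)


def build_event_sample_map(bout) -> dict[str, np.ndarray]:
    """Event positions in recording samples, per kind, for label building."""
    fs = bout.recording.sample_rate
    t0 = bout.recording.t0
    out = {}
    for kind in ("IC", "FC"):
        out[kind] = np.array(
            [(e.time - t0) * fs for e in bout.events if e.kind == kind]
        )
    return out


__all__ = [
    "SplitPlan",
    "GridSpec",
    "make_split_plan",
    "grid_search",
    "build_event_sample_map",
]
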