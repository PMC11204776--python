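"""Intraclass correlation from ANOVA mean squares, plus the rater analyses.

Forms follow the single-rating Shrout-Fleiss conventions:

  * ICC(1):   one-way random           (MSR - MSW) / (MSR + (k-1) MSW)
  * ICC(2,1): two-way random, absolute (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)
  * ICC(3,1): two-way mixed, consistency (MSR - MSE) / (MSR + (k-1) MSE)

with MSR the between-target, MSC the between-rater, MSE the residual and
MSW the within-target mean square.  Estimates are clipped to [0, 1] for
reporting; the raw value is retained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .errors import DegenerateSignalError

__all__ = [
    "RatingsMatrix",
    "ICCResult",
    "icc",
    "intraobserver_analysis",
    "interobserver_analysis",
    "landis_koch_label",
    "IntraObserverResult",
    "InterObserverResult",
]

ICC_FORMS = ("ICC(1)", "ICC(2,1)", "ICC(3,1)")
MEASURES = ("time", "amplitude")


@dataclass(frozen=True)
class RatingsMatrix:
    """Complete n_targets x k_raters matrix of one measure."""

    values: np.ndarray
    measure: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 2:
            raise ValueError(f"ratings must be 2-D, got shape {arr.shape}")
        n, k = arr.shape
        if n < 2 or k < 2:
            raise ValueError(f"need >= 2 targets and >= 2 raters, got {n} x {k}")
        if not np.all(np.isfinite(arr)):
            raise ValueError("ratings must be complete (no missing cells)")
        object.__setattr__(self, "values", arr)

    @property
    def n_targets(self) -> int:
        return self.values.shape[0]

    @property
    def k_raters(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class ICCResult:
    estimate: float  # clipped to [0, 1]
    estimate_raw: float
    form: str
    n_targets: int
    k_raters: int
    ms_between_targets: float
    ms_between_raters: float
    ms_error: float
    ms_within: float
    measure: str = ""

    def to_dict(self) -> dict:
        return {
            "estimate": self.estimate,
            "estimate_raw": self.estimate_raw,
            "form": self.form,
            "n_targets": self.n_targets,
            "k_raters": self.k_raters,
            "ms_between_targets": self.ms_between_targets,
            "ms_between_raters": self.ms_between_raters,
            "ms_error": self.ms_error,
            "ms_within": self.ms_within,
            "measure": self.measure,
            "label": landis_koch_label(self.estimate),
        }


def icc(matrix: RatingsMatrix, form: str = "ICC(2,1)") -> ICCResult:
    """Intraclass correlation of a complete ratings matrix."""
    if form not in ICC_FORMS:
        raise ValueError(f"form must be one of {ICC_FORMS}, got {form!r}")
    x = matrix.values
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)

    ss_total = float(((x - grand) ** 2).sum())
    if ss_total <= 0:
        raise DegenerateSignalError("zero total variance; ICC undefined")
    ss_rows = float(k * ((row_means - grand) ** 2).sum())
    ss_cols = float(n * ((col_means - grand) ** 2).sum())
    ss_err = max(ss_total - ss_rows - ss_cols, 0.0)
    ss_within = max(ss_total - ss_rows, 0.0)

    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    msw = ss_within / (n * (k - 1))

    if form == "ICC(1)":
        denom = msr + (k - 1) * msw
        est = (msr - msw) / denom if denom > 0 else 0.0
    elif form == "ICC(2,1)":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
        est = (msr - mse) / denom if denom > 0 else 0.0
    else:  # ICC(3,1)
        denom = msr + (k - 1) * mse
        est = (msr - mse) / denom if denom > 0 else 0.0

    return ICCResult(
        estimate=float(np.clip(est, 0.0, 1.0)),
        estimate_raw=float(est),
        form=form,
        n_targets=n,
        k_raters=k,
        ms_between_targets=msr,
        ms_between_raters=msc,
        ms_error=mse,
        ms_within=msw,
        measure=matrix.measure,
    )


def landis_koch_label(estimate: float) -> str:
    """Agreement band of a reliability estimate in [0, 1]."""
    if not (0.0 <= estimate <= 1.0):
        raise ValueError(f"estimate must lie in [0, 1], got {estimate}")
    if estimate <= 0.2:
        return "poor"
    if estimate <= 0.4:
        return "fair"
    if estimate <= 0.6:
        return "moderate"
    if estimate <= 0.8:
        return "substantial"
    return "almost perfect"


def _measure_values(cv_table: pd.DataFrame, measure: str, time_mode: str) -> pd.Series:
    if measure == "amplitude":
        return cv_table[["amp1", "amp2", "amp3"]].mean(axis=1)
    if time_mode == "interval":
        # maneuver-to-maneuver timing, start-offset independent
        iv1 = cv_table["time2"] - cv_table["time1"]
        iv2 = cv_table["time3"] - cv_table["time2"]
        return (iv1 + iv2) / 2.0
    return cv_table[["time1", "time2", "time3"]].mean(axis=1)


@dataclass
class IntraObserverResult:
    per_evaluator: dict[str, dict[str, ICCResult]]
    global_average: dict[str, float]
    excluded: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "per_evaluator": {
                e: {m: r.to_dict() for m, r in res.items()}
                for e, res in self.per_evaluator.items()
            },
            "global_average": self.global_average,
            "excluded": self.excluded,
        }


@dataclass
class InterObserverResult:
    per_measure: dict[str, ICCResult]

    def to_dict(self) -> dict:
        return {m: r.to_dict() for m, r in self.per_measure.items()}


def intraobserver_analysis(
    cv_table: pd.DataFrame,
    form: str = "ICC(1)",
    time_mode: str = "interval",
) -> IntraObserverResult:
    """Repeatability of each evaluator across their own repeats.

    Targets are subjects; raters are that evaluator's repeats.  Evaluators
    without at least two repeats on at least two subjects are excluded with
    a warning.  Global averages are unweighted means over evaluators.
    """
    per_evaluator: dict[str, dict[str, ICCResult]] = {}
    excluded: list[str] = []
    for evaluator, sub in cv_table.groupby("evaluator_id", sort=True):
        results: dict[str, ICCResult] = {}
        ok = True
        for measure in MEASURES:
            vals = sub.assign(value=_measure_values(sub, measure, time_mode))
            mat = vals.pivot_table(
                index="subject_id", columns="repeat_index", values="value"
            ).dropna(axis=0)
            if mat.shape[1] < 2 or mat.shape[0] < 2:
                ok = False
                break
            results[measure] = icc(
                RatingsMatrix(mat.to_numpy(), measure=measure), form
            )
        if ok:
            per_evaluator[str(evaluator)] = results
        else:
            excluded.append(str(evaluator))
            warnings.warn(
                f"evaluator {evaluator!r} excluded from intraobserver analysis "
                "(fewer than 2 complete repeats)",
                stacklevel=2,
            )
    if not per_evaluator:
        raise ValueError("no evaluator has enough repeats for an intraobserver ICC")
    global_average = {
        m: float(np.mean([res[m].estimate for res in per_evaluator.values()]))
        for m in MEASURES
    }
    return IntraObserverResult(
        per_evaluator=per_evaluator, global_average=global_average, excluded=excluded
    )


def interobserver_analysis(
    cv_table: pd.DataFrame,
    form: str = "ICC(2,1)",
    time_mode: str = "interval",
    repeat: str = "first",
) -> InterObserverResult:
    """Agreement between evaluators over shared subjects.

    Targets are subjects; raters are evaluators.  Per (subject, evaluator)
    the first repeat is used (``repeat='mean'`` averages repeats).  Subjects
    not rated by every evaluator are dropped (complete-case).
    """
    if repeat not in ("first", "mean"):
        raise ValueError(f"repeat must be 'first' or 'mean', got {repeat!r}")
    per_measure: dict[str, ICCResult] = {}
    for measure in MEASURES:
        vals = cv_table.assign(value=_measure_values(cv_table, measure, time_mode))
        if repeat == "first":
            idx = vals.groupby(["subject_id", "evaluator_id"])["repeat_index"].idxmin()
            vals = vals.loc[idx]
            mat = vals.pivot_table(
                index="subject_id", columns="evaluator_id", values="value"
            )
        else:
            mat = vals.pivot_table(
                index="subject_id", columns="evaluator_id", values="value",
                aggfunc="mean",
            )
        if mat.shape[1] < 2:
            raise ValueError("interobserver analysis needs >= 2 evaluators")
        mat = mat.dropna(axis=0)
        if mat.shape[0] < 2:
            raise ValueError(
                "fewer than 2 subjects rated by all evaluators "
                "(disjoint or near-disjoint coverage)"
            )
        per_measure[measure] = icc(RatingsMatrix(mat.to_numpy(), measure=measure), form)
    return InterObserverResult(per_measure=per_measure)
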