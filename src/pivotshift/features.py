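"""Characteristic vectors and the four scalar pivot-segment features.

Features, all computed on the extracted pivot region:
  * sd_nv               population SD of the normalized values
  * max_ov              maximum of the original values (rad/s)
  * range_plus_mean_ov  (max - min) + mean of the original values (rad/s)
  * mean_square_ov      sum of squares / N of the original values ((rad/s)^2)
"""

from __future__ import annotations

import math
import warnings
from typing import Iterable, Optional, Union

import numpy as np
import pandas as pd

from .grading import ClassBins, cdp_grade
from .model import (
    FEATURE_COLUMNS,
    CharacteristicVector,
    FeatureVector,
    PivotSegment,
    StudySession,
)
from .preprocess import DetectedPeaks, PeakConfig, process_recording

__all__ = [
    "characteristic_vector",
    "compute_features",
    "extract_feature_table",
    "characteristic_table",
    "FEATURE_COLUMNS",
]

PeakInput = Union[DetectedPeaks, Iterable[tuple[float, float]]]


def characteristic_vector(peaks: PeakInput) -> CharacteristicVector:
    """Build the characteristic vector from exactly three detected peaks.

    Accepts a :class:`DetectedPeaks` or an iterable of (time_cs, amplitude)
    pairs in any order; the result is ordered by time.
    """
    if isinstance(peaks, DetectedPeaks):
        pairs = list(zip(peaks.times_cs, peaks.amplitudes))
    else:
        pairs = [(float(t), float(a)) for t, a in peaks]
    if len(pairs) != 3:
        raise ValueError(f"exactly 3 peaks required, got {len(pairs)}")
    pairs.sort(key=lambda p: p[0])
    times = tuple(p[0] for p in pairs)
    amps = tuple(p[1] for p in pairs)
    return CharacteristicVector(amplitudes=amps, times=times)


def compute_features(pivot: PivotSegment) -> FeatureVector:
    """Compute the four scalar features of one pivot segment."""
    ov = pivot.ov
    nv = pivot.nv
    n = len(ov)
    if n < 2:
        raise ValueError("pivot segment must have at least 2 samples")
    return FeatureVector(
        sd_nv=float(np.std(nv)),  # population (divide-by-N) SD
        max_ov=float(np.max(ov)),
        range_plus_mean_ov=float(np.max(ov) - np.min(ov) + np.mean(ov)),
        mean_square_ov=float(np.sum(ov * ov) / n),
    )


def characteristic_table(
    session: StudySession, config: PeakConfig = PeakConfig()
) -> pd.DataFrame:
    """One row per recording: ids plus peak amplitudes and times.

    Recordings whose peaks cannot be detected are skipped with a warning.
    """
    rows = []
    for rec in session.recordings:
        try:
            proc = process_recording(rec, config)
            cv = characteristic_vector(proc.peaks)
        except Exception as exc:  # noqa: BLE001 - degraded captures are expected
            warnings.warn(
                f"skipping recording ({rec.subject_id}, {rec.evaluator_id}, "
                f"{rec.repeat_index}): {exc}",
                stacklevel=2,
            )
            continue
        row = {
            "subject_id": rec.subject_id,
            "evaluator_id": rec.evaluator_id,
            "repeat_index": rec.repeat_index,
        }
        for k in range(3):
            row[f"amp{k + 1}"] = cv.amplitudes[k]
            row[f"time{k + 1}"] = cv.times[k]
        rows.append(row)
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.sort_values(
            ["subject_id", "evaluator_id", "repeat_index"], ignore_index=True
        )
    return df


def extract_feature_table(
    session: StudySession,
    config: PeakConfig = PeakConfig(),
    bins: ClassBins = ClassBins(),
    grades: Optional[dict[str, int]] = None,
) -> pd.DataFrame:
    """One row per (recording, maneuver) with features, CV entries, class, grade.

    The speed class is the bin of the recording's maximum peak amplitude.
    The grade comes from ``grades`` (subject_id -> grade) when given, else
    from the subject's KT-1000 readings; missing readings yield NaN.
    """
    rows = []
    for rec in session.recordings:
        try:
            proc = process_recording(rec, config)
            cv = characteristic_vector(proc.peaks)
        except Exception as exc:  # noqa: BLE001
            warnings.warn(
                f"skipping recording ({rec.subject_id}, {rec.evaluator_id}, "
                f"{rec.repeat_index}): {exc}",
                stacklevel=2,
            )
            continue
        klass = bins.bin(max(cv.amplitudes))
        if grades is not None:
            grade = grades.get(rec.subject_id, math.nan)
        else:
            subj = session.subject(rec.subject_id)
            if subj.kt1000_left_mm is None or subj.kt1000_right_mm is None:
                grade = math.nan
            else:
                grade = cdp_grade(subj.kt1000_left_mm, subj.kt1000_right_mm).grade
        for m, pivot in enumerate(proc.pivots):
            fv = compute_features(pivot)
            row = {
                "subject_id": rec.subject_id,
                "evaluator_id": rec.evaluator_id,
                "repeat_index": rec.repeat_index,
                "maneuver": m,
                **fv.to_dict(),
            }
            for k in range(3):
                row[f"amp{k + 1}"] = cv.amplitudes[k]
                row[f"time{k + 1}"] = cv.times[k]
            row["peak_amp"] = proc.peaks.amplitudes[m]
            row["klass"] = klass
            row["grade"] = grade
            rows.append(row)
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.sort_values(
            ["subject_id", "evaluator_id", "repeat_index", "maneuver"],
            ignore_index=True,
        )
    return df
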