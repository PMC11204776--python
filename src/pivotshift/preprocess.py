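"""Raw recording -> per-maneuver segments -> isolated pivot regions.

The X axis is the analysis axis.  Peak detection finds positive local
maxima with a prominence of at least a configurable fraction of the global
maximum, then selects the admissible subset of the expected size (peaks at
least ``min_separation_cs`` apart) that maximizes the summed amplitude,
breaking ties toward earlier peaks.  Segmentation follows the maneuver
anatomy: flexion runs from the rise onset to the peak, extension from the
peak to the trough, and the pivot from the trough to the next maneuver's
rise onset (or the window end).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import NamedTuple, Optional, Sequence

import numpy as np
from scipy.signal import find_peaks

from .errors import DegenerateSignalError, TooFewPeaksError
from .model import GyroRecording, ManeuverSegment, PivotSegment

__all__ = [
    "PeakConfig",
    "DetectedPeaks",
    "select_axis",
    "normalize_unit_interval",
    "detect_peaks",
    "segment_maneuvers",
    "extract_pivot",
    "process_recording",
    "ProcessedRecording",
]


@dataclass(frozen=True)
class PeakConfig:
    min_separation_cs: float = 50.0
    min_prominence_frac: float = 0.2
    expected_peaks: int = 3

    def __post_init__(self) -> None:
        if self.min_separation_cs < 1:
            raise ValueError("min_separation_cs must be >= 1")
        if not (0 < self.min_prominence_frac <= 1):
            raise ValueError("min_prominence_frac must be in (0, 1]")
        if self.expected_peaks < 1:
            raise ValueError("expected_peaks must be >= 1")


class DetectedPeaks(NamedTuple):
    """Selected peaks in time order: sample indices, times (cs), amplitudes (rad/s)."""

    indices: tuple[int, ...]
    times_cs: tuple[float, ...]
    amplitudes: tuple[float, ...]


def select_axis(recording: GyroRecording, axis: str) -> np.ndarray:
    """Project one axis ('x', 'y' or 'z') out of a recording."""
    return recording.axis(axis).copy()


def normalize_unit_interval(signal: Sequence[float]) -> np.ndarray:
    """Affinely map a signal so its minimum is 0 and maximum is 1."""
    arr = np.asarray(signal, dtype=float)
    if arr.ndim != 1 or len(arr) < 2:
        raise ValueError("signal must be one-dimensional with length >= 2")
    lo, hi = float(arr.min()), float(arr.max())
    if hi == lo:
        raise DegenerateSignalError(
            f"cannot normalize a constant signal (all values == {lo})"
        )
    return (arr - lo) / (hi - lo)


def _best_subset(
    idx: np.ndarray, amps: np.ndarray, k: int, min_sep: float
) -> Optional[tuple[int, ...]]:
    """Max-summed-amplitude subset of size k with pairwise spacing >= min_sep.

    Ties are broken toward the lexicographically earliest index tuple.
    Candidates are assumed sorted by index.  Exhaustive for small candidate
    sets, dynamic programming otherwise; both share the same objective.
    """
    m = len(idx)
    if m < k:
        return None
    if m <= 22:
        best = None
        for combo in combinations(range(m), k):
            ok = all(
                idx[combo[j + 1]] - idx[combo[j]] >= min_sep
                for j in range(k - 1)
            )
            if not ok:
                continue
            s = float(amps[list(combo)].sum())
            key = (-s, tuple(idx[list(combo)]))
            if best is None or key < best[0]:
                best = (key, combo)
        return None if best is None else tuple(int(idx[j]) for j in best[1])

    # DP over candidates: best[j][i] = best chain of j+1 peaks ending at i.
    NEG = (-np.inf, ())
    best = [[NEG] * m for _ in range(k)]
    for i in range(m):
        best[0][i] = (float(amps[i]), (int(idx[i]),))
    for j in range(1, k):
        for i in range(m):
            cand = NEG
            for p in range(i):
                if idx[i] - idx[p] < min_sep:
                    continue
                prev = best[j - 1][p]
                if prev[0] == -np.inf:
                    continue
                s = prev[0] + float(amps[i])
                t = prev[1] + (int(idx[i]),)
                if (s, tuple(-v for v in t)) > (cand[0], tuple(-v for v in cand[1])):
                    cand = (s, t)
            best[j][i] = cand
    final = max(
        (b for b in best[k - 1] if b[0] > -np.inf),
        key=lambda b: (b[0], tuple(-v for v in b[1])),
        default=None,
    )
    return None if final is None else final[1]


def detect_peaks(
    signal: Sequence[float],
    config: PeakConfig = PeakConfig(),
    times_cs: Optional[Sequence[float]] = None,
) -> DetectedPeaks:
    """Find the maneuver peaks of a 1-D X-axis signal.

    Returns exactly ``config.expected_peaks`` peaks in time order; raises
    :class:`TooFewPeaksError` (carrying the peaks that were found) when the
    signal does not admit that many.
    """
    arr = np.asarray(signal, dtype=float)
    if arr.ndim != 1 or len(arr) < 3:
        raise ValueError("signal must be one-dimensional with length >= 3")
    if np.ptp(arr) == 0:
        raise DegenerateSignalError("constant signal has no peaks")
    gmax = float(arr.max())
    if gmax <= 0:
        raise DegenerateSignalError("signal has no positive excursion")

    threshold = config.min_prominence_frac * gmax
    cand, _ = find_peaks(arr, prominence=threshold)
    cand = cand.astype(int)
    amps = arr[cand]

    chosen = _best_subset(cand, amps, config.expected_peaks, config.min_separation_cs)
    if chosen is None:
        # report the largest admissible subset that does exist
        for k in range(min(config.expected_peaks - 1, len(cand)), 0, -1):
            fallback = _best_subset(cand, amps, k, config.min_separation_cs)
            if fallback is not None:
                raise TooFewPeaksError(
                    config.expected_peaks, fallback, [float(arr[i]) for i in fallback]
                )
        raise TooFewPeaksError(config.expected_peaks, [], [])

    indices = tuple(sorted(chosen))
    if times_cs is None:
        t = tuple(float(i) for i in indices)
    else:
        tarr = np.asarray(times_cs, dtype=float)
        t = tuple(float(tarr[i]) for i in indices)
    return DetectedPeaks(
        indices=indices, times_cs=t, amplitudes=tuple(float(arr[i]) for i in indices)
    )


def segment_maneuvers(
    signal: Sequence[float],
    peak_indices: Sequence[int],
    *,
    rise_fraction: float = 0.1,
    trough_horizon_cs: float = 100.0,
) -> list[tuple[ManeuverSegment, ManeuverSegment, ManeuverSegment]]:
    """Split the signal into (flexion, extension, pivot) triplets per peak.

    flexion = [rise onset, peak); extension = [peak, trough);
    pivot = [trough, next rise onset) or [trough, window end) for the last
    maneuver.  The rise onset is the last sample before the peak at which
    the signal falls below ``rise_fraction`` of that peak's height.
    """
    arr = np.asarray(signal, dtype=float)
    n = len(arr)
    peaks = sorted(int(p) for p in peak_indices)
    if len(peaks) == 0:
        raise ValueError("at least one peak index is required")
    if peaks[0] < 0 or peaks[-1] >= n:
        raise ValueError("peak indices out of bounds")

    def rise_onset(p: int, lower: int) -> int:
        thr = rise_fraction * arr[p]
        j = p
        while j > lower and arr[j - 1] > thr:
            j -= 1
        return min(j, p - 1) if p > lower else p - 1

    # troughs between consecutive peaks; after the last peak within a horizon
    troughs: list[int] = []
    for i, p in enumerate(peaks):
        if i + 1 < len(peaks):
            lo, hi = p, peaks[i + 1]
        else:
            lo, hi = p, min(n, p + int(trough_horizon_cs) + 1)
        tr = lo + int(np.argmin(arr[lo:hi]))
        troughs.append(max(tr, p + 1))

    triplets = []
    prev_trough = 0
    for i, p in enumerate(peaks):
        lower = prev_trough if i > 0 else 0
        rise = max(rise_onset(p, lower), lower)
        trough = min(troughs[i], n - 1)
        if i + 1 < len(peaks):
            nxt_lower = trough
            nxt_rise = max(rise_onset(peaks[i + 1], nxt_lower), nxt_lower)
            pivot_end = max(nxt_rise, trough + 1)
        else:
            pivot_end = n
        if pivot_end - trough < 2:
            warnings.warn(
                f"pivot window after peak at index {p} truncated to "
                f"{pivot_end - trough} sample(s)",
                stacklevel=2,
            )
            pivot_end = min(max(pivot_end, trough + 1), n)
        triplets.append(
            (
                ManeuverSegment(rise, p, "flexion", p),
                ManeuverSegment(p, trough, "extension", p),
                ManeuverSegment(trough, pivot_end, "pivot", p),
            )
        )
        prev_trough = trough
    return triplets


def extract_pivot(
    signal: Sequence[float],
    normalized: Sequence[float],
    segment: ManeuverSegment,
    source=None,
) -> PivotSegment:
    """Slice the pivot region out of aligned original and normalized signals."""
    if segment.phase != "pivot":
        raise ValueError(f"segment phase must be 'pivot', got {segment.phase!r}")
    arr = np.asarray(signal, dtype=float)
    nrm = np.asarray(normalized, dtype=float)
    if len(arr) != len(nrm):
        raise ValueError("signal and normalized signal must have equal length")
    if segment.end_index > len(arr):
        raise ValueError("segment exceeds signal bounds")
    if len(segment) < 2:
        raise ValueError(f"pivot segment too short ({len(segment)} sample(s))")
    return PivotSegment(
        ov=arr[segment.slice].copy(), nv=nrm[segment.slice].copy(), source=source
    )


@dataclass(eq=False)
class ProcessedRecording:
    """Everything the feature stage needs from one recording."""

    signal: np.ndarray
    normalized: np.ndarray
    peaks: DetectedPeaks
    segments: list[tuple[ManeuverSegment, ManeuverSegment, ManeuverSegment]]
    pivots: list[PivotSegment]


def process_recording(
    recording: GyroRecording, config: PeakConfig = PeakConfig()
) -> ProcessedRecording:
    """Run the full preprocessing chain on a recording's X axis.

    Normalization is per whole recording so normalized pivot values are
    comparable across the maneuvers of one capture.
    """
    sig = select_axis(recording, "x")
    nrm = normalize_unit_interval(sig)
    peaks = detect_peaks(sig, config, times_cs=recording.t)
    segs = segment_maneuvers(sig, peaks.indices)
    pivots = [
        extract_pivot(
            sig,
            nrm,
            trip[2],
            source=(recording.subject_id, recording.evaluator_id,
                    recording.repeat_index, i),
        )
        for i, trip in enumerate(segs)
    ]
    return ProcessedRecording(
        signal=sig, normalized=nrm, peaks=peaks, segments=segs, pivots=pivots
    )
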