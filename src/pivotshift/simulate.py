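"""Synthetic gyroscope recordings shaped like pivot-shift exam captures.

A nominal capture is 5 s at 100 Hz (500 samples).  The X axis carries
``n_maneuvers`` repetitions of a flexion peak (raised-cosine lobe), an
extension trough, and a "pivot" (joint-reduction) region whose morphology
depends on the speed class: a damped sinusoid for classes 1-4 and a
flat-topped plateau for class 0.  Y and Z carry low-amplitude noise only.

All randomness flows from one root seed; per-recording streams are derived
by stable hashing of (subject, evaluator, repeat) so cohorts are
reproducible regardless of generation order.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .grading import DEFAULT_CLASS_EDGES, cdp_grade
from .model import GyroRecording, StudySession, SubjectRecord

__all__ = [
    "SimParams",
    "RaterProfile",
    "simulate_recording",
    "simulate_recording_with_truth",
    "simulate_cohort",
    "apply_rater_effect",
    "CLASS_AMP_CENTERS",
]

# Flexion-peak amplitude centers per speed class; chosen to sit well inside
# the default class bins [50, 100, 150, 200] rad/s with wide gaps.
CLASS_AMP_CENTERS = (30.0, 80.0, 130.0, 180.0, 230.0)

# Pivot-region morphology knobs.  Classes 1-4: damped sinusoid with a
# relative amplitude of PIVOT_REL_AMP times the flexion peak; the laxity
# grade modulates cycle count and damping so grades are distinguishable
# from pivot morphology alone.  Class 0: plateau whose relative height
# grows geometrically with grade but stays below the peak-detection
# prominence threshold (20% of the global maximum).
PIVOT_REL_AMP = 0.60
PLATEAU_REL_BASE = 0.04
PLATEAU_REL_STEP = 1.55


def _stable_hash(text: str) -> int:
    return zlib.crc32(str(text).encode("utf-8"))


def _rng_for(*entropy: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(e) & 0xFFFFFFFF for e in entropy]))


@dataclass(frozen=True)
class SimParams:
    """Parameters of one simulated recording."""

    n_maneuvers: int = 3
    peak_times_cs: Optional[Sequence[float]] = None
    peak_amplitudes: Optional[Sequence[float]] = None
    klass: int = 2
    grade: int = 0
    noise_sd: float = 0.5
    flexion_width_cs: float = 40.0
    extension_width_cs: float = 40.0
    pivot_width_cs: float = 110.0
    sample_rate: float = 100.0
    duration: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_maneuvers < 1:
            raise ValueError("n_maneuvers must be >= 1")
        if self.klass not in (0, 1, 2, 3, 4):
            raise ValueError(f"klass must be in 0..4, got {self.klass}")
        if self.grade not in (0, 1, 2, 3):
            raise ValueError(f"grade must be in 0..3, got {self.grade}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class RaterProfile:
    """Systematic evaluator effect: amplitude gain and peak-time jitter."""

    amplitude_gain: float = 1.0
    time_jitter_sd_cs: float = 0.0
    seed_offset: int = 0

    def __post_init__(self) -> None:
        if self.amplitude_gain <= 0:
            raise ValueError("amplitude_gain must be > 0")
        if self.time_jitter_sd_cs < 0:
            raise ValueError("time_jitter_sd_cs must be >= 0")


def _raised_cos(n: int, center: float, half_width: float, height: float) -> np.ndarray:
    """Raised-cosine lobe: `height` at `center`, zero beyond +/- half_width."""
    lo = max(0, int(np.floor(center - half_width)))
    hi = min(n, int(np.ceil(center + half_width)) + 1)
    out = np.zeros(n)
    if hi <= lo:
        return out
    i = np.arange(lo, hi)
    u = (i - center) / half_width
    mask = np.abs(u) <= 1.0
    out[lo:hi][mask] = height * np.cos(np.pi * u[mask] / 2.0) ** 2
    return out


def _pivot_wave(length: int, cycles: float, decay: float) -> np.ndarray:
    """Damped sinusoid on [0, 1), tapered to zero at both ends."""
    u = np.arange(length) / length
    return np.exp(-decay * u) * np.sin(2 * np.pi * cycles * u) * (1.0 - u)


def _plateau_wave(length: int, ramp: int = 10) -> np.ndarray:
    """Flat-topped lobe with smooth cosine ramps at both ends."""
    ramp = min(ramp, length // 2)
    w = np.ones(length)
    if ramp > 0:
        edge = np.sin(np.linspace(0, np.pi / 2, ramp, endpoint=False)) ** 2
        w[:ramp] = edge
        w[-ramp:] = edge[::-1]
    return w


def _synthesize(params: SimParams, rng: np.random.Generator):
    n = int(round(params.sample_rate * params.duration))
    hf = params.flexion_width_cs / 2.0
    ew = params.extension_width_cs
    he = ew / 2.0

    if params.peak_times_cs is not None:
        times = np.asarray(params.peak_times_cs, dtype=float)
        if len(times) != params.n_maneuvers:
            raise ValueError(
                f"peak_times_cs has {len(times)} entries for "
                f"{params.n_maneuvers} maneuvers"
            )
        if np.any(times < 0) or np.any(times >= n):
            raise ValueError(f"peak times must lie within [0, {n}), got {times.tolist()}")
        if not np.all(np.diff(times) > 0):
            raise ValueError(f"peak times must be strictly increasing, got {times.tolist()}")
    else:
        # keep the last pivot window inside the capture window
        start = rng.uniform(65.0, 90.0)
        gaps = rng.uniform(130.0, 155.0, size=params.n_maneuvers - 1)
        times = start + np.concatenate([[0.0], np.cumsum(gaps)])
    if np.any(np.diff(times) < params.flexion_width_cs):
        raise ValueError(
            "peak times closer than the flexion width "
            f"({params.flexion_width_cs} cs): {times.tolist()}"
        )

    if params.peak_amplitudes is not None:
        amps = np.asarray(params.peak_amplitudes, dtype=float)
        if len(amps) != params.n_maneuvers:
            raise ValueError(
                f"peak_amplitudes has {len(amps)} entries for "
                f"{params.n_maneuvers} maneuvers"
            )
        if np.any(amps <= 0):
            raise ValueError("peak amplitudes must be positive")
    else:
        center = CLASS_AMP_CENTERS[params.klass]
        amps = center + rng.uniform(-5.0, 5.0, size=params.n_maneuvers)

    x = np.zeros(n)
    peak_idx = np.rint(times).astype(int)
    pivot_windows: list[tuple[int, int]] = []
    for i, (p, a) in enumerate(zip(peak_idx, amps)):
        x += _raised_cos(n, p, hf, a)
        x += _raised_cos(n, p + hf + he, he, -0.6 * a)
        ps = int(round(p + hf + ew))
        if i + 1 < len(peak_idx):
            limit = int(peak_idx[i + 1] - hf)
        else:
            limit = n
        pe = min(ps + int(params.pivot_width_cs), limit, n)
        length = pe - ps
        if length >= 8:
            if params.klass >= 1:
                cycles = 2.0 + params.grade
                decay = 4.8 - 1.3 * params.grade
                wave = PIVOT_REL_AMP * a * _pivot_wave(length, cycles, decay)
            else:
                rel = PLATEAU_REL_BASE * PLATEAU_REL_STEP ** params.grade
                wave = rel * a * _plateau_wave(length)
            x[ps:pe] += wave
            pivot_windows.append((ps, pe))

    if params.noise_sd > 0:
        x = x + rng.normal(0.0, params.noise_sd, n)
        y = rng.normal(0.0, 0.3 * params.noise_sd, n)
        z = rng.normal(0.0, 0.3 * params.noise_sd, n)
    else:
        y = np.zeros(n)
        z = np.zeros(n)

    truth = {
        "peak_indices": peak_idx.tolist(),
        "peak_times_cs": times.tolist(),
        "peak_amplitudes": amps.tolist(),
        "pivot_windows": pivot_windows,
        "klass": params.klass,
        "grade": params.grade,
    }
    return x, y, z, truth


def simulate_recording_with_truth(
    params: SimParams,
    subject_id: str = "sim",
    evaluator_id: str = "sim",
    repeat_index: int = 1,
) -> tuple[GyroRecording, dict]:
    """Like :func:`simulate_recording` but also returns ground truth
    (peak locations/amplitudes, pivot windows, class, grade)."""
    rng = _rng_for(
        params.seed, _stable_hash(subject_id), _stable_hash(evaluator_id), repeat_index
    )
    x, y, z, truth = _synthesize(params, rng)
    n = len(x)
    rec = GyroRecording(
        subject_id=str(subject_id),
        evaluator_id=str(evaluator_id),
        repeat_index=int(repeat_index),
        t=np.arange(n, dtype=float) * (100.0 / params.sample_rate),
        x=x,
        y=y,
        z=z,
        sample_rate=params.sample_rate,
        duration=params.duration,
    )
    return rec, truth


def simulate_recording(
    params: SimParams,
    subject_id: str = "sim",
    evaluator_id: str = "sim",
    repeat_index: int = 1,
) -> GyroRecording:
    """Simulate one tri-axial recording; deterministic given params + ids."""
    rec, _ = simulate_recording_with_truth(params, subject_id, evaluator_id, repeat_index)
    return rec


def apply_rater_effect(recording: GyroRecording, profile: RaterProfile) -> GyroRecording:
    """Scale amplitudes by the rater gain and shift the signal in time.

    The time shift is one draw from N(0, time_jitter_sd) rounded to whole
    samples (the sampling grid is 1 cs); vacated samples are zero-filled.
    Deterministic given the profile seed and the recording identity.
    """
    rng = _rng_for(
        profile.seed_offset,
        _stable_hash(recording.subject_id),
        _stable_hash(recording.evaluator_id),
        recording.repeat_index,
    )
    shift = 0
    if profile.time_jitter_sd_cs > 0:
        shift = int(round(rng.normal(0.0, profile.time_jitter_sd_cs)))

    def _move(a: np.ndarray) -> np.ndarray:
        out = a * profile.amplitude_gain
        if shift > 0:
            out = np.concatenate([np.zeros(shift), out[:-shift]])
        elif shift < 0:
            out = np.concatenate([out[-shift:], np.zeros(-shift)])
        return out

    return GyroRecording(
        subject_id=recording.subject_id,
        evaluator_id=recording.evaluator_id,
        repeat_index=recording.repeat_index,
        t=recording.t.copy(),
        x=_move(recording.x),
        y=_move(recording.y),
        z=_move(recording.z),
        sample_rate=recording.sample_rate,
        duration=recording.duration,
    )


_GRADE_MM_DIFF = {0: (0, 2), 1: (3, 3), 2: (4, 5), 3: (6, 9)}


def _enforce_spacing(times: np.ndarray, min_gap: float, lo: float, hi: float) -> np.ndarray:
    t = np.clip(np.sort(times), lo, hi)
    for i in range(1, len(t)):
        t[i] = max(t[i], t[i - 1] + min_gap)
    return np.clip(t, lo, hi + (len(t) - 1) * 0.0)


def simulate_cohort(
    grade_counts: Mapping[int, int],
    raters: Optional[Sequence[RaterProfile]] = None,
    repeats_per_subject: int = 1,
    seed: int = 0,
    *,
    noise_sd: Optional[float] = None,
    noise_frac: float = 0.02,
    class_policy: str = "speed-from-grade",
    class_edges: Sequence[float] = DEFAULT_CLASS_EDGES,
) -> tuple[StudySession, pd.DataFrame]:
    """Simulate a full cohort and return (session, truth table).

    One subject per requested grade slot; each subject is recorded
    ``repeats_per_subject`` times by every rater.  KT-1000 mm values are
    drawn so the grading map reproduces the requested grade exactly.

    class_policy:
      * ``"speed-from-grade"`` (default): the speed class is grade + 1,
        giving well-separated grade morphologies (higher laxity, faster
        maneuver).
      * ``"random"``: uniform class 0-4 per subject.

    The truth table has one row per recording with the requested grade and
    the realized speed class (bin of the maximum peak amplitude).
    """
    grade_counts = {int(g): int(c) for g, c in grade_counts.items()}
    if any(c < 0 for c in grade_counts.values()):
        raise ValueError("grade counts must be >= 0")
    n_subjects = sum(grade_counts.values())
    if n_subjects == 0:
        raise ValueError("empty cohort: all grade counts are zero")
    if any(g not in (0, 1, 2, 3) for g in grade_counts):
        raise ValueError("grades must be in 0..3")
    if raters is None:
        raters = [RaterProfile()]
    if len(raters) == 0:
        raise ValueError("at least one rater profile is required")
    if repeats_per_subject < 1:
        raise ValueError("repeats_per_subject must be >= 1")
    if class_policy not in ("speed-from-grade", "random"):
        raise ValueError(f"unknown class_policy {class_policy!r}")

    edges = np.asarray(class_edges, dtype=float)
    subjects: list[SubjectRecord] = []
    recordings: list[GyroRecording] = []
    truth_rows: list[dict] = []
    evaluator_ids = [f"E{j + 1}" for j in range(len(raters))]

    sidx = 0
    for grade in sorted(grade_counts):
        for _ in range(grade_counts[grade]):
            sidx += 1
            sid = f"S{sidx:03d}"
            srng = _rng_for(seed, 3, _stable_hash(sid))

            d_lo, d_hi = _GRADE_MM_DIFF[grade]
            diff = int(srng.integers(d_lo, d_hi + 1))
            base = int(srng.integers(4, 11))
            if srng.random() < 0.5 and base - diff >= 0:
                left, right = base, base - diff
            else:
                left, right = base + diff, base
            subjects.append(
                SubjectRecord(
                    subject_id=sid,
                    initials=f"P{sidx:02d}",
                    age=float(srng.integers(18, 38)),
                    gender=str(srng.choice(["F", "M"])),
                    height_cm=float(np.round(srng.normal(168, 9), 1)),
                    weight_kg=float(np.round(srng.normal(70, 12), 1)),
                    kt1000_left_mm=float(left),
                    kt1000_right_mm=float(right),
                )
            )
            assert cdp_grade(left, right).grade == grade

            if class_policy == "speed-from-grade":
                klass = min(grade + 1, 4)
            else:
                klass = int(srng.integers(0, 5))
            center = CLASS_AMP_CENTERS[klass]

            # Subject-level base maneuver geometry (what the ICC analysis
            # treats as the target's true value).
            start = srng.uniform(68.0, 82.0)
            gaps = srng.uniform(133.0, 147.0, size=2)
            base_times = start + np.concatenate([[0.0], np.cumsum(gaps)])
            base_amps = center + srng.uniform(-2.0, 2.0, size=3)

            for eid, prof in zip(evaluator_ids, raters):
                for rep in range(1, repeats_per_subject + 1):
                    rrng = _rng_for(
                        seed, 7, _stable_hash(sid), _stable_hash(eid), rep
                    )
                    times = base_times.copy()
                    if prof.time_jitter_sd_cs > 0:
                        times = times + rrng.normal(0.0, prof.time_jitter_sd_cs, 3)
                    times = times + rrng.normal(0.0, 1.5, 3)
                    times = _enforce_spacing(times, 55.0, 40.0, 465.0)
                    amps = base_amps * prof.amplitude_gain
                    amps = amps * (1.0 + rrng.normal(0.0, 0.01, 3))
                    amps = np.maximum(amps, 1.0)
                    rec_noise = (
                        noise_sd if noise_sd is not None else noise_frac * center
                    )
                    params = SimParams(
                        n_maneuvers=3,
                        peak_times_cs=times.tolist(),
                        peak_amplitudes=amps.tolist(),
                        klass=klass,
                        grade=grade,
                        noise_sd=rec_noise,
                        seed=seed,
                    )
                    rec = simulate_recording(params, sid, eid, rep)
                    recordings.append(rec)
                    max_amp = float(np.max(amps))
                    realized = int(np.searchsorted(edges, max_amp, side="right"))
                    truth_rows.append(
                        {
                            "subject_id": sid,
                            "evaluator_id": eid,
                            "repeat_index": rep,
                            "grade": grade,
                            "klass": realized,
                            "morphology_klass": klass,
                            "max_peak_amp": max_amp,
                        }
                    )

    session = StudySession(
        subjects=subjects,
        recordings=recordings,
        evaluators=evaluator_ids,
        provenance=f"simulated cohort (seed={seed}, policy={class_policy})",
        seed=seed,
    )
    return session, pd.DataFrame(truth_rows)
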