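"""Core domain types shared across the package.

Time is measured in centiseconds (cs) throughout: at the nominal 100 Hz
sampling rate one sample corresponds to one centisecond, so sample indices
and times coincide.  Angular velocity is in rad/s.  Sample-index intervals
are half-open ``[start, end)`` and 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Any, Iterable, Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "GyroRecording",
    "SubjectRecord",
    "CharacteristicVector",
    "ManeuverSegment",
    "PivotSegment",
    "FeatureVector",
    "CDPGrade",
    "ManeuverClass",
    "StudySession",
    "PHASES",
]

PHASES = ("flexion", "extension", "pivot")


def _farray(values: Iterable[float], name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


@dataclass(eq=False)
class GyroRecording:
    """One tri-axial angular-velocity capture (nominally 5 s at 100 Hz)."""

    subject_id: str
    evaluator_id: str
    repeat_index: int
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    sample_rate: float = 100.0
    duration: float = 5.0

    def __post_init__(self) -> None:
        self.t = _farray(self.t, "t")
        self.x = _farray(self.x, "x")
        self.y = _farray(self.y, "y")
        self.z = _farray(self.z, "z")
        n = len(self.t)
        if not (len(self.x) == len(self.y) == len(self.z) == n):
            raise ValueError(
                "axis arrays must share one length, got "
                f"t={n} x={len(self.x)} y={len(self.y)} z={len(self.z)}"
            )
        if n >= 2 and not np.all(np.diff(self.t) > 0):
            raise ValueError("t must be strictly increasing")
        if int(self.repeat_index) < 1:
            raise ValueError(f"repeat_index must be >= 1, got {self.repeat_index}")
        self.repeat_index = int(self.repeat_index)
        if self.sample_rate <= 0 or self.duration <= 0:
            raise ValueError("sample_rate and duration must be positive")

    @property
    def n_samples(self) -> int:
        return len(self.t)

    @property
    def nominal_samples(self) -> int:
        return int(round(self.sample_rate * self.duration))

    def axis(self, name: str) -> np.ndarray:
        try:
            return {"x": self.x, "y": self.y, "z": self.z}[name]
        except KeyError:
            raise ValueError(f"unknown axis {name!r}; expected one of x, y, z") from None

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GyroRecording):
            return NotImplemented
        return (
            self.subject_id == other.subject_id
            and self.evaluator_id == other.evaluator_id
            and self.repeat_index == other.repeat_index
            and self.sample_rate == other.sample_rate
            and self.duration == other.duration
            and np.array_equal(self.t, other.t)
            and np.array_equal(self.x, other.x)
            and np.array_equal(self.y, other.y)
            and np.array_equal(self.z, other.z)
        )

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "evaluator_id": self.evaluator_id,
            "repeat_index": self.repeat_index,
            "sample_rate": self.sample_rate,
            "duration": self.duration,
            "t": self.t.tolist(),
            "x": self.x.tolist(),
            "y": self.y.tolist(),
            "z": self.z.tolist(),
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "GyroRecording":
        return cls(**dict(d))


@dataclass(frozen=True)
class SubjectRecord:
    """Demographics plus KT-1000 arthrometry for one participant."""

    subject_id: str
    initials: str = ""
    age: Optional[float] = None
    gender: Optional[str] = None
    height_cm: Optional[float] = None
    weight_kg: Optional[float] = None
    kt1000_left_mm: Optional[float] = None
    kt1000_right_mm: Optional[float] = None
    ikdc_label: Optional[str] = None
    notes: Optional[str] = None

    def __post_init__(self) -> None:
        for name in ("kt1000_left_mm", "kt1000_right_mm"):
            v = getattr(self, name)
            if v is not None and (not np.isfinite(v) or v < 0):
                raise ValueError(f"{name} must be finite and >= 0, got {v}")

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "SubjectRecord":
        return cls(**dict(d))


@dataclass(frozen=True)
class CharacteristicVector:
    """Three positive-peak amplitudes (rad/s) and peak times (cs), in time order."""

    amplitudes: tuple[float, float, float]
    times: tuple[float, float, float]

    def __post_init__(self) -> None:
        amps = tuple(float(a) for a in self.amplitudes)
        times = tuple(float(t) for t in self.times)
        if len(amps) != 3 or len(times) != 3:
            raise ValueError(
                f"exactly three peaks required, got {len(amps)} amplitudes "
                f"and {len(times)} times"
            )
        if not (times[0] < times[1] < times[2]):
            raise ValueError(f"peak times must be strictly increasing, got {times}")
        if any(a <= 0 for a in amps):
            raise ValueError(f"peak amplitudes must be positive, got {amps}")
        object.__setattr__(self, "amplitudes", amps)
        object.__setattr__(self, "times", times)

    @property
    def intervals(self) -> tuple[float, float]:
        """Inter-peak intervals in cs (maneuver-to-maneuver timing)."""
        return (self.times[1] - self.times[0], self.times[2] - self.times[1])

    def to_dict(self) -> dict:
        return {"amplitudes": list(self.amplitudes), "times": list(self.times)}

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "CharacteristicVector":
        return cls(tuple(d["amplitudes"]), tuple(d["times"]))


@dataclass(frozen=True)
class ManeuverSegment:
    """Half-open sample-index interval of one phase of one maneuver."""

    start_index: int
    end_index: int
    phase: str
    peak_index: int

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise ValueError(f"phase must be one of {PHASES}, got {self.phase!r}")
        if not (0 <= self.start_index < self.end_index):
            raise ValueError(
                f"need 0 <= start < end, got [{self.start_index}, {self.end_index})"
            )

    def __len__(self) -> int:
        return self.end_index - self.start_index

    @property
    def slice(self) -> slice:
        return slice(self.start_index, self.end_index)

    def to_dict(self) -> dict:
        return {
            "start_index": self.start_index,
            "end_index": self.end_index,
            "phase": self.phase,
            "peak_index": self.peak_index,
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "ManeuverSegment":
        return cls(**dict(d))


@dataclass(eq=False)
class PivotSegment:
    """Joint-reduction slice of the X-axis signal, original + normalized values."""

    ov: np.ndarray
    nv: np.ndarray
    source: Any = None  # (recording id, maneuver index) or similar

    def __post_init__(self) -> None:
        self.ov = _farray(self.ov, "ov")
        self.nv = _farray(self.nv, "nv")
        if len(self.ov) != len(self.nv):
            raise ValueError(
                f"ov and nv must align, got {len(self.ov)} vs {len(self.nv)}"
            )
        if len(self.ov) < 2:
            raise ValueError(f"pivot segment needs >= 2 samples, got {len(self.ov)}")
        # tolerate float round-off at the interval edges
        if self.nv.min() < -1e-12 or self.nv.max() > 1 + 1e-12:
            raise ValueError("nv values must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.ov)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PivotSegment):
            return NotImplemented
        return (
            np.array_equal(self.ov, other.ov)
            and np.array_equal(self.nv, other.nv)
            and self.source == other.source
        )

    def to_dict(self) -> dict:
        return {"ov": self.ov.tolist(), "nv": self.nv.tolist(), "source": self.source}

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "PivotSegment":
        return cls(**dict(d))


@dataclass(frozen=True)
class FeatureVector:
    """The four scalar features of one pivot segment.

    sd_nv uses the population (divide-by-N) standard deviation, matching the
    divide-by-N convention of mean_square_ov.
    """

    sd_nv: float
    max_ov: float
    range_plus_mean_ov: float
    mean_square_ov: float

    def __post_init__(self) -> None:
        if not (-1e-12 <= self.sd_nv <= 0.5 + 1e-12):
            raise ValueError(f"sd_nv must lie in [0, 0.5], got {self.sd_nv}")
        if self.mean_square_ov < 0:
            raise ValueError(f"mean_square_ov must be >= 0, got {self.mean_square_ov}")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.sd_nv, self.max_ov, self.range_plus_mean_ov, self.mean_square_ov]
        )

    def to_dict(self) -> dict:
        return {
            "sd_nv": self.sd_nv,
            "max_ov": self.max_ov,
            "range_plus_mean_ov": self.range_plus_mean_ov,
            "mean_square_ov": self.mean_square_ov,
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "FeatureVector":
        return cls(**dict(d))


FEATURE_COLUMNS = ("sd_nv", "max_ov", "range_plus_mean_ov", "mean_square_ov")


@dataclass(frozen=True)
class CDPGrade:
    """Laxity grade 0-3 derived from a KT-1000 side-to-side mm difference."""

    grade: int
    mm_difference: float

    def __post_init__(self) -> None:
        if self.grade not in (0, 1, 2, 3):
            raise ValueError(f"grade must be in 0..3, got {self.grade}")
        if self.mm_difference < 0:
            raise ValueError(f"mm_difference must be >= 0, got {self.mm_difference}")

    def to_dict(self) -> dict:
        return {"grade": self.grade, "mm_difference": self.mm_difference}

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "CDPGrade":
        return cls(**dict(d))


@dataclass(frozen=True)
class ManeuverClass:
    """Speed-based maneuver class 0-4 with the peak speed it was binned on."""

    klass: int
    peak_speed: float

    def __post_init__(self) -> None:
        if self.klass not in (0, 1, 2, 3, 4):
            raise ValueError(f"klass must be in 0..4, got {self.klass}")
        if self.peak_speed < 0:
            raise ValueError(f"peak_speed must be >= 0, got {self.peak_speed}")

    def to_dict(self) -> dict:
        return {"klass": self.klass, "peak_speed": self.peak_speed}

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "ManeuverClass":
        return cls(**dict(d))


@dataclass(eq=False)
class StudySession:
    """Cohort container: subjects x evaluators x repeats plus provenance."""

    subjects: list[SubjectRecord] = field(default_factory=list)
    recordings: list[GyroRecording] = field(default_factory=list)
    evaluators: list[str] = field(default_factory=list)
    provenance: str = ""
    seed: Optional[int] = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = {s.subject_id for s in self.subjects}
        evs = set(self.evaluators)
        for rec in self.recordings:
            if rec.subject_id not in ids:
                raise ValueError(
                    f"recording references unknown subject {rec.subject_id!r}"
                )
            if rec.evaluator_id not in evs:
                raise ValueError(
                    f"recording references unknown evaluator {rec.evaluator_id!r}"
                )

    def subject(self, subject_id: str) -> SubjectRecord:
        for s in self.subjects:
            if s.subject_id == subject_id:
                return s
        raise KeyError(subject_id)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, StudySession):
            return NotImplemented
        return (
            self.subjects == other.subjects
            and self.recordings == other.recordings
            and self.evaluators == other.evaluators
            and self.provenance == other.provenance
            and self.seed == other.seed
            and self.extra == other.extra
        )
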