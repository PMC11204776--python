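"""Laxity grading from KT-1000 side-to-side differences and speed-class binning.

The grading map (grade 0: difference 0-2 mm, 1: 3 mm, 2: 4-5 mm,
3: >= 6 mm) is total over non-negative differences: the difference is
rounded to the nearest whole millimeter (half away from zero) first, and
the open gap between 5 and 6 mm therefore cannot occur.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence, Union

import numpy as np

from .model import CDPGrade, ManeuverClass

__all__ = ["cdp_grade", "grade_from_difference", "assign_class", "ClassBins",
           "DEFAULT_CLASS_EDGES"]

#: Default speed-class bin edges in rad/s (boundaries are configurable).
DEFAULT_CLASS_EDGES = (50.0, 100.0, 150.0, 200.0)


def grade_from_difference(mm_difference: float) -> int:
    """Map a non-negative KT-1000 mm difference to a laxity grade 0-3."""
    if mm_difference < 0 or not math.isfinite(mm_difference):
        raise ValueError(f"mm difference must be finite and >= 0, got {mm_difference}")
    d = int(math.floor(mm_difference + 0.5))  # round half up
    if d <= 2:
        return 0
    if d == 3:
        return 1
    if d <= 5:
        return 2
    return 3


def cdp_grade(left_mm: float, right_mm: float) -> CDPGrade:
    """Grade knee laxity from KT-1000 readings of both legs (mm)."""
    for name, v in (("left_mm", left_mm), ("right_mm", right_mm)):
        if v is None:
            raise ValueError(f"{name} is missing; both sides are required")
        if not math.isfinite(v) or v < 0:
            raise ValueError(f"{name} must be finite and >= 0, got {v}")
    diff = abs(float(left_mm) - float(right_mm))
    return CDPGrade(grade=grade_from_difference(diff), mm_difference=diff)


@dataclass(frozen=True)
class ClassBins:
    """Strictly increasing rad/s thresholds splitting peak speed into 5 classes."""

    edges: Sequence[float] = DEFAULT_CLASS_EDGES

    def __post_init__(self) -> None:
        edges = tuple(float(e) for e in self.edges)
        if len(edges) != 4:
            raise ValueError(f"exactly 4 edges define 5 classes, got {len(edges)}")
        if not all(a < b for a, b in zip(edges, edges[1:])):
            raise ValueError(f"edges must be strictly increasing, got {edges}")
        object.__setattr__(self, "edges", edges)

    def bin(self, speed: float) -> int:
        return int(np.searchsorted(self.edges, speed, side="right"))


def assign_class(
    peaks: Union[float, Iterable[float]], bins: ClassBins = ClassBins()
) -> ManeuverClass:
    """Bin the maximum peak angular speed (rad/s) into a maneuver class 0-4."""
    if np.isscalar(peaks):
        speeds = np.asarray([peaks], dtype=float)
    else:
        speeds = np.asarray(list(peaks), dtype=float)
    if speeds.size == 0:
        raise ValueError("no peaks supplied; at least one peak speed is required")
    if np.any(speeds < 0) or not np.all(np.isfinite(speeds)):
        raise ValueError("peak speeds must be finite and >= 0")
    top = float(speeds.max())
    return ManeuverClass(klass=bins.bin(top), peak_speed=top)
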