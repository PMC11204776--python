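"""Plain-text persistence: recording CSVs, JSON session manifests, tables.

Recording files are UTF-8 comma-separated with the mandatory header
``t_cs,gx_rad_s,gy_rad_s,gz_rad_s``; times are integer centiseconds and
axis values are written with ``repr`` so floats round-trip exactly.  A
session is a ``session.json`` manifest next to its recording files.  All
writers are deterministic: stable row ordering, fixed numeric formatting.
"""

from __future__ import annotations

import csv
import json
import warnings
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .errors import ParseError
from .model import GyroRecording, StudySession, SubjectRecord

__all__ = [
    "write_recording",
    "read_recording",
    "write_session",
    "read_session",
    "export_feature_table",
    "write_json",
    "SCHEMA_VERSION",
]

SCHEMA_VERSION = "1"
RECORDING_HEADER = ["t_cs", "gx_rad_s", "gy_rad_s", "gz_rad_s"]

# Recordings within this relative deviation of the nominal sample count load
# with a warning; anything further off is an error.
SAMPLE_COUNT_TOLERANCE = 0.02


def write_recording(recording: GyroRecording, path: Union[str, Path]) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(RECORDING_HEADER)
        for t, gx, gy, gz in zip(
            recording.t, recording.x, recording.y, recording.z
        ):
            writer.writerow([int(round(t)), repr(float(gx)), repr(float(gy)),
                             repr(float(gz))])
    return path


def read_recording(
    path: Union[str, Path],
    subject_id: str = "",
    evaluator_id: str = "",
    repeat_index: int = 1,
    sample_rate: float = 100.0,
    duration: float = 5.0,
) -> GyroRecording:
    """Parse a recording CSV; errors name the offending line number."""
    path = Path(path)
    t: list[float] = []
    cols: list[list[float]] = [[], [], []]
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError("empty file; header row is mandatory", path, 1) from None
        if [h.strip() for h in header] != RECORDING_HEADER:
            raise ParseError(
                f"bad header {header!r}; expected {','.join(RECORDING_HEADER)}",
                path,
                1,
            )
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 4:
                raise ParseError(
                    f"expected 4 columns, found {len(row)}", path, lineno
                )
            try:
                values = [float(v) for v in row]
            except ValueError as exc:
                raise ParseError(f"unparseable number: {exc}", path, lineno) from None
            if t and values[0] <= t[-1]:
                raise ParseError(
                    f"time not strictly increasing ({values[0]} after {t[-1]})",
                    path,
                    lineno,
                )
            t.append(values[0])
            for c, v in zip(cols, values[1:]):
                c.append(v)

    n = len(t)
    nominal = int(round(sample_rate * duration))
    if n != nominal:
        deviation = abs(n - nominal) / nominal
        if deviation <= SAMPLE_COUNT_TOLERANCE:
            warnings.warn(
                f"{path}: {n} samples where {nominal} were expected "
                f"({deviation:.1%} off nominal)",
                stacklevel=2,
            )
        else:
            raise ParseError(
                f"{n} samples deviate more than "
                f"{SAMPLE_COUNT_TOLERANCE:.0%} from the nominal {nominal}",
                path,
            )
    return GyroRecording(
        subject_id=subject_id,
        evaluator_id=evaluator_id,
        repeat_index=repeat_index,
        t=np.asarray(t),
        x=np.asarray(cols[0]),
        y=np.asarray(cols[1]),
        z=np.asarray(cols[2]),
        sample_rate=sample_rate,
        duration=duration,
    )


def _recording_filename(rec: GyroRecording) -> str:
    return f"{rec.subject_id}_{rec.evaluator_id}_r{rec.repeat_index}.csv"


def write_json(obj, path: Union[str, Path]) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


def write_session(session: StudySession, directory: Union[str, Path]) -> Path:
    """Write ``session.json`` plus one CSV per recording into a directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    refs = []
    order = sorted(
        session.recordings,
        key=lambda r: (r.subject_id, r.evaluator_id, r.repeat_index),
    )
    for rec in order:
        fname = _recording_filename(rec)
        write_recording(rec, directory / fname)
        refs.append(
            {
                "file": fname,
                "subject_id": rec.subject_id,
                "evaluator_id": rec.evaluator_id,
                "repeat_index": rec.repeat_index,
            }
        )
    manifest = {
        "schema_version": SCHEMA_VERSION,
        "provenance": session.provenance,
        "seed": session.seed,
        "evaluators": list(session.evaluators),
        "subjects": [s.to_dict() for s in session.subjects],
        "recordings": refs,
        **session.extra,
    }
    return write_json(manifest, directory / "session.json")


_KNOWN_MANIFEST_KEYS = {
    "schema_version",
    "provenance",
    "seed",
    "evaluators",
    "subjects",
    "recordings",
}


def read_session(directory: Union[str, Path]) -> StudySession:
    """Load a session directory written by :func:`write_session`.

    Unknown manifest keys are accepted and preserved in ``session.extra``.
    Dangling recording references raise one error naming every missing file.
    """
    directory = Path(directory)
    manifest_path = directory / "session.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no session.json in {directory}")
    with open(manifest_path, encoding="utf-8") as fh:
        manifest = json.load(fh)

    missing = [
        ref["file"]
        for ref in manifest.get("recordings", [])
        if not (directory / ref["file"]).exists()
    ]
    if missing:
        raise FileNotFoundError(
            f"manifest references missing recording file(s): {', '.join(missing)}"
        )

    recordings = [
        read_recording(
            directory / ref["file"],
            subject_id=ref["subject_id"],
            evaluator_id=ref["evaluator_id"],
            repeat_index=ref["repeat_index"],
        )
        for ref in manifest.get("recordings", [])
    ]
    extra = {k: v for k, v in manifest.items() if k not in _KNOWN_MANIFEST_KEYS}
    return StudySession(
        subjects=[SubjectRecord.from_dict(d) for d in manifest.get("subjects", [])],
        recordings=recordings,
        evaluators=list(manifest.get("evaluators", [])),
        provenance=manifest.get("provenance", ""),
        seed=manifest.get("seed"),
        extra=extra,
    )


def export_feature_table(
    feature_table: pd.DataFrame, path: Union[str, Path]
) -> Path:
    """Write a feature table CSV with stable ordering and formatting."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = feature_table.copy()
    sort_keys = [
        k
        for k in ("subject_id", "evaluator_id", "repeat_index", "maneuver")
        if k in df.columns
    ]
    if sort_keys and not df.empty:
        df = df.sort_values(sort_keys, ignore_index=True)
    df.to_csv(path, index=False, float_format="%.12g", lineterminator="\n")
    return path
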