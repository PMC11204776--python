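"""Run configuration loaded from YAML, with strict key checking."""

from __future__ import annotations

from pathlib import Path
from typing import Any, Mapping, Union

import yaml

from .errors import ConfigError

__all__ = ["load_config", "DEFAULT_CONFIG", "merged"]

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "grade_counts": {0: 10, 1: 9, 2: 9, 3: 2},
    "raters": [{"amplitude_gain": 1.0, "time_jitter_sd_cs": 0.0}],
    "repeats": 1,
    "noise_sd": None,
    "noise_frac": 0.02,
    "class_policy": "speed-from-grade",
    "peak": {
        "min_separation_cs": 50.0,
        "min_prominence_frac": 0.2,
        "expected_peaks": 3,
    },
    "grading": {"class_edges": [50.0, 100.0, 150.0, 200.0]},
    "icc": {"intra_form": "ICC(1)", "inter_form": "ICC(2,1)", "time_mode": "interval"},
    "classify": {
        "stage1_method": "svm",
        "stage2_method": "dt",
        "per_grade_test_count": 3,
        "min_grade_count_for_test": 3,
    },
}

_RATER_KEYS = {"amplitude_gain", "time_jitter_sd_cs", "seed_offset"}


def _check_keys(given: Mapping, allowed: Mapping, context: str = "") -> None:
    for key in given:
        if key not in allowed:
            where = f" in {context}" if context else ""
            raise ConfigError(f"unknown configuration key {key!r}{where}")
        if isinstance(allowed[key], dict) and isinstance(given[key], Mapping):
            _check_keys(given[key], allowed[key], context=str(key))


def merged(overrides: Mapping[str, Any] | None = None) -> dict[str, Any]:
    """Defaults overlaid with (validated) overrides."""
    cfg = {
        k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULT_CONFIG.items()
    }
    if not overrides:
        return cfg
    _check_keys(overrides, DEFAULT_CONFIG)
    for key, value in overrides.items():
        if key == "raters":
            for i, rater in enumerate(value):
                for rk in rater:
                    if rk not in _RATER_KEYS:
                        raise ConfigError(
                            f"unknown configuration key {rk!r} in raters[{i}]"
                        )
            cfg[key] = [dict(r) for r in value]
        elif key == "grade_counts":
            cfg[key] = dict(value)  # replaces the default cohort wholesale
        elif isinstance(value, Mapping) and isinstance(cfg.get(key), dict):
            cfg[key].update(value)
        else:
            cfg[key] = value
    if "grade_counts" in cfg:
        cfg["grade_counts"] = {int(g): int(c) for g, c in cfg["grade_counts"].items()}
    return cfg


def load_config(path: Union[str, Path, None]) -> dict[str, Any]:
    """Load a YAML config file and merge it over the defaults."""
    if path is None:
        return merged()
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, Mapping):
        raise ConfigError(f"config root must be a mapping, got {type(data).__name__}")
    return merged(data)
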