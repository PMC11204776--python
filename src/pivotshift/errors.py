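"""Exception types raised across the package."""

from __future__ import annotations


class PivotShiftError(Exception):
    """Base class for all package errors."""


class ParseError(PivotShiftError):
    """A delimited file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, path=None, line: int | None = None):
        self.path = path
        self.line = line
        prefix = ""
        if path is not None:
            prefix += f"{path}: "
        if line is not None:
            prefix += f"line {line}: "
        super().__init__(prefix + message)


class DegenerateSignalError(PivotShiftError):
    """Signal has no usable variation (e.g. constant, so min == max)."""


class TooFewPeaksError(PivotShiftError):
    """Fewer admissible peaks than requested; carries what was found."""

    def __init__(self, expected: int, found_indices, found_amplitudes):
        self.expected = expected
        self.found_indices = list(found_indices)
        self.found_amplitudes = list(found_amplitudes)
        super().__init__(
            f"expected {expected} peaks but only {len(self.found_indices)} "
            f"admissible peak(s) found at indices {self.found_indices}"
        )


class ConfigError(PivotShiftError):
    """Invalid run configuration (unknown key, bad value)."""
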