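"""Exception hierarchy for mfbia."""


class MfbiaError(Exception):
    """Base class for all mfbia errors."""


class DomainError(MfbiaError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class DegenerateGeometryError(DomainError):
    """Geometry that makes a quantity undefined (e.g. R_inf >= R0, collinear arc)."""


class CalibrationError(MfbiaError):
    """No admissible dispersion exponent reproduces the target reactance."""

    def __init__(self, message: str, muscle: str | None = None, gender: str | None = None):
        super().__init__(message)
        self.muscle = muscle
        self.gender = gender


class LookupError_(MfbiaError, KeyError):
    """Unknown muscle / gender / parameter in the normative table."""


class ParseError(MfbiaError, ValueError):
    """Malformed input file; carries the offending line number when known."""

    def __init__(self, message: str, line: int | None = None):
        super().__init__(message if line is None else f"line {line}: {message}")
        self.line = line


class IncompleteDesignError(MfbiaError):
    """A cohort is missing a decade (or gender) required by the pooled age contrast."""


class SamplingError(MfbiaError):
    """Truncated-normal rejection sampling exhausted its retry budget."""
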