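"""Exception types shared across the pipeline.

Errors are grouped so the CLI can map them onto distinct exit codes:
input/format problems, parameter misuse, data that is too short or
degenerate, and the subject-level data-quality exclusion (artifact load
above threshold), which is a screening decision rather than a failure.
"""


class WarmupHRVError(Exception):
    """Base class for all package errors."""


class FormatError(WarmupHRVError):
    """Unparsable or schema-violating input file."""


class EmptyInputError(WarmupHRVError):
    """File or series contains no usable data."""


class ParameterError(WarmupHRVError):
    """Invalid parameter value (non-positive lambda, reversed window, ...)."""


class InsufficientDataError(WarmupHRVError):
    """Series or cohort too short for the requested computation."""


class CoverageError(WarmupHRVError):
    """Recording does not span the requested analysis window."""


class DegenerateSignalError(WarmupHRVError):
    """Signal has zero fluctuation at some box size; no slope defined."""


class SchemaError(WarmupHRVError):
    """Cohort table violates the long-format schema; carries coordinates."""

    def __init__(self, message: str, violations: list[str] | None = None):
        super().__init__(message)
        self.violations = violations or []


class ExclusionError(WarmupHRVError):
    """Recording excluded on data-quality grounds (artifact percentage)."""
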