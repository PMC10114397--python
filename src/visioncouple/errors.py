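"""Exception hierarchy.

Validation failures (bad files, illegal scale values, unpaired records) are
kept distinct from computation failures (degenerate data) so callers — and
the CLI exit codes — can tell "fix your input" apart from "your data carry
no information".
"""


class VisionCoupleError(Exception):
    """Base class for all package errors."""


class DomainError(VisionCoupleError, ValueError):
    """A value outside its scale's legal domain (e.g. BRBP level 9)."""


class PairingError(VisionCoupleError, ValueError):
    """Pre/post records that cannot be matched into a subject pair."""


class IncompleteRecordError(VisionCoupleError, ValueError):
    """A required examination field is missing from a record."""


class CohortFormatError(VisionCoupleError, ValueError):
    """A cohort file that cannot be parsed; carries row context."""

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        if row is not None:
            message = f"row {row}: {message}"
        super().__init__(message)


class DegenerateDataError(VisionCoupleError, ValueError):
    """Data without the variation a statistic needs (zero SD, all-zero D)."""


class DegenerateNormalizationError(DegenerateDataError):
    """A constant column under cohort min-max normalization."""


class SpecError(VisionCoupleError, ValueError):
    """An invalid generative specification (e.g. non-PD correlation)."""
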