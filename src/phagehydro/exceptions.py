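"""Exception hierarchy for phagehydro.

All library errors derive from :class:`PhageHydroError` so callers (and the
CLI) can catch one base class and present a diagnostic instead of a traceback.
"""


class PhageHydroError(Exception):
    """Base class for all phagehydro errors."""


class FastaParseError(PhageHydroError):
    """Malformed FASTA input; the message names the offending line."""


class SequenceValidationError(PhageHydroError):
    """A sequence contains characters outside the 20-letter amino-acid alphabet."""


class LabelError(PhageHydroError):
    """Label file or header labels are inconsistent with the sequence records."""


class LengthError(PhageHydroError):
    """A sequence is too short for an encoder's minimum-length precondition."""


class EncodingError(PhageHydroError):
    """Aggregated encoder failure across a dataset; lists offending record ids."""

    def __init__(self, message: str, failed_ids: list[str] | None = None):
        super().__init__(message)
        self.failed_ids = failed_ids or []


class ConfigError(PhageHydroError):
    """Invalid configuration (empty grids, infeasible bias, bad parameters)."""
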