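"""Exception hierarchy.

All package-specific errors derive from :class:`MirResponseError` so callers
can catch one base class; each also derives from the closest builtin so code
that is unaware of this package still fails in an idiomatic way.
"""


class MirResponseError(Exception):
    """Base class for all mirresponse errors."""


class InvalidConfigError(MirResponseError, ValueError):
    """A configuration object contains invalid or non-finite values."""


class PairingError(MirResponseError, ValueError):
    """Sample columns do not form the required (subject, T0/T8) pairing."""


class InsufficientPairsError(PairingError):
    """Fewer subject pairs than the paired test requires."""


class IncompleteInputError(MirResponseError, ValueError):
    """A required input set (e.g. a responder set for an arm) is missing."""


class ConsistencyError(MirResponseError, ValueError):
    """Cross-referenced objects disagree (e.g. targets name unknown miRNAs)."""


class UndefinedPercentChangeError(MirResponseError, ZeroDivisionError):
    """Baseline score is zero: percent change from baseline is undefined."""


class FastqParseError(MirResponseError, ValueError):
    """A FASTQ record could not be parsed; carries the record index."""

    def __init__(self, message: str, record_index: int | None = None):
        super().__init__(message)
        self.record_index = record_index
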