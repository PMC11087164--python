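"""Exception hierarchy for arccheck_qa."""


class ArcCheckError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ArcCheckError):
    """A spec/configuration object violates its invariants."""


class OutOfBoundsError(ArcCheckError):
    """A sampling position (or a whole detector set) falls outside a dose grid."""


class FormatError(ArcCheckError):
    """A DICOM object is missing required content or is not of the expected kind."""


class UnreachableTargetError(ArcCheckError):
    """A tuning target lies outside the attainable range.

    Parameters
    ----------
    attainable:
        The (lo, hi) interval of values the tuned quantity can actually reach.
    """

    def __init__(self, message: str, attainable: tuple[float, float] | None = None):
        super().__init__(message)
        self.attainable = attainable
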