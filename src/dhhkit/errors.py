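"""Exception hierarchy shared across dhhkit modules."""


class DhhkitError(Exception):
    """Base class for all dhhkit errors."""


class ParseError(DhhkitError):
    """Raised when an input file cannot be parsed."""


class ValidationError(DhhkitError):
    """Raised when an input violates a documented invariant."""


class SegmentationError(DhhkitError):
    """Raised when motif anchors required for segmentation are missing or misordered."""


class FitError(DhhkitError):
    """Raised when a model fit is underdetermined."""
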