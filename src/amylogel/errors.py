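"""Exception types shared across the package."""


class AmylogelError(Exception):
    """Base class for package-specific errors."""


class CurveParseError(AmylogelError, ValueError):
    """A curve file contains a malformed row; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        super().__init__(message)
        self.line = line


class DuplicateQError(AmylogelError, ValueError):
    """A curve contains duplicate q values after sorting."""


class GridMismatchError(AmylogelError, ValueError):
    """Two curves do not share a common q grid."""


class DegenerateInputError(AmylogelError, ValueError):
    """Input data carry no usable signal (e.g. all-zero intensities)."""


class NoGelPointError(AmylogelError, RuntimeError):
    """The low-q intensity trace is flat; no gel point can be located."""


class PeakNotFoundError(AmylogelError, RuntimeError):
    """No interior local maximum exists in the requested range."""


class NoValidStateError(AmylogelError, ValueError):
    """An energy map forbids every conformational state."""
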