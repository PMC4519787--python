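"""Exception hierarchy.

All domain errors derive from :class:`StainSimError` so callers can catch the
package's failures with a single ``except`` clause; the more specific
subclasses let tests and pipelines distinguish contract violations from
numerically degenerate situations.
"""


class StainSimError(Exception):
    """Base class for all errors raised by this package."""


class InvalidInputError(StainSimError, ValueError):
    """An argument violates an operation's precondition."""


class GridMismatchError(StainSimError):
    """Spectra defined on different wavelength grids were combined."""


class CollinearStainsError(StainSimError):
    """The stain matrix is singular or numerically near-singular."""


class SignalClippedError(StainSimError):
    """A channel signal is zero or negative, so no absorbance exists."""


class DegenerateInputError(StainSimError):
    """Input is formally valid but the operation is undefined on it."""


class ExtrapolationError(StainSimError):
    """A correction query lies outside the calibrated output region."""


class NoThresholdError(StainSimError):
    """An automatic threshold cannot be computed (e.g. constant image)."""
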