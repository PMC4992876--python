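"""Exception hierarchy for fmisopk.

All package errors derive from :class:`FmisopkError` so callers can catch
one base class at pipeline boundaries while tests assert on specific types.
"""


class FmisopkError(Exception):
    """Base class for all fmisopk errors."""


class InvalidSpecError(FmisopkError):
    """A frame-schedule, input-function or phantom specification is malformed."""


class InvalidRecordError(FmisopkError):
    """An injection record is unusable (e.g. zero injected dose)."""


class ExtrapolationError(FmisopkError):
    """Model evaluation requested beyond the support of the input function."""


class GridError(FmisopkError):
    """Two time grids or image grids that must match do not."""


class UndefinedMacroError(FmisopkError):
    """Macro influx rate undefined (k2 + k3 == 0)."""


class UnfittableSignalError(FmisopkError):
    """TAC carries no signal distinguishable from background; fit refused."""


class UndefinedEpsilonError(FmisopkError):
    """Goodness-of-fit epsilon undefined (measured TAC is identically zero)."""


class EmptyTransformError(FmisopkError):
    """Patlak transform produced no valid points."""


class InsufficientPointsError(FmisopkError):
    """Too few valid Patlak points beyond t* for a line fit."""


class EmptyRoiError(FmisopkError):
    """Thresholding produced an empty region of interest."""


class InvalidBloodError(FmisopkError):
    """Blood reference activity is nonpositive; T/B ratio undefined."""


class InvalidBackgroundError(FmisopkError):
    """Background region mean is nonpositive; contrast ratio undefined."""


class FormatError(FmisopkError):
    """A file is not in the expected on-disk format/dimensionality."""


class ConsistencyError(FmisopkError):
    """Inputs that must agree (e.g. frame count vs schedule) do not."""
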