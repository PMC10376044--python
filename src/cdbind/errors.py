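"""Exception hierarchy shared across the analysis modules."""


class CdbindError(Exception):
    """Base class for all package errors."""


class ValidationError(CdbindError, ValueError):
    """Input violates a documented precondition (non-finite, wrong sign, wrong shape)."""


class IdentifiabilityError(CdbindError, RuntimeError):
    """Data carry no information about the parameters being fitted."""


class DegenerateCurveError(CdbindError, RuntimeError):
    """A continuous-variation curve is flat (all shift changes zero)."""


class MissingObservationError(CdbindError, KeyError):
    """A requested proton has no observed shift in the sample (absent, not zero)."""


class GridMismatchError(CdbindError, ValueError):
    """Two kinetic traces do not share a time grid or concentration."""


class ParseError(CdbindError, ValueError):
    """A CSV/config file does not match the documented dialect."""
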