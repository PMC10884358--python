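"""Exception hierarchy for the msx toolkit."""


class MsxError(Exception):
    """Base class for all msx-specific errors."""


class ValidationError(MsxError, ValueError):
    """Input data violates a schema or type invariant."""


class DegenerateMapError(MsxError, ValueError):
    """A map is constant across channels (zero after average referencing)."""


class MontageMismatchError(MsxError, ValueError):
    """Two objects that must share an electrode montage do not."""


class SingularSplineSystemError(MsxError, ValueError):
    """The spherical-spline linear system is singular (coincident electrodes)."""
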