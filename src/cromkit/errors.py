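"""Exception hierarchy for the CRoM measurement toolkit."""


class CromError(Exception):
    """Base class for all toolkit errors."""


class FormatError(CromError):
    """A file could not be parsed in the declared format."""


class ValidationError(CromError):
    """Input violates a schema or domain invariant."""


class DegenerateGeometryError(CromError):
    """Geometry too degenerate to process (collinear contour, identical points)."""


class UnmeasurableEdgeError(CromError):
    """No usable contour band could be extracted near a measurement edge."""


class PhantomParameterError(CromError):
    """Phantom parameters describe a geometrically impossible scene."""
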