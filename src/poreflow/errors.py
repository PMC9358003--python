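"""Exception hierarchy.

All errors raised by the package derive from :class:`PoreflowError` so callers
can catch a single type at the pipeline boundary.
"""


class PoreflowError(Exception):
    """Base class for all package errors."""


class ParseError(PoreflowError):
    """A text input could not be parsed; the message names the offending line."""


class ValidationError(PoreflowError):
    """Input violates a documented invariant (e.g. non-positive radius)."""


class FormatError(PoreflowError):
    """A mesh or table file is structurally invalid (e.g. non-triangular face)."""


class EmptyStructureError(PoreflowError):
    """No atoms remain after exclusion filters."""


class SizeError(PoreflowError):
    """Too few atoms for a 3D triangulation (< 5)."""


class DegeneracyError(PoreflowError):
    """Geometrically degenerate input (coplanar points, flat tetrahedron)."""


class NoChannelError(PoreflowError):
    """No cavity component available for channel selection."""


class ResolutionError(PoreflowError):
    """Surface grid too coarse to resolve the smallest atom."""


class NoOverlapError(PoreflowError):
    """Channel tetrahedra and surface mesh do not intersect (inconsistent inputs)."""


class EndpointError(PoreflowError):
    """Path endpoints coincide; tortuousness is undefined."""


class DegeneratePathError(PoreflowError):
    """Skeleton has a single node; no path can be pruned."""


class ConnectivityError(PoreflowError):
    """Source and target are not connected (or are the same node)."""


class FixtureSpecError(PoreflowError):
    """Synthetic-fixture parameters would produce a sealed or unresolvable lumen."""
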