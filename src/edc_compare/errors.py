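"""Exception hierarchy shared across the pipeline.

All errors derive from :class:`EdcError` so callers can catch pipeline
failures with a single except clause while tests can assert on the
specific failure mode.
"""


class EdcError(Exception):
    """Base class for all package errors."""


class MapFormatError(EdcError):
    """A density-map file is unreadable or its header is inconsistent."""


class GeometryError(EdcError):
    """A superposition problem is degenerate (too few or collinear points)."""


class CofactorError(EdcError):
    """A required cofactor (Cu, heme Fe) is missing or ambiguous."""


class SelectionError(EdcError):
    """An atom selection came back empty where atoms are required."""


class PairingError(EdcError):
    """Two structures could not be put into residue/atom correspondence."""


class UsageError(EdcError):
    """The operation was invoked in an unsupported way (e.g. scoring on an
    unsmoothed grid)."""
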