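"""Exception hierarchy shared by all stages."""


class CxcaxisError(Exception):
    """Base class for all package errors."""


class ParseError(CxcaxisError):
    """A file could not be parsed; the message names the offending location."""


class ValidationError(CxcaxisError):
    """Input violated a documented invariant (e.g. overlapping TM ranges)."""


class SelectionError(CxcaxisError):
    """An atom/residue selection resolved to nothing or to an unknown segment."""


class DegenerateGeometryError(CxcaxisError):
    """Too few or collinear points for a rigid-body superposition."""


class TopologyError(CxcaxisError):
    """Atom counts or connectivity do not match between related inputs."""


class DependencyError(CxcaxisError):
    """A pipeline stage is missing an upstream input."""
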