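"""Exception hierarchy."""


class NucleomorphError(Exception):
    """Base class for all package-specific errors."""


class PackingError(NucleomorphError):
    """Raised when a hard-core point process cannot reach its target count."""


class DegenerateGeometryError(NucleomorphError):
    """Raised for geometrically degenerate input (collinear, coplanar, duplicate points)."""
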