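"""Exception hierarchy shared across the package.

Exit-code convention for the CLI: 0 ok, 1 validation error, 2 geometry error.
"""


class RsaPlanError(Exception):
    """Base class for all package errors."""


class ValidationError(RsaPlanError):
    """Invalid configuration, specification, or argument values."""


class GeometryError(RsaPlanError):
    """Degenerate or inconsistent geometric input (collinear landmarks,
    coplanar point sets, endpoints inside a wrapping obstacle, ...)."""
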