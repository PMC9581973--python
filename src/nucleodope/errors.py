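"""Exception hierarchy with stable process exit codes.

Configuration problems, malformed data, and solver non-convergence get
distinct codes so shell pipelines can tell them apart.
"""


class NucleodopeError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigError(NucleodopeError):
    """Invalid configuration, scenario spec, or missing residue definitions."""

    exit_code = 2


class DataError(NucleodopeError):
    """Malformed or insufficient input data."""

    exit_code = 3


class ParseError(DataError):
    """A file failed to parse under its declared format."""


class GeometryError(DataError):
    """Degenerate geometry (e.g. collinear ring atoms)."""


class ConvergenceError(NucleodopeError):
    """An iterative solver failed to converge."""

    exit_code = 4
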