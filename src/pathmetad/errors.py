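"""Exception hierarchy.

All package errors derive from :class:`PathMetadError` so callers can catch
one base class; specific subclasses distinguish bad user input from
numerically degenerate geometry and from file-format problems.
"""


class PathMetadError(Exception):
    """Base class for all errors raised by pathmetad."""


class InputError(PathMetadError, ValueError):
    """Invalid argument values (mismatched lengths, empty masks, bad config)."""


class DegenerateGeometryError(PathMetadError):
    """Geometry that does not define the requested quantity.

    Raised for collinear superposition selections, coincident points in a
    dihedral, or duplicated path references.
    """


class SelectionError(PathMetadError, KeyError):
    """A residue-map label or atom-name selection resolved to no atoms."""


class ParseError(PathMetadError, ValueError):
    """Malformed input file; carries the offending line number when known."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class ConfigError(PathMetadError, ValueError):
    """Invalid run configuration (unknown keys, out-of-range parameters)."""


class IntegrationError(PathMetadError, RuntimeError):
    """Dynamics became unstable (non-finite energies or coordinates)."""
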