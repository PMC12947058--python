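"""Exception types shared across the package."""


class FilmdoseError(Exception):
    """Base class for package-specific errors."""


class InvalidGeometryError(FilmdoseError, ValueError):
    """Voxel geometry with non-positive dimension or density."""


class CalibrationError(FilmdoseError, ValueError):
    """Single-event model cannot be identified from the given anchor."""


class DomainError(FilmdoseError, ValueError):
    """Argument outside the physical domain (negative dose, zero reading, ...)."""


class ParseError(FilmdoseError, ValueError):
    """Malformed input file; carries an approximate line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (near line {line})"
        super().__init__(message)
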