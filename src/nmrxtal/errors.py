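"""Exception hierarchy shared across the package."""


class NmrxtalError(Exception):
    """Base class for all package errors."""


class ParseError(NmrxtalError):
    """A file or stream could not be parsed; carries a line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class StructureFileError(ParseError):
    """Structural information (lattice, cell parameters) missing or invalid."""


class DuplicateSiteError(NmrxtalError):
    """Two atoms carry the same (label, index) identity."""


class ConsistencyError(NmrxtalError):
    """Cross-references between blocks or tables do not line up."""


class NotAnEFGError(NmrxtalError):
    """Tensor handed to the quadrupolar analysis is not traceless/symmetric."""


class ConfigurationError(NmrxtalError):
    """A referencing scheme or run configuration is incomplete."""


class DegenerateFitError(NmrxtalError):
    """A regression was requested on degenerate input."""


class PackingError(NmrxtalError):
    """The synthetic generator could not place sites without overlap."""
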