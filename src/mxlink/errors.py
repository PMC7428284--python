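"""Exception hierarchy for multiplex-network handling."""


class MultiplexError(Exception):
    """Base class for all mxlink errors."""


class ParseError(MultiplexError):
    """A multiplex edge-list record could not be parsed.

    Carries the offending line number so file problems are actionable.
    """

    def __init__(self, message: str, path=None, line: int | None = None):
        self.path = path
        self.line = line
        prefix = ""
        if path is not None:
            prefix += f"{path}: "
        if line is not None:
            prefix += f"line {line}: "
        super().__init__(prefix + message)


class ConfigurationError(MultiplexError):
    """Inconsistent run configuration (unknown layer, bad manifest, ...)."""


class ContractViolation(MultiplexError, ValueError):
    """An operation precondition was violated (dimension mismatch, empty input, ...)."""
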