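"""Exception hierarchy for the pipeline."""


class SnpGseaError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SnpGseaError):
    """A configuration value is invalid; the message names the field."""


class ParseError(SnpGseaError):
    """A file violates its format contract; carries the offending location."""

    def __init__(self, message: str, path=None, line: int | None = None):
        loc = ""
        if path is not None:
            loc += f"{path}"
        if line is not None:
            loc += f":{line}"
        super().__init__(f"{loc}: {message}" if loc else message)
        self.path = path
        self.line = line


class UndefinedResultError(SnpGseaError):
    """A statistic is undefined for the given input (e.g. monomorphic SNP)."""


class InfeasibleSimulationError(SnpGseaError):
    """Rejection sampling exceeded its draw cap."""


class SchemaError(SnpGseaError):
    """A required column is missing from an input table."""
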