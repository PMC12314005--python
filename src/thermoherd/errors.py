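"""Exception hierarchy for the thermoherd pipeline."""


class ThermoherdError(Exception):
    """Base class for all pipeline errors."""


class SchemaError(ThermoherdError):
    """A table is missing a required column or contains an invalid value."""


class RowError(SchemaError):
    """A specific row failed to parse; carries a 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class GeometryError(ThermoherdError):
    """A polygon ring is degenerate or self-intersecting."""


class DomainError(ThermoherdError):
    """A physical quantity is outside its admissible domain."""


class UndefinedCorrelationError(ThermoherdError):
    """Correlation requested on a zero-variance or too-short vector."""
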