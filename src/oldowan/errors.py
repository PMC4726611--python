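"""Exception types shared across the package."""


class OldowanError(Exception):
    """Base class for all package errors."""


class ParameterError(OldowanError, ValueError):
    """Invalid simulation or model parameters."""


class DomainError(OldowanError, ValueError):
    """A measurement value outside its physical domain (e.g. non-positive length)."""


class SchemaError(OldowanError, ValueError):
    """An input table does not conform to the expected column schema."""
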