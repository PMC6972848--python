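"""Exception hierarchy for parklens."""


class ParklensError(Exception):
    """Base class for all parklens errors."""


class ConfigurationError(ParklensError):
    """An invalid configuration field; the message names the field."""


class ValidationError(ParklensError):
    """Invalid input data for an operation."""


class GeometryError(ParklensError):
    """Invalid geometry (e.g. an unclosed or self-intersecting ring)."""


class FitError(ParklensError):
    """Model fitting failed; carries the optimizer trace when available."""

    def __init__(self, message: str, trace=None):
        super().__init__(message)
        self.trace = trace
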