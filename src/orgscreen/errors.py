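"""Exception hierarchy shared across the pipeline stages."""


class OrgscreenError(Exception):
    """Base class for all orgscreen errors."""


class DesignError(OrgscreenError):
    """Sample sheet / expression matrix inconsistency."""


class ParseError(OrgscreenError):
    """Malformed input text (TSV cell, Boolean expression)."""

    def __init__(self, message: str, position: int | None = None):
        if position is not None:
            message = f"{message} (at position {position})"
        super().__init__(message)
        self.position = position


class ConfigError(OrgscreenError):
    """Invalid pipeline configuration."""


class GenerationError(OrgscreenError):
    """Synthetic-data request that cannot be realized."""
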