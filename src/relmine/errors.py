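"""Exception hierarchy shared across the pipeline stages."""


class RelmineError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(RelmineError):
    """A configuration value, file layout, or vector length is invalid."""


class CorpusFormatError(RelmineError):
    """An input corpus file is malformed."""


class ContractViolationError(RelmineError):
    """A pluggable component returned output violating its contract."""


class InvariantViolationError(RelmineError):
    """A domain-type invariant was violated (e.g. overlapping mention spans)."""


class PipelineStageError(RelmineError):
    """A pipeline stage failed; carries the stage name and offending address."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")


class UndefinedPrecisionError(RelmineError):
    """Precision requested over an empty set of indicators."""
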