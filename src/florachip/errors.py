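"""Exception hierarchy shared across the pipeline stages."""


class FlorachipError(Exception):
    """Base class for all package errors."""


class ConfigError(FlorachipError):
    """A configuration value is missing, malformed, or out of range."""


class InputError(FlorachipError):
    """An input file or record violates its format contract."""


class PlacementError(FlorachipError):
    """Simulated features cannot be placed without violating spacing rules."""


class NormalizationError(FlorachipError):
    """A track cannot be normalized (e.g. zero fragments)."""


class ContractError(FlorachipError):
    """Two objects that must share state (scale, chromosomes) do not."""


class StageError(FlorachipError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")
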