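"""Exception types shared across the pipeline."""


class FlxsigError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(FlxsigError, ValueError):
    """Invalid simulation or analysis configuration."""


class DegenerateReferenceError(FlxsigError, ValueError):
    """Control group cannot serve as a z-score reference (too small or zero spread)."""


class MissingDataError(FlxsigError, ValueError):
    """A required behavioral measure or contrast is absent; no silent imputation."""


class EmptyResultError(FlxsigError, ValueError):
    """A filtering step removed every record."""
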