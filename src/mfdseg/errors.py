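"""Exception types shared across the package."""


class DimensionError(ValueError):
    """Array shapes or channel counts are inconsistent."""


class InvalidStatisticsError(ValueError):
    """Batch-normalization statistics are unusable (e.g. non-positive std)."""


class UnsupportedCompositionError(ValueError):
    """A transform composition outside the supported algebra was requested."""


class ModeError(RuntimeError):
    """An operation was requested in the wrong train/deploy mode."""


class ConfigError(ValueError):
    """A model or dataset configuration is invalid."""
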