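"""Exception hierarchy for celltex."""


class CelltexError(Exception):
    """Base class for all celltex errors."""


class InvalidInput(CelltexError, ValueError):
    """A physical or numerical argument is out of its valid domain."""


class ConfigError(CelltexError, ValueError):
    """A run configuration failed schema validation."""


class EmptySectorError(CelltexError):
    """A reduction sector or band selected no unmasked pixels."""


class GridMismatchError(CelltexError):
    """Two profiles that must share a grid do not."""


class ScalingError(CelltexError):
    """Pole-figure branches cannot be scaled (zero/negative match intensity)."""


class UnknownPresetError(CelltexError, KeyError):
    """Requested preset name is not registered."""
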