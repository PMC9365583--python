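"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """A config value or combination of values is invalid."""


class ShapeError(ValueError):
    """Array shapes are incompatible with the requested operation."""


class PairingError(ValueError):
    """Low-dose / normal-dose inputs cannot be paired."""


class NumericError(ArithmeticError):
    """A computation produced or received a non-finite value."""
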