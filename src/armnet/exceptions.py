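"""Exception hierarchy used across the package."""


class ArmnetError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(ArmnetError, ValueError):
    """Data fed to an operation violates its preconditions."""


class InvalidParameterError(ArmnetError, ValueError):
    """An operation parameter is out of its admissible range."""


class ShapeError(ArmnetError, ValueError):
    """Incompatible array shapes between operands."""


class ConfigError(ArmnetError, ValueError):
    """A model/block configuration is internally inconsistent."""
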