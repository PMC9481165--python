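"""Exception hierarchy shared across the package."""


class CorticonetError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(CorticonetError, ValueError):
    """An argument violates a documented precondition."""


class EstimationError(CorticonetError, RuntimeError):
    """A geometric or statistical estimate cannot be formed from the data."""


class SingularProjectionError(EstimationError):
    """A point lies on the singular axis of the flat-map projection."""


class ConfigurationError(CorticonetError):
    """A config file or architecture specification is inconsistent."""


class WiringError(CorticonetError):
    """Activation shapes do not match the architecture graph."""


class TrainingError(CorticonetError):
    """The training loop produced a non-finite loss."""
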