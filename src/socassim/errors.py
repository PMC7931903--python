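"""Exception types shared across the package."""


class InvalidConfigurationError(ValueError):
    """A configuration value violates a precondition."""


class InvalidParameterError(ValueError):
    """A parameter value is out of bounds or inconsistent."""


class NumericalFailureError(RuntimeError):
    """A linear solve or optimization failed; carries diagnostics."""

    def __init__(self, message, condition_number=None):
        super().__init__(message)
        self.condition_number = condition_number


class StepSizeError(RuntimeError):
    """An explicit integration step was unstable."""


class InterfaceError(ValueError):
    """Mismatched shapes, units, or grids between components."""


class InsufficientDataError(ValueError):
    """Too few samples or sites to perform the requested fit."""
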