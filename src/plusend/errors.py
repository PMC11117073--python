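"""Exception hierarchy shared across the package."""


class PlusEndError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(PlusEndError, ValueError):
    """A simulation or analysis configuration value is invalid."""


class InsufficientDataError(PlusEndError, ValueError):
    """Not enough observations to perform the requested computation."""


class FitError(PlusEndError, RuntimeError):
    """A nonlinear fit failed to converge; carries solver diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class MultipleComponentsError(PlusEndError, ValueError):
    """A mask expected to hold one object contains several components."""

    def __init__(self, message: str, component_sizes: list[int]):
        super().__init__(message)
        self.component_sizes = component_sizes
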