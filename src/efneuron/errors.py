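"""Exception hierarchy shared across the package."""


class EFNeuronError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(EFNeuronError, ValueError):
    """An input parameter violates its documented invariant."""


class MorphologyError(EFNeuronError, ValueError):
    """A morphology tree violates a structural invariant."""


class SWCParseError(EFNeuronError, ValueError):
    """Malformed SWC input.

    Carries the 1-based line number when the offending line is known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class InitializationError(EFNeuronError, RuntimeError):
    """Steady-state initialization failed to converge."""

    def __init__(self, message: str, residual: float | None = None):
        self.residual = residual
        super().__init__(message)


class SolverDivergenceError(EFNeuronError, RuntimeError):
    """The membrane potential left the physically plausible range."""

    def __init__(self, message: str, time_ms: float | None = None,
                 site: object | None = None):
        self.time_ms = time_ms
        self.site = site
        super().__init__(message)


class SuprathresholdFieldError(EFNeuronError, RuntimeError):
    """A field meant to be subthreshold evoked a spike."""


class ConfigError(EFNeuronError, ValueError):
    """A run configuration failed schema validation."""
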