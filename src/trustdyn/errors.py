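"""Exception hierarchy shared across the package."""


class TrustdynError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(TrustdynError, ValueError):
    """A numerical parameter violates its admissible range."""


class ConfigurationError(TrustdynError, ValueError):
    """A structural/configuration input is inconsistent (counts, keys, shapes)."""


class StabilityError(TrustdynError, ValueError):
    """The integration step is too large for the fastest time constant."""


class IntegrationError(TrustdynError, RuntimeError):
    """The state became non-finite during integration.

    Carries the first offending step index in ``step``.
    """

    def __init__(self, message: str, step: int | None = None):
        super().__init__(message)
        self.step = step


class FlatSignalError(TrustdynError, ValueError):
    """A spectral readout was requested on a (near-)constant signal."""


class InsufficientDataError(TrustdynError, ValueError):
    """A series is too short for the requested analysis."""
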