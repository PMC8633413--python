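"""Exception hierarchy shared across the package."""


class CrinetError(Exception):
    """Base class for all package errors."""


class InvalidInputError(CrinetError, ValueError):
    """Inputs violate a documented precondition."""


class IntegrationError(CrinetError):
    """ODE integration produced a non-finite state.

    Carries ``time``, the first requested output time that could not be
    reached.
    """

    def __init__(self, message: str, time: float | None = None):
        super().__init__(message)
        self.time = time


class FitError(CrinetError):
    """Optimization failed to converge; ``best`` holds the best-so-far result."""

    def __init__(self, message: str, best=None):
        super().__init__(message)
        self.best = best


class DegenerateMarkerError(CrinetError, ValueError):
    """Marker has fewer than two usable genotype classes."""


class SchemaError(CrinetError, ValueError):
    """A tabular input file does not match its documented schema."""
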