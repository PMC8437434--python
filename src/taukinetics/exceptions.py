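"""Exception hierarchy for taukinetics."""


class TauKineticsError(Exception):
    """Base class for all package errors."""


class InvalidInputError(TauKineticsError, ValueError):
    """An argument violates a documented precondition or invariant."""


class IntegrationError(TauKineticsError, RuntimeError):
    """ODE integration failed to converge.

    Carries the offending parameter set in ``params`` when available.
    """

    def __init__(self, message, params=None):
        super().__init__(message)
        self.params = params


class FitError(TauKineticsError, RuntimeError):
    """An optimization failed or was refused as underdetermined."""


class AlignmentError(TauKineticsError, ValueError):
    """Two traces could not be aligned onto a common time grid."""


class NotSaturatedError(TauKineticsError, RuntimeError):
    """A kinetic trace never reached a detectable plateau."""


class InsufficientDataError(TauKineticsError, ValueError):
    """Too few conditions/replicates for the requested analysis."""


class DependencyError(TauKineticsError, RuntimeError):
    """A workflow stage is missing an upstream product."""
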