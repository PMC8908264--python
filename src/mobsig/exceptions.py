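"""Exception hierarchy for mobsig."""


class MobsigError(Exception):
    """Base class for all mobsig errors."""


class FormatError(MobsigError):
    """An input file does not conform to the expected layout (missing
    columns, duplicate identifiers, out-of-range values)."""


class ConvergenceError(MobsigError):
    """Iterative proportional fitting failed to satisfy both margin
    constraints within the iteration budget.

    Carries diagnostics so the caller can inspect how close the fit got.
    """

    def __init__(self, message, *, iterations=None, max_rel_error=None):
        super().__init__(message)
        self.iterations = iterations
        self.max_rel_error = max_rel_error


class CalibrationError(MobsigError):
    """The deterrence parameter cannot be calibrated: the observed mean
    trip distance lies outside the range achievable within the bracket,
    or the objective is insensitive to the parameter."""

    def __init__(self, message, *, bracket=None, achievable=None):
        super().__init__(message)
        self.bracket = bracket
        self.achievable = achievable


class ModelError(MobsigError):
    """A mobility model is undefined for the given inputs (e.g. radiation
    with a single populated city)."""
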