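"""Exception hierarchy.

All package errors derive from :class:`AmorphkinError` so callers (and the
CLI) can catch everything the library raises with one except clause.
"""


class AmorphkinError(Exception):
    """Base class for all errors raised by amorphkin."""


class ParseError(AmorphkinError):
    """A CSV/JSON input could not be parsed into a valid domain object."""


class ValidationError(AmorphkinError):
    """A domain-type invariant was violated."""


class FitError(AmorphkinError):
    """A nonlinear fit failed to converge or produced an inadmissible result."""

    def __init__(self, message: str, best_residual: float | None = None):
        super().__init__(message)
        self.best_residual = best_residual


class AnalysisError(AmorphkinError):
    """An analysis stage could not produce a result from admissible input."""


class NoCrystallizationError(AnalysisError):
    """Permittivity contrast too small: no crystallization detected.

    Raised when the static-permittivity drop over the isothermal hold is
    below the detection threshold (the behaviour of a fully stabilized
    amorphous sample).
    """
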