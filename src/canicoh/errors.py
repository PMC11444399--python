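"""Exception hierarchy for canicoh.

All errors derive from :class:`CanicohError` (a ``ValueError``) so callers
can catch the whole family with one clause while scripts that only use the
standard library still see a conventional ``ValueError``.
"""


class CanicohError(ValueError):
    """Base class for all canicoh errors."""


class InvalidSpecError(CanicohError):
    """A generator spec violates its invariants (e.g. overlapping calls)."""


class InvalidInputError(CanicohError):
    """Input data violates a precondition (empty, wrong rate, out of range)."""


class InvalidArgumentError(CanicohError):
    """An argument is outside its documented domain (mode, factor, window)."""


class InsufficientDurationError(CanicohError):
    """Signal too short for the requested analysis."""


class InsufficientDataError(CanicohError):
    """Too few trials / samples to run the estimator."""


class NoPeakError(CanicohError):
    """No spectral peak exists (silent or constant input)."""


class UnvoicedInputError(CanicohError):
    """Pitch tracking found no voiced frames."""


class DegenerateVarianceError(CanicohError):
    """A variance needed in a denominator is zero."""


class DegenerateInputError(CanicohError):
    """Statistical input is degenerate (all tied, zero-variance differences)."""


class NotFoundError(CanicohError, KeyError):
    """A requested subject/condition is absent from a table."""


class ConvergenceError(CanicohError):
    """A model fit failed to converge."""
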