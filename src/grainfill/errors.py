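"""Exception hierarchy for grainfill."""


class GrainfillError(Exception):
    """Base class for all grainfill errors."""


class ParameterDomainError(GrainfillError, ValueError):
    """A distribution parameter is outside its valid domain."""


class DegenerateSampleError(GrainfillError, ValueError):
    """A sample is too degenerate to estimate from (e.g. zero variance)."""


class EMCollapseError(GrainfillError, RuntimeError):
    """An EM restart collapsed (vanishing component or degenerate M-step)."""


class FitFailureError(GrainfillError, RuntimeError):
    """Every restart of a fit failed."""


class DivergenceError(ParameterDomainError):
    """A closed-form integral diverges for the given parameters."""


class AlignmentError(GrainfillError, ValueError):
    """Two cultivar-indexed inputs do not share the same index."""


class EmptyPanelError(GrainfillError, ValueError):
    """Marker filtering removed every marker."""
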