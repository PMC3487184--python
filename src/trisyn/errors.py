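"""Exception hierarchy for trisyn."""


class TrisynError(Exception):
    """Base class for all model-level errors."""


class InvalidParameterError(TrisynError, ValueError):
    """A parameter violates its documented constraint."""


class InvalidDiscretizationError(TrisynError, ValueError):
    """Time step incompatible with a process time scale (e.g. dt >= tau)."""


class NumericalError(TrisynError, ArithmeticError):
    """Integration produced a non-finite state; names the offending step."""


class FitError(TrisynError, RuntimeError):
    """A curve fit failed or the data are degenerate."""


class ComparisonError(TrisynError, ValueError):
    """Two results are not comparable (e.g. mismatched grids or seeds)."""
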