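"""Exception hierarchy shared across the pipeline."""


class LipidMRError(Exception):
    """Base class for all package errors."""


class ValidationError(LipidMRError):
    """Input value violates a documented precondition."""


class ParseError(LipidMRError):
    """A cohort file could not be parsed; carries line/column context."""


class DesignError(LipidMRError):
    """Design matrix is rank deficient or an outcome is degenerate."""


class ConvergenceError(LipidMRError):
    """Iteratively reweighted least squares failed to converge."""


class SeparationError(LipidMRError):
    """Complete or quasi-complete separation in a logistic fit."""


class ZeroCellError(LipidMRError):
    """A 2x2 table has an empty cell; no continuity correction is applied."""


class DegenerateSubsetError(LipidMRError):
    """An analytic subset has too few rows per exposure-outcome cell."""


class NestingError(LipidMRError):
    """Likelihood-ratio comparison attempted between non-nested fits."""


class WeakInstrumentError(LipidMRError):
    """Instrument fails the strength threshold (improvement chi-square <= 10)."""
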