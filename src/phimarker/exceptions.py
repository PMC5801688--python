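"""Exception hierarchy for phimarker."""


class PhimarkerError(Exception):
    """Base class for all package-specific errors."""


class PanelFormatError(PhimarkerError, ValueError):
    """A panel or p-value file does not follow the documented CSV dialect."""


class UndefinedStatisticError(PhimarkerError, ValueError):
    """A contingency table has a zero marginal or zero expected count, so
    phi / chi-squared are undefined for it."""


class NoPredictionError(PhimarkerError, ValueError):
    """A marker yields no prediction on a test set (no mutated test cells);
    the marker is non-evaluable rather than scored."""


class EmptyReportError(PhimarkerError, ValueError):
    """A panel scan produced no testable drug-feature pair."""
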