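"""Exception hierarchy for sleepdyn."""


class SleepdynError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(SleepdynError, ValueError):
    """A parameter is outside its admissible range."""


class InvalidLengthError(SleepdynError, ValueError):
    """A series is too short (or empty) for the requested operation."""


class OnsetNotFoundError(SleepdynError):
    """No quiescent run qualifying as sleep onset exists in the recording."""


class ShortRecordingError(SleepdynError):
    """Recording ends before the requested analysis window is complete."""


class DegenerateSeriesError(SleepdynError):
    """The series is constant (or otherwise degenerate) for this analysis."""


class UnreliableTestError(SleepdynError):
    """Expected counts too small for the chi-square approximation."""


class DivergenceError(SleepdynError):
    """An iterated map left its bounded region."""
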