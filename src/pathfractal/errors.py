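"""Exception hierarchy shared across the pipeline."""


class PathfractalError(Exception):
    """Base class for all package errors."""


class TrackFormatError(PathfractalError):
    """A track table violates the expected layout (bad columns, duplicate or
    non-monotone frame indices)."""


class DegenerateInputError(PathfractalError):
    """Input too small or empty for the requested operation."""


class ParameterError(PathfractalError):
    """An argument is outside its valid range."""


class CalibrationError(PathfractalError):
    """A metric in centimetres was requested from an uncalibrated trajectory."""


class InsufficientDataError(PathfractalError):
    """Not enough observations to run a statistical procedure."""


class ComparabilityError(PathfractalError):
    """Candidate models were fit on differing observation sets."""
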