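"""Exception hierarchy for the VERT population state model."""


class VertError(Exception):
    """Base class for all package-specific errors."""


class FormatError(VertError):
    """A file does not conform to the expected CSV/YAML layout."""


class ValidationError(VertError):
    """Input data violate a structural invariant (ordering, shape, alphabet)."""


class DegenerateInputError(VertError):
    """Input is structurally valid but degenerate (e.g. zero total count)."""


class CalibrationError(VertError):
    """Neutral calibration is missing, empty, or has zero variance."""


class ParameterError(VertError):
    """A tuning parameter is outside its legal range."""


class TrainingError(VertError):
    """Supervised training cannot estimate a parameter (state never visited)."""
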