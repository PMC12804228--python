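"""Exception hierarchy shared across the pipeline stages."""


class SkintribError(Exception):
    """Base class for all package-specific errors."""


class InvalidPlanError(SkintribError):
    """A trial plan is internally inconsistent (e.g. strokes do not fit)."""


class ValidationError(SkintribError):
    """An input object violates a structural invariant."""


class EmptySeriesError(SkintribError):
    """No valid samples remain after masking."""


class NoStrokesError(SkintribError):
    """A recording contains no segmentable sliding movement."""


class NotSegmentableError(SkintribError):
    """An RMS profile has no friction-like valley structure to segment.

    Raised for waveforms whose envelope never drops between strokes, the
    behaviour observed on smooth planar substrates.
    """


class ParameterError(SkintribError):
    """A parameter value is outside its admissible range."""


class ParseError(SkintribError):
    """A file does not match the expected schema."""
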