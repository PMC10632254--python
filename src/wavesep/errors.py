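"""Exception hierarchy for wavesep."""


class WavesepError(Exception):
    """Base class for all wavesep errors."""


class InvalidInputError(WavesepError, ValueError):
    """Input data violate a precondition (shape, monotonicity, grids)."""


class InvalidParameterError(WavesepError, ValueError):
    """A parameter is outside its admissible range."""


class LandmarkError(WavesepError, RuntimeError):
    """A required beat landmark could not be detected.

    The message names the missing landmark.
    """


class InsufficientDataError(WavesepError, ValueError):
    """Too few samples to carry out the requested fit."""


class DegenerateInputError(WavesepError, ValueError):
    """Degenerate signal (flat waveform, zero amplitude, non-positive slope)."""


class FormatError(WavesepError, ValueError):
    """A file on disk does not match the expected layout."""
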