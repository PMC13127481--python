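"""Exception hierarchy for the waveform pipeline."""


class PuwaveError(Exception):
    """Base class for all package errors."""


class FormatError(PuwaveError):
    """A file does not conform to the declared dialect."""


class DataError(PuwaveError):
    """Input data violate an invariant (non-monotone time, NaN, ...)."""


class ParameterError(PuwaveError):
    """A parameter is outside its admissible range."""


class DetectionError(PuwaveError):
    """Beat detection failed."""


class EstimationError(PuwaveError):
    """Pulse-wave-speed estimation failed."""


class LandmarkError(PuwaveError):
    """Wave-intensity landmarks could not be ordered A < B < C < D."""


class QuantificationError(PuwaveError):
    """Wave quantification failed (e.g. non-positive reference integral)."""
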