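"""Exception hierarchy."""


class OppscreenError(Exception):
    """Base class for package errors."""


class ConfigurationError(OppscreenError):
    """Invalid spec/config (e.g. ellipse exceeding image bounds)."""


class ValidationError(OppscreenError):
    """Invalid runtime input (e.g. non-finite BMD)."""


class MeasurementError(OppscreenError):
    """ROI measurement failed (e.g. empty ROI after erosion)."""


class TrainingDivergedError(OppscreenError):
    """Non-finite loss encountered during training."""
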