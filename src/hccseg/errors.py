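"""Package-specific exception types."""


class HccSegError(Exception):
    """Base class for all package errors."""


class PlacementError(HccSegError):
    """A phantom lesion could not be placed inside the liver."""


class RegistrationError(HccSegError):
    """Registration diverged; carries the optimizer metric trace."""

    def __init__(self, message: str, metric_trace: list[float] | None = None):
        super().__init__(message)
        self.metric_trace = metric_trace or []


class GeometryError(HccSegError):
    """A degenerate or out-of-bounds ROI box."""


class TrainingError(HccSegError):
    """Training failed (e.g. NaN loss); carries the history so far."""

    def __init__(self, message: str, history=None):
        super().__init__(message)
        self.history = history
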