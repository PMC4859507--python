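"""Exception types shared across the pipeline."""


class FiberquantError(Exception):
    """Base class for all package errors."""


class PlacementError(FiberquantError):
    """Raised when the synthetic field cannot hold the requested fibers."""


class DegenerateSegmentationError(FiberquantError):
    """Thresholding produced an all-foreground or all-background mask.

    Carries the threshold that was applied so the failure can be diagnosed.
    """

    def __init__(self, message: str, threshold: float | None = None):
        super().__init__(message)
        self.threshold = threshold


class ConfigurationError(FiberquantError):
    """Invalid or inconsistent run configuration."""


class InsufficientPairsError(FiberquantError):
    """A paired test was requested with fewer than two usable pairs."""
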