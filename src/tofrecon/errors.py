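"""Exception hierarchy for tofrecon."""


class TofReconError(Exception):
    """Base class for all tofrecon errors."""


class InvalidConfigError(TofReconError, ValueError):
    """A configuration object violates its invariants."""


class DimensionalityError(TofReconError, ValueError):
    """Input array has the wrong number of dimensions."""


class InfeasibleSplitError(TofReconError, ValueError):
    """No integer slab length satisfies the requested split."""


class NoThresholdError(TofReconError, ValueError):
    """Thresholding is undefined (e.g. constant input volume)."""


class DegenerateMaskError(TofReconError, ValueError):
    """A mask is empty where a nonempty one is required."""


class ShapeError(TofReconError, ValueError):
    """Array shapes do not agree."""


class InvalidPFError(TofReconError, ValueError):
    """Partial-Fourier fraction out of range."""


class InfeasibleMaskError(TofReconError, ValueError):
    """Requested acceleration cannot be realized on this grid."""


class CalibrationError(TofReconError, ValueError):
    """Sampling mask lacks a usable calibration region."""


class UndefinedMetricError(TofReconError, ValueError):
    """Metric undefined for this input (e.g. all-zero reference)."""


class WindowError(TofReconError, ValueError):
    """SSIM window does not fit inside the volume."""


class StepSizeError(TofReconError, RuntimeError):
    """Iterative solver diverged; step size too large."""


class TrainingDivergenceError(TofReconError, RuntimeError):
    """Training loss became non-finite."""

    def __init__(self, message: str, epoch: int | None = None):
        super().__init__(message)
        self.epoch = epoch


class EmptyMaskError(TofReconError, ValueError):
    """Vessel mask came out empty."""


class SchemaError(TofReconError, ValueError):
    """Run configuration violates the expected schema."""
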