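"""Exception types shared across the pipeline."""


class DualAEError(Exception):
    """Base class for all package-specific errors."""


class PlacementError(DualAEError):
    """An anomaly could not be placed inside the brain after bounded retries."""


class DegenerateDataError(DualAEError, ValueError):
    """Input data carry no usable variation (e.g. zero pooled variance)."""


class ConfigurationError(DualAEError, ValueError):
    """Inconsistent model/pipeline configuration (shape or option mismatch)."""


class TrainingDivergedError(DualAEError, RuntimeError):
    """Non-finite loss encountered during optimization."""

    def __init__(self, epoch: int, learning_rate: float):
        self.epoch = epoch
        self.learning_rate = learning_rate
        super().__init__(
            f"non-finite training loss at epoch {epoch} (learning rate {learning_rate:g})"
        )


class RankError(DualAEError, ValueError):
    """Requested SVD truncation rank is infeasible for the given matrix."""
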