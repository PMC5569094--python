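"""Exception hierarchy for the stokesflow package."""


class StokesflowError(Exception):
    """Base class for all package-specific errors."""


class FormatError(StokesflowError):
    """Input file exists but its structure is not understood."""


class NoCellFound(StokesflowError):
    """Segmentation produced no foreground component above the area threshold."""

    def __init__(self, frame_index: int, message: str | None = None):
        self.frame_index = frame_index
        super().__init__(message or f"no cell found in frame {frame_index}")


class MeshingError(StokesflowError):
    """Mask could not be converted into a valid finite-element mesh."""


class CompatibilityError(StokesflowError):
    """Dirichlet boundary velocity violates the incompressibility flux condition."""


class ConvergenceError(StokesflowError):
    """Iterative minimisation failed to make progress.

    Carries the last iterate so callers can inspect it.
    """

    def __init__(self, message: str, iterate=None):
        self.iterate = iterate
        super().__init__(message)


class DegenerateInput(StokesflowError):
    """Input carries no usable signal (e.g. constant images)."""


class FitError(StokesflowError):
    """Nonlinear least-squares fit did not converge."""

    def __init__(self, message: str, init=None, residual=None):
        self.init = init
        self.residual = residual
        super().__init__(message)


class UndefinedCorrelation(StokesflowError):
    """Cross-correlation of a constant series is undefined."""


class DegenerateTransform(StokesflowError):
    """No sample survived the sigmoid linearising transform."""


class DomainError(StokesflowError):
    """Requested evaluation point or segment leaves the meshed domain."""
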