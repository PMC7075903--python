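"""Exception types shared across the package."""


class ActiveSheetError(Exception):
    """Base class for package-specific errors."""


class DegenerateContactError(ActiveSheetError):
    """Two interacting particle centers coincide; the contact normal is undefined."""


class TessellationDegeneracyError(ActiveSheetError):
    """Voronoi tessellation is degenerate (collinear or duplicate generators)."""


class NonConvergenceError(ActiveSheetError):
    """An iterative solver failed to reach its tolerance.

    Attributes
    ----------
    residual : float
        Final residual when iteration stopped.
    """

    def __init__(self, message, residual=None):
        super().__init__(message)
        self.residual = residual


class UnstableStepWarning(UserWarning):
    """Integrator step moved a particle by a distance comparable to its radius."""


class IncommensurateWavevectorWarning(UserWarning):
    """A requested wavevector is not commensurate with the periodic box."""
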