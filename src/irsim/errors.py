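"""Exception hierarchy.

``ValidationError`` covers bad user inputs (wrong shapes, incompatible grids,
malformed files); ``ComputationError`` covers failures that arise during an
otherwise well-posed run (non-convergence, leakage-guard trips). The CLI maps
the two branches to distinct exit codes.
"""


class IrsimError(Exception):
    """Base class for all package errors."""


class ValidationError(IrsimError, ValueError):
    """Invalid input data, configuration, or file contents."""


class GridMismatchError(ValidationError):
    """Two objects do not share the same wavenumber grid."""


class CalibrationError(ValidationError):
    """Calibration is impossible (too few spectra, mixed labels)."""


class DegenerateLabelsError(ValidationError):
    """A classification input contains fewer than two classes."""


class UnsplittableError(ValidationError):
    """A class has too few members for the requested fold count."""


class ConfigError(ValidationError):
    """Malformed or unknown configuration keys."""


class ComputationError(IrsimError, RuntimeError):
    """A well-posed computation failed at run time."""


class LeakageError(ComputationError):
    """A held-out sample leaked into calibration or training."""


class ConvergenceError(ComputationError):
    """An iterative procedure did not converge within its budget."""
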