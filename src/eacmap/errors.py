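"""Exception hierarchy for eacmap.

Per-channel estimation failures are *data* (missing values with reason codes),
not exceptions; these classes cover configuration and contract violations that
should abort a computation.
"""


class EacmapError(Exception):
    """Base class for all eacmap errors."""


class ConfigurationError(EacmapError):
    """A montage / config is unusable (e.g. too few channels in the fit window)."""


class CalibrationError(EacmapError):
    """Requested cohort calibration targets are infeasible."""


class UnsupportedWavelengthError(EacmapError):
    """No chromophore data packaged for the requested wavelength."""


class InvalidChannelError(EacmapError):
    """A channel's samples violate a precondition (non-finite, non-positive mean)."""


class UndefinedSNRError(EacmapError):
    """SNR is undefined (zero variance after filtering)."""


class ParameterError(EacmapError):
    """An operation parameter is out of its admissible range."""


class EmptySelectionError(EacmapError):
    """A channel selection produced no usable samples."""


class UnderdeterminedFitError(EacmapError):
    """Too few samples or degenerate distance spread for a slope fit."""


class DegenerateGeometryError(EacmapError):
    """Projected points are collinear / degenerate for interpolation."""


class AlignmentError(EacmapError):
    """Grid maps do not share a common raster."""


class UndefinedCorrelationError(EacmapError):
    """Correlation undefined (zero variance or perfect collinearity)."""


class DegenerateTestError(EacmapError):
    """A statistical test is degenerate (e.g. zero-variance differences)."""


class NoPulseError(EacmapError):
    """Fewer than two heart beats detected in the optical pulse signal."""
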