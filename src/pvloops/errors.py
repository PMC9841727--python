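"""Exception hierarchy for the pvloops pipeline.

Every stage raises a subclass of :class:`PVLoopsError` so the CLI can report
the failing stage with a remedial hint instead of a bare traceback.
"""


class PVLoopsError(Exception):
    """Base class for all pvloops errors."""


class FormatError(PVLoopsError):
    """Input file does not conform to the declared dialect (e.g. missing column)."""


class TimingError(PVLoopsError):
    """Timestamps are non-uniform or otherwise inconsistent with the sample rate."""


class ArgumentError(PVLoopsError, ValueError):
    """Invalid argument value (non-integer factor, rate below native, ...)."""


class BoundsError(PVLoopsError):
    """Requested interval lies outside the data range."""


class NoWindowError(PVLoopsError):
    """Gradient activity never exceeds the detection threshold."""


class DetectionError(PVLoopsError):
    """A fiducial detector found nothing usable (flat ECG, monotone volume, ...)."""


class InsufficientDataError(PVLoopsError):
    """Fewer beats / points available than the operation requires."""


class OnsetNotFoundError(DetectionError):
    """Automatic occlusion-onset detection failed; configure the time manually."""


class GeometryError(PVLoopsError):
    """Contour geometry is invalid for centerline-rotation volumetry."""


class IncompleteBeatError(PVLoopsError):
    """A beat is missing a fiducial required for the requested summary."""


class PairingError(PVLoopsError):
    """Pressure- and volume-side beat counts disagree over the analysis window."""


class FitError(PVLoopsError):
    """A pressure-volume relationship fit could not be computed."""


class InsufficientPointsError(FitError):
    """Fewer than three fiducial points supplied to a PVR fit."""


class DegenerateFitError(FitError):
    """Zero volume variance: the fit line is vertical/undefined."""


class NonPhysiologicalFitError(FitError):
    """EDPVR slope is non-positive; compliance is undefined."""


class UndefinedICCError(PVLoopsError):
    """Intraclass correlation is undefined (zero total variance)."""


class ConfigurationError(PVLoopsError):
    """Simulator or run configuration violates a parameter invariant."""
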