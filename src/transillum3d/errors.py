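"""Exception hierarchy for transillum3d."""


class Transillum3DError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(Transillum3DError, ValueError):
    """A physical or numerical parameter is out of its valid range."""


class GeometryError(Transillum3DError, ValueError):
    """A phantom or sampling geometry does not fit the image grid."""


class TruncationError(Transillum3DError, ValueError):
    """Kernel support too small for the requested tail tolerance.

    Carries ``suggested_radius`` (mm), the smallest support radius that
    would meet the tolerance, when one exists.
    """

    def __init__(self, message, suggested_radius=None):
        super().__init__(message)
        self.suggested_radius = suggested_radius


class FeatureExtractionError(Transillum3DError, ValueError):
    """No usable absorption dip / non-converging profile fit."""


class LookupTableError(Transillum3DError, ValueError):
    """Lookup-table construction failed (e.g. a node without features)."""


class SizeError(Transillum3DError, ValueError):
    """Kernel larger than the image it should be applied to."""


class NoPeakError(Transillum3DError, ValueError):
    """A focus curve is degenerate (flat) and has no fittable peak."""


class CalibrationError(Transillum3DError, ValueError):
    """Not enough distinct points for a linear depth calibration."""


class DetectionError(Transillum3DError, ValueError):
    """No curvilinear absorber could be detected in the image."""
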