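"""Exception hierarchy for the octcornea pipeline."""


class OctCorneaError(Exception):
    """Base class for all package-specific errors."""


class GeometryError(OctCorneaError, ValueError):
    """Raised when physical/raster geometry is inconsistent (e.g. an
    interface would fall outside the imaged depth range, or an image is
    too narrow to host the reflex exclusion plus its flanking regions)."""


class DetectionError(OctCorneaError, RuntimeError):
    """No detectable anterior surface / apex in an image or region."""


class SegmentationError(DetectionError):
    """Peak-to-interface assignment failed.

    Carries ``qc_flags`` describing which interfaces could not be
    assigned; downstream code uses these to trigger the manual-override
    path.
    """

    def __init__(self, message: str, qc_flags: tuple = ()):
        super().__init__(message)
        self.qc_flags = tuple(qc_flags)


class ValidationError(OctCorneaError, ValueError):
    """Inconsistent or non-physical user-supplied values."""


class InsufficientDataError(OctCorneaError, ValueError):
    """A statistic was requested on fewer observations than it needs."""


class ConfigError(OctCorneaError, ValueError):
    """Malformed pipeline configuration (unknown keys, bad types)."""
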