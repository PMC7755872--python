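"""Exception hierarchy for the hoquant pipeline.

Every stage raises a subclass of :class:`HoquantError`, so callers (and the
CLI) can distinguish pipeline failures from programming errors.
"""


class HoquantError(Exception):
    """Base class for all hoquant errors."""


class ConfigurationError(HoquantError):
    """Invalid acquisition/model configuration (unknown voltage pair, size, ...)."""


class GeometryError(HoquantError):
    """Phantom or ROI geometry is inconsistent (insert outside body, overlap, ...)."""


class RoiError(HoquantError):
    """ROI is empty or too small after erosion."""


class DegenerateSpectraError(HoquantError):
    """Spectral separation too small; the material basis is ill-conditioned."""


class ProvenanceError(HoquantError):
    """Duplicate or inconsistent calibration-table entries."""


class CalibrationLookupError(HoquantError):
    """Requested (voltage pair, diameter) not present / outside calibrated range."""


class RegistrationError(HoquantError):
    """Low- and high-kV volumes are not co-registered (shape/spacing mismatch)."""


class PairingError(HoquantError):
    """ROIs do not map one-to-one onto ground-truth inserts."""


class SegmentationError(HoquantError):
    """Deposit segmentation produced an empty mask."""


class UndefinedSNRError(HoquantError):
    """SNR requested on a region with zero standard deviation."""


class RankError(HoquantError):
    """Regression design is rank deficient (all abscissae identical)."""


class DomainError(HoquantError, ValueError):
    """Scalar argument outside its mathematical domain."""


class DependencyError(HoquantError):
    """A pipeline stage is missing a required upstream product."""
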