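"""Exception hierarchy.

All pipeline errors derive from :class:`DoseAccumError` so callers can catch
one base class; the subtypes mirror the distinct failure contracts of the
I/O, geometry and DVH layers.
"""


class DoseAccumError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(DoseAccumError):
    """A DICOM or text input is malformed or missing required attributes."""


class UnsupportedUnitsError(FormatError):
    """Dose units other than Gy."""


class NonUniformGridError(FormatError):
    """Dose-grid slice offsets are not uniformly spaced."""


class RigidityError(DoseAccumError):
    """A registration matrix is not rigid within tolerance."""


class EmptyStructureError(DoseAccumError):
    """An operation that requires a nonempty ROI/mask got an empty one."""


class UndefinedMetricError(DoseAccumError):
    """A metric is mathematically undefined for the given input."""


class FrameMismatchError(DoseAccumError):
    """Two objects that must share a frame of reference do not."""


class CoverageError(DoseAccumError):
    """Too much of a structure lies outside the dose grid."""


class LookupError_(DoseAccumError):
    """A requested structure or metric name is not present."""


class ConfigError(DoseAccumError):
    """Invalid configuration value."""


class InsufficientDataError(DoseAccumError):
    """Not enough observations for a statistic."""


class DegenerateInputError(DoseAccumError):
    """A statistic is undefined because an input series is degenerate."""


class CourseError(DoseAccumError):
    """A treatment-course manifest or its files are inconsistent."""
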