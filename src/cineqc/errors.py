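"""Exception hierarchy for cineqc.

Every error raised by the package derives from :class:`CineQCError` so
pipeline code can isolate per-study failures with a single except clause.
"""


class CineQCError(Exception):
    """Base class for all cineqc errors."""


class LabellingError(CineQCError):
    """A voxel value outside the declared label vocabulary."""


class GeometryError(CineQCError):
    """Non-positive or otherwise invalid voxel geometry."""


class ConsistencyError(CineQCError):
    """Shape/spacing mismatch between volumes that must be congruent."""


class ManifestError(CineQCError):
    """A study manifest names a missing or malformed entry."""


class PhantomSpecError(CineQCError):
    """A phantom specification describes impossible geometry."""


class DefectError(CineQCError):
    """A defect cannot be applied to the given study."""


class IncompleteStudyError(CineQCError):
    """A ventricle is segmented in fewer than two phases."""


class ConfigurationError(CineQCError):
    """An operation was requested with inconsistent configuration."""


class DegenerateHistogramError(CineQCError):
    """All histogram mass lies in a single bin; no threshold exists."""


class InsufficientDataError(CineQCError):
    """Too few observations for the requested statistic."""
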