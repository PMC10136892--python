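"""Exception hierarchy for pipeline failure modes.

Every recoverable domain error derives from :class:`RadpetError` so callers
(and the CLI) can distinguish expected analysis failures from bugs.
"""


class RadpetError(Exception):
    """Base class for all domain errors raised by this package."""


class UnsupportedParameterError(RadpetError):
    """A parameter outside the supported family (e.g. gamma skew <= 0)."""


class InvalidReferenceError(RadpetError):
    """Liver reference region empty or unusable."""


class NoTumorFoundError(RadpetError):
    """Segmentation produced an empty tumor mask; patient must be excluded."""


class GeometryMismatchError(RadpetError):
    """Volumes/masks with incompatible grids and no resampling transform."""


class DegenerateRegionError(RadpetError):
    """Mask too small/degenerate for the requested feature computation."""


class SchemaMismatchError(RadpetError):
    """Feature tables with different patients or feature names."""


class EmptyFeatureSpaceError(RadpetError):
    """All features constant after normalization; nothing to select."""


class UnsplittableStratumError(RadpetError):
    """An outcome stratum too small to split into train and test."""


class DegenerateLabelsError(RadpetError):
    """Binary outcome with a single class."""


class DegenerateSplitError(RadpetError):
    """Dichotomization threshold left one survival group empty."""


class NoEventsError(RadpetError):
    """Survival comparison without any observed events."""


class InvalidCategoryError(RadpetError):
    """Unknown RECIST response category."""


class PhantomPlacementError(RadpetError):
    """Could not place lesions without colliding with the liver."""
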