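"""Exception hierarchy for contourqa.

Everything raised on purpose by this package derives from :class:`ContourQAError`
so callers (in particular the cohort runner, which must not die on a single bad
mask) can catch package errors without swallowing programming mistakes.
"""


class ContourQAError(Exception):
    """Base class for all contourqa errors."""


class MaskFormatError(ContourQAError):
    """A mask file could not be parsed in the requested/detected format."""


class MaskValidationError(ContourQAError, ValueError):
    """A mask, grid or RLE object violates a structural invariant."""


class ManifestSchemaError(ContourQAError):
    """A cohort manifest CSV is missing columns, has duplicate keys, or bad labels."""


class EmptyMaskError(ContourQAError):
    """An operation defined only on non-empty masks was given an empty mask."""


class CohortSizeError(ContourQAError):
    """A percentile model was fitted on fewer rows than its configured floor."""


class GeometryError(ContourQAError):
    """A synthetic phantom does not fit inside its grid (with a 1-voxel margin)."""


class DefectError(ContourQAError):
    """A defect injection is not applicable to the given mask."""
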