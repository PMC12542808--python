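"""Exception hierarchy for baitkit.

All toolkit-specific failures derive from :class:`BaitkitError` so callers
can catch one base class at CLI boundaries.
"""


class BaitkitError(Exception):
    """Base class for all baitkit errors."""


class FormatError(BaitkitError):
    """A file could not be parsed as the expected format."""


class AlignmentShapeError(FormatError):
    """Sequences in one alignment do not share the same length."""


class NamingError(BaitkitError):
    """A taxon or locus label violates a naming convention."""


class CoordinateError(BaitkitError):
    """Exon coordinates are inconsistent (overlap, out of range, reversed)."""


class ArityError(BaitkitError):
    """An operation received fewer inputs than it mathematically requires."""


class UndefinedIdentityError(BaitkitError):
    """No sequence pair shares any comparable column."""


class EmptyInputError(BaitkitError):
    """An operation that requires at least one element received none."""


class ConfigError(BaitkitError):
    """A configuration value is outside its legal range."""


class DataError(BaitkitError):
    """Input data violate a documented precondition."""


class DegenerateFitError(BaitkitError):
    """A regression cannot be fit (e.g. constant predictor)."""
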