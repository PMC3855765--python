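"""Exception hierarchy.

Everything raised on purpose by this package derives from :class:`BnecError`,
so callers can catch one type at a pipeline boundary.  Subclasses double as
``ValueError`` where the cause is a bad argument, so ad-hoc callers that only
know the standard library still behave sensibly.
"""


class BnecError(Exception):
    """Base class for all errors raised by bnec."""


class ParameterError(BnecError, ValueError):
    """An argument is out of its documented range or inconsistent."""


class AcyclicityError(BnecError, ValueError):
    """An operation would create, or was handed, a directed cycle."""


class RankDeficiencyError(BnecError, ValueError):
    """A design matrix is rank deficient (collinear parents or confounds)."""


class DegenerateVarianceError(BnecError, ValueError):
    """A conditional variance of zero poisons a likelihood evaluation."""


class DegenerateInputError(BnecError, ValueError):
    """A column is constant (zero variance) where variation is required."""


class ExtractionError(BnecError, ValueError):
    """A region-of-interest sphere contains no voxel centers."""


class FormatError(BnecError, ValueError):
    """A file on disk does not match the expected tabular/NIfTI layout."""


class ConfigError(BnecError, ValueError):
    """A run configuration is invalid (missing paths, bad values)."""


class DataError(BnecError, ValueError):
    """Input data violates a precondition (shape, group sizes, NaNs)."""
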