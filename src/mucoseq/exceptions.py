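"""Exception hierarchy.

Every error raised on purpose by mucoseq derives from :class:`MucoseqError`
so callers can catch the package's failures without masking programming
errors.
"""


class MucoseqError(Exception):
    """Base class for all mucoseq errors."""


class InvalidDesignError(MucoseqError, ValueError):
    """Sample design does not support the requested operation
    (missing factor columns, undersized groups, overlapping groups)."""


class EmptyInputError(MucoseqError, ValueError):
    """An operation received an empty table where data is required."""


class DegenerateSampleError(MucoseqError, ValueError):
    """A sample has zero total counts and cannot be library-size normalized."""


class UniverseMismatchError(MucoseqError, ValueError):
    """Two signed gene sets do not share the same gene universe."""


class SamplingError(MucoseqError, ValueError):
    """A requested random subset is larger than the sampling universe."""


class SplitInfeasibleError(MucoseqError, ValueError):
    """A group is too small for the requested train/test split."""


class MeasurementValidationError(MucoseqError, ValueError):
    """A measurement table violates the protocol's validity rules
    (e.g. fewer than 25 distance measurements for a mouse)."""


class PairingError(MucoseqError, ValueError):
    """Paired comparison received rows that cannot be matched into pairs."""


class InsufficientDataError(MucoseqError, ValueError):
    """Too few observations for the requested estimate (e.g. a slope
    from a single time point)."""
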