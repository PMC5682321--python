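"""Exception hierarchy.

All stgc-specific failures derive from :class:`StgcError` so callers can
catch the package's errors without masking programming mistakes.
"""


class StgcError(Exception):
    """Base class for all stgc errors."""


class ConfigurationError(StgcError):
    """Invalid analysis configuration (e.g. non-divisible windowing)."""


class LengthError(StgcError):
    """A time series is too short for the requested operation."""


class DegenerateSeriesError(StgcError):
    """A series is constant or otherwise uninformative."""


class SingularDesignError(StgcError):
    """Rank-deficient regression design; the message names the offending columns."""


class StationarityError(StgcError):
    """A generating VAR coupling matrix has spectral radius >= 1."""


class IdentifiabilityError(StgcError):
    """Model parameters cannot be identified from the supplied data."""


class EmptyTractError(StgcError):
    """No unmasked voxels remain in a tract."""
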