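"""Exception types raised across the package.

All input-contract violations raise :class:`BmsError` (a ``ValueError``
subclass) with a message naming the offending quantity, so callers can
distinguish bad inputs from programming errors.
"""


class BmsError(ValueError):
    """Base class for labelled input/contract errors."""


class DataError(BmsError):
    """Malformed or inconsistent data arrays (shapes, NaNs, labels)."""


class DesignError(BmsError):
    """Invalid model specification or design matrix (rank, missing labels)."""


class GridError(BmsError):
    """Inconsistent voxel grids, masks, or image geometry."""
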