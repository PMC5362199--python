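"""Exception types shared across the pipeline stages."""


class LichentrendError(Exception):
    """Base class for all package errors."""


class AlignmentError(LichentrendError):
    """Rasters do not share a grid, or a grid does not nest in another."""


class ConfigurationError(LichentrendError):
    """Invalid or incomplete configuration (band maps, parameters, paths)."""


class EmptyDomainError(LichentrendError):
    """An operation's spatial domain (mask ∩ valid ∩ zone) is empty."""


class InsufficientDataError(LichentrendError):
    """Fewer observations than the operation's minimum."""


class DegenerateInputError(LichentrendError):
    """Input with zero variance or otherwise degenerate structure."""


class RecipeError(LichentrendError):
    """Synthetic-data recipe that cannot be realised (e.g. target LVE > amplitude)."""


class FitError(LichentrendError):
    """Model fit failed to converge; carries diagnostics in the message."""
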