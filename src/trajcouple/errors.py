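"""Exception hierarchy.

``ValidationError`` covers malformed inputs and configuration (CLI exit code
2); ``ComputeError`` covers failures arising during a computation on valid
inputs (CLI exit code 1).
"""


class TrajcoupleError(Exception):
    """Base class for all package errors."""


class ValidationError(TrajcoupleError):
    """Invalid input data, file, selection, or configuration."""


class ParseError(ValidationError):
    """Malformed file content; message names the offending line."""


class DimensionError(ValidationError):
    """Array/atom-count shape mismatch."""


class SelectionError(ValidationError):
    """Unknown region label or empty atom selection."""


class AlignmentError(ValidationError):
    """Frame universes of two per-frame datasets do not match."""


class ComputeError(TrajcoupleError):
    """A computation failed on otherwise valid inputs."""


class DegenerateFitError(ComputeError):
    """Superposition fit set is too small or collinear."""


class NumericRangeError(ComputeError):
    """A value exceeded the representable numeric range."""


class EmptyLandscapeError(ComputeError):
    """Every histogram bin fell below the occupancy cutoff."""
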