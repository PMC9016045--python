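"""Exception types raised across the package."""


class IraequantError(Exception):
    """Base class for all package-specific errors."""


class InvalidMetadataError(IraequantError):
    """Scan metadata violates its contract (nonpositive weight/dose, ...)."""


class AlignmentError(IraequantError):
    """Two grids do not overlap in world space, or do not match when required."""


class EmptyOrganError(IraequantError):
    """An organ label referenced by an operation has no voxels in the mask."""


class SingleClassError(IraequantError):
    """A two-group statistic was requested on a cohort with only one class."""


class InsufficientDataError(IraequantError):
    """Too few observations for the requested estimate (e.g. n < 2 for a normal range)."""


class PhantomSpecError(IraequantError):
    """A phantom geometry specification is degenerate or exceeds the grid."""


class CalibrationError(IraequantError):
    """Baseline calibration failed to converge; carries per-organ diagnostics."""

    def __init__(self, message: str, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics
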