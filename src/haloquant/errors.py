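"""Exception hierarchy for haloquant."""


class HaloQuantError(Exception):
    """Base class for all haloquant errors."""


class InvalidParameterError(HaloQuantError, ValueError):
    """A numeric or structural parameter violates its precondition."""


class InsufficientStandardError(HaloQuantError, ValueError):
    """Too few (or degenerate) standard lanes to fit a calibration curve."""


class DegenerateStandardError(HaloQuantError, ValueError):
    """A fitted standard curve has a non-positive slope."""


class InvalidLaneError(HaloQuantError, ValueError):
    """A gel lane fails its invariants (e.g. zero cells on a lysate lane)."""


class CalibrationError(HaloQuantError, ValueError):
    """A calibration input is unusable (non-positive denominator, etc.)."""


class FitFailureError(HaloQuantError, RuntimeError):
    """A nonlinear fit failed to converge; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class GeometryError(HaloQuantError, ValueError):
    """A synthetic geometry violates containment or sizing constraints."""


class SegmentationFailureError(HaloQuantError, RuntimeError):
    """Segmentation could not find an acceptable nuclear mass."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}
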