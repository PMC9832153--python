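"""Exception types shared across the package."""


class HeatRhythmError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(HeatRhythmError):
    """A synthetic-data or run configuration violates its invariants."""


class BinningError(HeatRhythmError):
    """A temperature falls outside the bin coverage, or a required bin is missing."""


class PanelValidationError(HeatRhythmError):
    """A visitation panel violates the schema (hours, keys, missing values)."""


class ConvergenceError(HeatRhythmError):
    """Alternating-projection demeaning failed to converge.

    Carries the last max absolute per-sweep change in ``residual``.
    """

    def __init__(self, message: str, residual: float):
        super().__init__(message)
        self.residual = residual


class CollinearityError(HeatRhythmError):
    """The regressor block is singular after FE absorption."""


class UnsolvableShiftError(HeatRhythmError):
    """The time-shift equation has no solution inside the activity window."""
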