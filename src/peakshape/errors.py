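"""Exception hierarchy."""


class PeakShapeError(Exception):
    """Base class for all peakshape errors."""


class InvalidParameterError(PeakShapeError, ValueError):
    """A parameter is outside its valid domain (e.g. sigma <= 0)."""


class DegenerateSampleError(PeakShapeError, ValueError):
    """A read sample is empty or carries no scale information.

    Callers running per-peak loops should catch this and mark the peak
    skipped rather than aborting the run.
    """


class NormalizationError(PeakShapeError, ValueError):
    """Size-factor estimation failed (no peak positive in all samples)."""


class UntestableBinError(PeakShapeError, ValueError):
    """A count bin holds no null statistics to compare against."""


class InvalidConfigError(PeakShapeError, ValueError):
    """A simulation or run configuration violates its invariants."""


class InvalidInputError(PeakShapeError, ValueError):
    """Structurally invalid input (mismatched grids, misaligned tables)."""
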