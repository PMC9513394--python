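"""Exception hierarchy for abusvol."""


class AbusvolError(Exception):
    """Base class for all abusvol errors."""


class CalibrationError(AbusvolError):
    """Invalid scale reference or calibration (non-positive extents)."""


class ContourError(AbusvolError):
    """Invalid contour (fewer than 3 vertices, degenerate geometry)."""


class SeriesError(AbusvolError):
    """Invalid slice series (negative area, non-positive thickness)."""


class MeasurementError(AbusvolError):
    """Invalid caliper measurement (non-positive dimension)."""


class EmptyTumorError(AbusvolError):
    """A mask stack with no foreground pixels cannot be measured."""


class InsufficientDataError(AbusvolError):
    """Too few observations for the requested statistic."""


class DegenerateTestError(AbusvolError):
    """All paired differences are zero; the signed-rank test is undefined."""


class RatioError(AbusvolError):
    """Ratio statistics require strictly positive denominators."""


class PhantomError(AbusvolError):
    """Phantom specification produces a degenerate realization."""


class RenderError(AbusvolError):
    """Requested annotation does not fit in the rendered image."""


class FixtureError(AbusvolError):
    """Packaged study table failed its integrity check."""
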