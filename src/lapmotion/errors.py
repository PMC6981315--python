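"""Exception hierarchy.

All errors derive from :class:`LapMotionError` so callers can catch the
package's failures with one clause; each also derives from ``ValueError``
(or ``OSError`` for I/O) to behave idiomatically in generic code.
"""


class LapMotionError(Exception):
    """Base class for all lapmotion errors."""


class TrajectoryFormatError(LapMotionError, ValueError):
    """A trajectory file is malformed (bad cell, missing column, bad XML)."""


class InsufficientDataError(LapMotionError, ValueError):
    """Too few samples for the requested computation (< 2 points, n < 2 pairs)."""


class DegenerateIndexError(LapMotionError, ValueError):
    """Expert and novice medians coincide for an index, so it cannot scale."""


class DegenerateRegressorError(LapMotionError, ValueError):
    """The regression predictor is constant; the OLS slope is undefined."""
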