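"""PET frame schedules.

A dynamic PET acquisition is binned into contiguous frames of increasing
duration.  The frame schedule (start / duration / mid time of every frame,
in seconds since injection) is the temporal backbone of all time-activity
curve arithmetic: frame averaging of model predictions, SUV windows and
fit weighting all refer to it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["FrameSchedule", "make_frame_schedule", "weights_from_schedule", "DEFAULT_FRAMING"]

#: 90-minute dynamic framing used throughout: 8 x 15 s, 3 x 60 s, 5 x 120 s,
#: 5 x 300 s, 5 x 600 s  (26 frames, 5400 s).
DEFAULT_FRAMING: tuple[tuple[int, float], ...] = (
    (8, 15.0),
    (3, 60.0),
    (5, 120.0),
    (5, 300.0),
    (5, 600.0),
)


@dataclass(frozen=True)
class FrameSchedule:
    """Contiguous, non-overlapping PET frames starting at injection (t = 0 s)."""

    start: np.ndarray
    duration: np.ndarray

    def __post_init__(self) -> None:
        start = np.asarray(self.start, dtype=float)
        duration = np.asarray(self.duration, dtype=float)
        object.__setattr__(self, "start", start)
        object.__setattr__(self, "duration", duration)
        if start.ndim != 1 or start.shape != duration.shape or start.size == 0:
            raise ValueError("start and duration must be equal-length 1-D arrays")
        if np.any(duration <= 0):
            raise ValueError("frame durations must be positive")
        if not np.isclose(start[0], 0.0):
            raise ValueError("first frame must start at t = 0")
        if not np.allclose(start[1:], start[:-1] + duration[:-1]):
            raise ValueError("frames must be contiguous and non-overlapping")

    @property
    def end(self) -> np.ndarray:
        return self.start + self.duration

    @property
    def mid(self) -> np.ndarray:
        return self.start + 0.5 * self.duration

    @property
    def n_frames(self) -> int:
        return int(self.start.size)

    @property
    def total_duration(self) -> float:
        """Total scan duration in seconds."""
        return float(self.end[-1])


def make_frame_schedule(spec=DEFAULT_FRAMING) -> FrameSchedule:
    """Build a :class:`FrameSchedule` from ``[(count, duration_s), ...]``.

    Frames are laid down contiguously from t = 0; the total duration is
    ``sum(count * duration)``.  The default spec is the 26-frame / 90-min
    schedule.
    """
    spec = list(spec)
    if not spec:
        raise ValueError("frame spec must not be empty")
    durations: list[float] = []
    for count, dur in spec:
        count = int(count)
        if count < 1:
            raise ValueError("frame counts must be >= 1")
        if dur <= 0:
            raise ValueError("frame durations must be > 0")
        durations.extend([float(dur)] * count)
    duration = np.asarray(durations)
    start = np.concatenate([[0.0], np.cumsum(duration)[:-1]])
    return FrameSchedule(start=start, duration=duration)


def weights_from_schedule(schedule: FrameSchedule, tac=None) -> np.ndarray:
    """Fit weights proportional to frame duration, normalised to sum to n frames.

    Longer frames accumulate more counts and carry proportionally more weight
    in the weighted least-squares kinetic fits.  ``tac`` is accepted for
    interface symmetry but unused by this duration-only scheme.
    """
    w = schedule.duration / schedule.duration.sum() * schedule.n_frames
    return w
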