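"""Acquisition timing for the triple-injection short-window protocol.

The protocol splits a standard FDG dose into three equal intravenous
boluses.  The first is given with the subject outside the scanner; after a
36-min uptake phase a single 24-min dynamic acquisition follows, built from
a 3-min late brain scan (36-39 min), 9 min of cardiac imaging (39-48 min,
during which the second bolus is given at 42.5 min) and a 12-min early
brain scan (48-60 min, third bolus at 49 min).  For simulation work the
full 60-min acquisition is represented by a single 50-frame schedule whose
first 36 min form the validation window.

Times are minutes from the first injection throughout.  Frame intervals
are half-open ``[start, start + duration)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "FrameSchedule",
    "InjectionSchedule",
    "ImagingWindow",
    "standard_protocol",
    "frame_midtimes",
    "select_window",
    "protocol_from_config",
    "SIMULATION_FRAME_BLOCKS",
]

_TOL = 1e-9

#: Frame blocks of the canonical 60-min simulation schedule as
#: (number of frames, frame duration in seconds).  They sum to exactly
#: 60 min over 50 frames; the 39-48 min cardiac stretch is the
#: 3x60 s, 3x20 s, 4x30 s, 3x60 s sequence of the protocol.
SIMULATION_FRAME_BLOCKS: tuple[tuple[int, int], ...] = (
    (3, 20),
    (4, 30),
    (3, 60),
    (22, 90),
    (3, 60),
    (3, 20),
    (4, 30),
    (3, 60),
    (2, 90),
    (3, 180),
)


@dataclass(frozen=True)
class FrameSchedule:
    """A sequence of non-overlapping acquisition frames.

    Parameters
    ----------
    start
        Frame start times in minutes from the first injection.
    duration
        Frame durations in minutes, same length as ``start``.
    """

    start: np.ndarray
    duration: np.ndarray

    def __post_init__(self) -> None:
        start = np.atleast_1d(np.asarray(self.start, dtype=float))
        duration = np.atleast_1d(np.asarray(self.duration, dtype=float))
        if start.ndim != 1 or duration.ndim != 1 or start.size != duration.size:
            raise ValueError("start and duration must be 1-D and equally long")
        if start.size:
            if np.any(duration <= 0):
                raise ValueError("frame durations must be positive")
            if np.any(np.diff(start) <= 0):
                raise ValueError("frame starts must be strictly increasing")
            if np.any(start[1:] < start[:-1] + duration[:-1] - _TOL):
                raise ValueError("frames must not overlap")
        object.__setattr__(self, "start", start)
        object.__setattr__(self, "duration", duration)

    @classmethod
    def from_blocks(
        cls, blocks: Iterable[tuple[int, float]], t0: float = 0.0
    ) -> "FrameSchedule":
        """Build an abutting schedule from ``(n_frames, duration_s)`` blocks."""
        durations: list[float] = []
        for n, dur_s in blocks:
            if n < 1 or dur_s <= 0:
                raise ValueError("blocks need n >= 1 and positive duration")
            durations.extend([dur_s / 60.0] * int(n))
        dur = np.asarray(durations)
        start = t0 + np.concatenate(([0.0], np.cumsum(dur[:-1])))
        return cls(start, dur)

    @property
    def n_frames(self) -> int:
        return int(self.start.size)

    @property
    def end(self) -> np.ndarray:
        """Frame end times in minutes."""
        return self.start + self.duration

    @property
    def total_duration(self) -> float:
        """Summed frame durations in minutes (gaps excluded)."""
        return float(self.duration.sum())

    @property
    def midtimes(self) -> np.ndarray:
        return self.start + 0.5 * self.duration

    def subset(self, indices: Sequence[int] | np.ndarray) -> "FrameSchedule":
        """Schedule restricted to the given frame indices (kept sorted)."""
        idx = np.asarray(indices, dtype=int)
        return FrameSchedule(self.start[idx], self.duration[idx])

    def __len__(self) -> int:  # pragma: no cover - convenience
        return self.n_frames


@dataclass(frozen=True)
class InjectionSchedule:
    """Bolus injection times (min) and dose fractions.

    The canonical protocol injects equal thirds at 0, 42.5 and 49 min.
    Fractions are not forced to sum to one so that the effect of varying
    the split can be explored; positivity and strictly increasing times
    are enforced.
    """

    times: np.ndarray
    fractions: np.ndarray

    def __post_init__(self) -> None:
        times = np.atleast_1d(np.asarray(self.times, dtype=float))
        fractions = np.atleast_1d(np.asarray(self.fractions, dtype=float))
        if times.size != fractions.size or times.size == 0:
            raise ValueError("times and fractions must be equally long and non-empty")
        if np.any(np.diff(times) <= 0):
            raise ValueError("injection times must be strictly increasing")
        if np.any(fractions <= 0):
            raise ValueError("dose fractions must be positive")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "fractions", fractions)

    @property
    def n_injections(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class ImagingWindow:
    """A labelled half-open imaging window ``[start, end)`` in minutes."""

    label: str
    start: float
    end: float

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError("window requires 0 <= start < end")


def standard_protocol(
    dose_fractions: Sequence[float] = (1 / 3, 1 / 3, 1 / 3),
) -> tuple[FrameSchedule, InjectionSchedule, Mapping[str, ImagingWindow]]:
    """Canonical 60-min simulation schedule, injections and windows.

    Returns the 50-frame schedule built from
    :data:`SIMULATION_FRAME_BLOCKS`, injections at (0, 42.5, 49) min with
    the given dose fractions, and the four imaging windows:
    ``validation`` [0, 36), ``brain_late`` [36, 39), ``cardiac`` [39, 48)
    and ``brain_early`` [48, 60).
    """
    schedule = FrameSchedule.from_blocks(SIMULATION_FRAME_BLOCKS)
    injections = InjectionSchedule(
        np.array([0.0, 42.5, 49.0]), np.asarray(dose_fractions, dtype=float)
    )
    windows = {
        "validation": ImagingWindow("validation", 0.0, 36.0),
        "brain_late": ImagingWindow("brain_late", 36.0, 39.0),
        "cardiac": ImagingWindow("cardiac", 39.0, 48.0),
        "brain_early": ImagingWindow("brain_early", 48.0, 60.0),
    }
    return schedule, injections, windows


def protocol_from_config(
    config: Mapping,
) -> tuple[FrameSchedule, InjectionSchedule, dict[str, ImagingWindow]]:
    """Build a protocol from a parsed YAML/JSON configuration mapping.

    Expected keys: ``frames`` — list of ``[n_frames, duration_s]``
    blocks; ``injection_times_min`` and ``dose_fractions`` — equal-length
    lists; optional ``windows`` — mapping of label to ``[start, end]``
    in minutes.
    """
    schedule = FrameSchedule.from_blocks(
        [(int(n), float(d)) for n, d in config["frames"]]
    )
    injections = InjectionSchedule(
        np.asarray(config["injection_times_min"], dtype=float),
        np.asarray(config["dose_fractions"], dtype=float),
    )
    windows = {
        label: ImagingWindow(label, float(start), float(end))
        for label, (start, end) in dict(config.get("windows", {})).items()
    }
    return schedule, injections, windows


def frame_midtimes(schedule: FrameSchedule) -> np.ndarray:
    """Frame midpoint times ``start + duration/2`` in minutes."""
    return schedule.midtimes


def select_window(schedule: FrameSchedule, window: ImagingWindow) -> np.ndarray:
    """Indices of frames fully contained in ``[window.start, window.end)``.

    Frames straddling a window boundary are excluded.
    """
    inside = (schedule.start >= window.start - _TOL) & (
        schedule.end <= window.end + _TOL
    )
    return np.flatnonzero(inside)
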