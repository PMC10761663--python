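"""Arterial input function model for the triple-injection protocol.

The plasma input is described by the third-order Feng model

    f(t) = A1 * t * exp(-mu1 * t) + A2 * (exp(-mu2 * t) - exp(-mu1 * t))

with amplitudes ``A1, A2`` (kBq/ml) and rate constants ``mu1 > mu2``
(1/min).  Splitting the dose into boluses at times ``t_j`` with fractions
``w_j`` amounts to convolving ``f`` with an impulse train, which has the
closed form

    Cp(t) = sum_j  w_j * f(t - t_j)   for t >= t_j.

Population shape values (mean +/- SD) from arterialised human FDG data
are exposed as :data:`FENG_POPULATION_MEAN` / ``_SD`` and drive the
simulation studies.  Measured curves are frame averages, so sampling onto
a schedule integrates the continuous model over each frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .protocol import FrameSchedule, InjectionSchedule

__all__ = [
    "FengParams",
    "TimeActivityCurve",
    "feng_value",
    "multi_injection_aif",
    "sample_aif",
    "FrameAverager",
    "FENG_POPULATION_MEAN",
    "FENG_POPULATION_SD",
]


@dataclass(frozen=True)
class FengParams:
    """Third-order Feng input-function shape parameters.

    a1, a2 : kBq/ml;  mu1, mu2 : 1/min, with mu1 > mu2 (the fast washout
    rate exceeds the slow clearance rate).
    """

    a1: float
    a2: float
    mu1: float
    mu2: float

    def __post_init__(self) -> None:
        if min(self.a1, self.a2, self.mu1, self.mu2) <= 0:
            raise ValueError("all Feng parameters must be positive")
        if not self.mu1 > self.mu2:
            raise ValueError("require mu1 > mu2")

    def as_array(self) -> np.ndarray:
        return np.array([self.a1, self.a2, self.mu1, self.mu2])

    @classmethod
    def from_array(cls, x: np.ndarray) -> "FengParams":
        return cls(*(float(v) for v in x))


#: Population mean of the Feng shape parameters (A1, A2 in kBq/ml;
#: mu1, mu2 in 1/min).
FENG_POPULATION_MEAN = FengParams(263.0, 16.0, 3.56, 0.029)
#: Corresponding population SDs, same order and units.
FENG_POPULATION_SD = (120.0, 1.32, 1.31, 0.012)


@dataclass(frozen=True)
class TimeActivityCurve:
    """Frame-sampled activity concentration (kBq/ml) on a schedule.

    Negative activities are permitted (noisy measurements); non-finite
    values are not.
    """

    schedule: FrameSchedule
    activity: np.ndarray

    def __post_init__(self) -> None:
        activity = np.atleast_1d(np.asarray(self.activity, dtype=float))
        if activity.size != self.schedule.n_frames:
            raise ValueError("activity length must equal the frame count")
        if not np.all(np.isfinite(activity)):
            raise ValueError("activity values must be finite")
        object.__setattr__(self, "activity", activity)

    @property
    def midtimes(self) -> np.ndarray:
        return self.schedule.midtimes

    def subset(self, indices: np.ndarray) -> "TimeActivityCurve":
        idx = np.asarray(indices, dtype=int)
        return TimeActivityCurve(self.schedule.subset(idx), self.activity[idx])

    def with_activity(self, activity: np.ndarray) -> "TimeActivityCurve":
        return TimeActivityCurve(self.schedule, activity)


def feng_value(params: FengParams, t) -> np.ndarray | float:
    """Evaluate the single-bolus Feng model at times ``t`` (min).

    Raises ``ValueError`` for negative times; returns 0 at ``t = 0``.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("feng_value is defined for t >= 0")
    e1 = np.exp(-params.mu1 * t_arr)
    out = params.a1 * t_arr * e1 + params.a2 * (np.exp(-params.mu2 * t_arr) - e1)
    return out if out.ndim else float(out)


def multi_injection_aif(
    params: FengParams, injections: InjectionSchedule, t
) -> np.ndarray | float:
    """Plasma input of a multi-bolus protocol at times ``t`` (min).

    Closed-form convolution of the Feng curve with the weighted impulse
    train: each injection contributes ``fraction * f(t - t_inj)`` once
    ``t`` has passed its injection time.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("multi_injection_aif is defined for t >= 0")
    out = np.zeros_like(t_arr)
    for t_inj, frac in zip(injections.times, injections.fractions):
        mask = t_arr >= t_inj
        if np.any(mask):
            out[mask] += frac * np.asarray(
                feng_value(params, t_arr[mask] - t_inj)
            )
    return out if out.ndim else float(out)


class FrameAverager:
    """Precomputed trapezoid quadrature for frame averages of a curve.

    PET frames measure the mean activity over the frame interval, so a
    continuous model is compared with data through
    ``(1/dur) * integral over the frame``.  The averager samples each
    frame on a fine grid (default step 0.01 min, at least 3 points) and
    stores trapezoid weights normalised to the frame duration, so that
    ``average(f(times))`` returns all frame means in one pass.
    """

    def __init__(self, schedule: FrameSchedule, step: float = 0.01) -> None:
        if step <= 0:
            raise ValueError("step must be positive")
        self.schedule = schedule
        times: list[np.ndarray] = []
        weights: list[np.ndarray] = []
        offsets = np.zeros(schedule.n_frames + 1, dtype=int)
        for i, (t0, dur) in enumerate(zip(schedule.start, schedule.duration)):
            n = max(2, int(round(dur / step))) + 1
            tt = np.linspace(t0, t0 + dur, n)
            w = np.full(n, dur / (n - 1))
            w[0] *= 0.5
            w[-1] *= 0.5
            times.append(tt)
            weights.append(w / dur)
            offsets[i + 1] = offsets[i] + n
        self.times = np.concatenate(times) if times else np.empty(0)
        self._weights = np.concatenate(weights) if weights else np.empty(0)
        self._offsets = offsets[:-1]

    def average(self, values: np.ndarray) -> np.ndarray:
        """Frame means of curve values sampled at :attr:`times`."""
        return np.add.reduceat(self._weights * values, self._offsets)


def sample_aif(
    params: FengParams,
    injections: InjectionSchedule,
    schedule: FrameSchedule,
    step: float = 0.01,
) -> TimeActivityCurve:
    """Frame-averaged samples of the multi-bolus input on a schedule."""
    averager = FrameAverager(schedule, step=step)
    values = np.asarray(multi_injection_aif(params, injections, averager.times))
    return TimeActivityCurve(schedule, averager.average(values))
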