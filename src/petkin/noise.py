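"""Frame-duration-scaled Gaussian noise for simulated PET curves.

Counting statistics make short frames noisier: for a frame of duration
``Δt`` (min) holding noiseless activity ``C`` the noisy measurement is

    C' = C + η * c * sqrt(C / Δt),     η ~ N(0, 1) i.i.d. per frame,

so the noise SD scales with sqrt(activity) and 1/sqrt(frame duration);
``c`` is a unitless level dial.  Noisy values are not clipped: negative
outcomes are retained and the fitting stages must tolerate them, since
clipping would bias low-activity frames upward.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .aif import TimeActivityCurve

__all__ = ["NoiseConfig", "add_frame_noise"]


@dataclass(frozen=True)
class NoiseConfig:
    """Noise level ``c`` (unitless, >= 0) and RNG seed."""

    c: float
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.c < 0:
            raise ValueError("noise level c must be nonnegative")


def add_frame_noise(
    curve: TimeActivityCurve,
    config: NoiseConfig,
    rng: np.random.Generator | None = None,
) -> TimeActivityCurve:
    """Return a noisy copy of ``curve``; the input is unchanged.

    One independent standard-normal deviate is drawn per frame from
    ``rng`` (or a fresh generator seeded with ``config.seed``).  The
    noiseless input must be nonnegative (its square root sets the SD).
    """
    a = curve.activity
    if np.any(a < 0):
        raise ValueError("noiseless input activity must be nonnegative")
    if config.c == 0:
        return curve.with_activity(a.copy())
    if rng is None:
        rng = np.random.default_rng(config.seed)
    sd = config.c * np.sqrt(a / curve.schedule.duration)
    return curve.with_activity(a + rng.standard_normal(a.size) * sd)
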