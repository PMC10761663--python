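"""Irreversible two-tissue compartment model (2TCM) and Patlak transform.

FDG in tissue is modelled with a free pool (exchange rates K1 in, k2 out)
and an irreversibly trapped phosphorylated pool (rate k3, k4 = 0).  The
measured voxel/ROI concentration mixes tissue and blood signal through a
plasma volume fraction vb:

    C_T(t) = (1 - vb) * (h ⊗ Cp)(t) + vb * Cp(t)
    h(t)   = K1*k2/(k2+k3) * exp(-(k2+k3) t) + K1*k3/(k2+k3)

The macro-parameter of irreversible uptake is the net influx rate
Ki = K1*k3/(k2+k3) (ml/g/min), which is also the asymptotic slope of the
Patlak plot  C_T(t)/Cp(t)  versus  \\int_0^t Cp / Cp(t).

Convolutions run on a uniform fine grid (default step 1/150 min = 0.4 s,
chosen so grid points land exactly on every frame boundary of the 20 s /
30 s / 60 s / 90 s / 180 s schedules and on the injection times) using an
exact trapezoid recursion for the exponential kernel; model curves are
then frame-averaged like the input sampling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, NamedTuple

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.signal import lfilter

from .aif import TimeActivityCurve
from .protocol import FrameSchedule

__all__ = [
    "TwoTCMParams",
    "impulse_response",
    "tac_2tcm",
    "net_influx_rate",
    "patlak_transform",
    "PatlakPoints",
    "DEFAULT_GRID_STEP",
]

#: Default uniform grid step (min) for convolution and frame averaging;
#: 0.4 s divides all canonical frame durations and injection times.
DEFAULT_GRID_STEP = 1.0 / 150.0


@dataclass(frozen=True)
class TwoTCMParams:
    """Micro-parameters of the irreversible 2TCM.

    k1 : ml/g/min influx; k2, k3 : 1/min efflux and phosphorylation;
    vb : unitless plasma volume fraction in [0, 1).
    """

    k1: float
    k2: float
    k3: float
    vb: float = 0.03

    def __post_init__(self) -> None:
        if min(self.k1, self.k2, self.k3) < 0:
            raise ValueError("K1, k2, k3 must be nonnegative")
        if not 0 <= self.vb < 1:
            raise ValueError("vb must lie in [0, 1)")

    def as_array(self) -> np.ndarray:
        """Free micro-parameters (K1, k2, k3); vb is carried separately."""
        return np.array([self.k1, self.k2, self.k3])


def impulse_response(params: TwoTCMParams, t) -> np.ndarray | float:
    """Tissue impulse-response kernel h(t) in ml/g/min.

    For ``k2 + k3 = 0`` the analytic limit is the constant ``K1``.
    """
    t_arr = np.asarray(t, dtype=float)
    alpha = params.k2 + params.k3
    if alpha == 0:
        out = np.full_like(t_arr, params.k1)
    else:
        out = (params.k1 * params.k2 / alpha) * np.exp(-alpha * t_arr) + (
            params.k1 * params.k3 / alpha
        )
    return out if out.ndim else float(out)


def net_influx_rate(params: TwoTCMParams) -> float:
    """Net influx rate Ki = K1*k3/(k2+k3) in ml/g/min.

    Raises ``ZeroDivisionError`` when ``k2 + k3 = 0`` (rate undefined).
    """
    alpha = params.k2 + params.k3
    if alpha == 0:
        raise ZeroDivisionError("net influx rate undefined for k2 + k3 = 0")
    return params.k1 * params.k3 / alpha


def exp_conv(alpha: float, values: np.ndarray, step: float) -> np.ndarray:
    """Trapezoid convolution of ``exp(-alpha t)`` with sampled ``values``.

    Uses the exact first-order recursion
    ``y[n] = d*y[n-1] + step/2 * (v[n] + d*v[n-1])`` with
    ``d = exp(-alpha*step)``, equivalent to trapezoid quadrature of the
    convolution integral on the uniform grid; O(n) via an IIR filter.
    """
    if alpha == 0:
        return cumulative_trapezoid(values, dx=step, initial=0.0)
    d = float(np.exp(-alpha * step))
    b = np.array([step / 2.0, d * step / 2.0])
    a = np.array([1.0, -d])
    y = lfilter(b, a, values)
    # lfilter seeds the recursion with step/2*v[0] at n=0; the trapezoid
    # convolution starts at zero, so remove that term's propagated tail.
    v0 = values[0]
    if v0 != 0.0:
        y -= (step / 2.0) * v0 * d ** np.arange(values.size)
    return y


def _uniform_grid(t_end: float, step: float) -> np.ndarray:
    n = int(round(t_end / step))
    if abs(n * step - t_end) > 1e-6:
        n = int(np.ceil(t_end / step))
    return np.arange(n + 1) * step


def _frame_average_uniform(
    values: np.ndarray, step: float, schedule: FrameSchedule
) -> np.ndarray:
    """Trapezoid frame means of a curve sampled on the uniform grid."""
    out = np.empty(schedule.n_frames)
    cum = cumulative_trapezoid(values, dx=step, initial=0.0)
    for i, (t0, dur) in enumerate(zip(schedule.start, schedule.duration)):
        i0 = t0 / step
        i1 = (t0 + dur) / step
        j0, j1 = int(round(i0)), int(round(i1))
        if abs(i0 - j0) < 1e-6 and abs(i1 - j1) < 1e-6:
            out[i] = (cum[j1] - cum[j0]) / dur
        else:  # frame boundaries off-grid: fall back to interpolation
            tt = np.linspace(t0, t0 + dur, max(3, int(round(dur / step)) + 1))
            grid = np.arange(values.size) * step
            out[i] = np.trapezoid(np.interp(tt, grid, values), tt) / dur
    return out


def tac_2tcm(
    params: TwoTCMParams,
    aif: Callable[[np.ndarray], np.ndarray],
    schedule: FrameSchedule,
    step: float = DEFAULT_GRID_STEP,
) -> TimeActivityCurve:
    """Frame-averaged tissue curve of the irreversible 2TCM.

    ``aif`` is the continuous plasma input, evaluated on the fine grid
    from time zero to the last frame end; the model curve is computed by
    convolution there and averaged over each frame of ``schedule``.
    """
    t_end = float(schedule.end[-1])
    grid = _uniform_grid(t_end, step)
    cp = np.asarray(aif(grid), dtype=float)
    ct = tissue_curve_on_grid(params, cp, step)
    return TimeActivityCurve(schedule, _frame_average_uniform(ct, step, schedule))


def tissue_curve_on_grid(
    params: TwoTCMParams, cp: np.ndarray, step: float
) -> np.ndarray:
    """2TCM tissue concentration on the uniform grid carrying ``cp``."""
    alpha = params.k2 + params.k3
    if alpha == 0:
        tissue = params.k1 * cumulative_trapezoid(cp, dx=step, initial=0.0)
    else:
        conv = exp_conv(alpha, cp, step)
        tissue = (params.k1 * params.k2 / alpha) * conv + (
            params.k1 * params.k3 / alpha
        ) * cumulative_trapezoid(cp, dx=step, initial=0.0)
    return (1.0 - params.vb) * tissue + params.vb * cp


class PatlakPoints(NamedTuple):
    """Patlak coordinates: normalised time x (min), tissue ratio y, midtime."""

    x: np.ndarray
    y: np.ndarray
    midtime: np.ndarray


def patlak_transform(
    tissue: TimeActivityCurve, plasma: TimeActivityCurve
) -> PatlakPoints:
    """Patlak plot coordinates from frame-sampled tissue and plasma curves.

    ``x_i = (∫_0^{t_i} Cp dτ) / Cp(t_i)`` and ``y_i = C_T(t_i)/Cp(t_i)``
    at frame midtimes, the plasma integral by trapezoid over midpoints
    from time zero (plasma taken as zero at t = 0, the injection).
    Frames with non-positive plasma are excluded with a warning.
    """
    if not np.allclose(tissue.schedule.start, plasma.schedule.start) or not np.allclose(
        tissue.schedule.duration, plasma.schedule.duration
    ):
        raise ValueError("tissue and plasma curves must share a schedule")
    mid = tissue.midtimes
    cp = plasma.activity
    t_int = np.concatenate(([0.0], mid))
    cp_int = np.concatenate(([0.0], cp))
    integral = cumulative_trapezoid(cp_int, t_int)[...]
    usable = cp > 0
    if not np.all(usable):
        warnings.warn(
            f"excluding {int((~usable).sum())} Patlak point(s) with "
            "non-positive plasma activity",
            stacklevel=2,
        )
    x = integral[usable] / cp[usable]
    y = tissue.activity[usable] / cp[usable]
    return PatlakPoints(x, y, mid[usable])
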