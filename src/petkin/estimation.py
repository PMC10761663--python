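"""Nonlinear and linear least-squares estimators.

Three fits are provided:

* :func:`fit_aif` — recover the four Feng input-function parameters from
  frame-averaged samples in a (short) imaging window, typically the
  9-min cardiac window 39-48 min; the recovered parameters define the
  plasma input over the whole acquisition through the multi-bolus
  closed form.
* :func:`fit_2tcm` — recover (K1, k2, k3) of the irreversible 2TCM from
  tissue frames in the short imaging window with vb held fixed; the net
  influx rate Ki follows from the estimate.
* :func:`fit_patlak` — ordinary linear least squares on the Patlak
  plot; the slope is Ki.

The nonlinear fits use a bounded trust-region least-squares solver
(``scipy.optimize.least_squares`` with method ``trf``): classic
Levenberg-Marquardt does not support the box bounds the protocol
requires, and the trust-region reflective variant is the standard
bounded drop-in.  Fits are unweighted.  Defaults: initialisation at the
bound midpoints for the input function and at (0.1 ml/g/min, 0.1/min,
0.05/min) for the 2TCM; step/cost tolerances 1e-8; an iteration cap of
500.  Non-convergence is flagged on the result, never raised.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.optimize import least_squares

from .aif import (
    FENG_POPULATION_MEAN,
    FENG_POPULATION_SD,
    FengParams,
    FrameAverager,
    TimeActivityCurve,
)
from .kinetics import (
    DEFAULT_GRID_STEP,
    TwoTCMParams,
    _frame_average_uniform,
    _uniform_grid,
    exp_conv,
    net_influx_rate,
    patlak_transform,
)
from .protocol import FrameSchedule, InjectionSchedule

__all__ = [
    "ParamBounds",
    "FitResult",
    "AIFFitter",
    "TwoTCMFitter",
    "fit_aif",
    "fit_2tcm",
    "fit_patlak",
    "simulation_aif_bounds",
    "simulation_2tcm_bounds",
    "DEFAULT_2TCM_INIT",
]

_MAX_ITER = 500
_TOL = 1e-8


@dataclass(frozen=True)
class ParamBounds:
    """Elementwise box bounds, ``lower < upper`` per parameter."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        lower = np.asarray(self.lower, dtype=float)
        upper = np.asarray(self.upper, dtype=float)
        if lower.shape != upper.shape or np.any(lower >= upper):
            raise ValueError("require lower < upper elementwise")
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)

    @property
    def midpoint(self) -> np.ndarray:
        return 0.5 * (self.lower + self.upper)

    def clip(self, x: np.ndarray) -> np.ndarray:
        return np.clip(x, self.lower, self.upper)


@dataclass(frozen=True)
class FitResult:
    """Outcome of a least-squares fit.

    ``estimate`` is a :class:`~petkin.aif.FengParams` or
    :class:`~petkin.kinetics.TwoTCMParams`; ``ki`` (ml/g/min) is filled
    for 2TCM fits when defined.
    """

    estimate: object
    residual_ss: float
    converged: bool
    n_iter: int
    message: str = ""
    ki: float | None = None


def simulation_aif_bounds(
    mean: FengParams = FENG_POPULATION_MEAN,
    sd: tuple[float, float, float, float] = FENG_POPULATION_SD,
) -> ParamBounds:
    """Simulation-study bounds: [0.5 x min, 2 x max] of mean -/+ SD per axis."""
    m = mean.as_array()
    s = np.asarray(sd)
    return ParamBounds(0.5 * (m - s), 2.0 * (m + s))


#: Kinetic-parameter grid of the recovery simulation (K1 ml/g/min; k2, k3 1/min).
SIM_K1_VALUES = (0.05, 0.075, 0.1)
SIM_K2_VALUES = (0.05, 0.15, 0.25)
SIM_K3_VALUES = (0.02, 0.03, 0.04)


def simulation_2tcm_bounds() -> ParamBounds:
    """2TCM bounds by the same [0.5 x min, 2 x max] convention."""
    lo = 0.5 * np.array([SIM_K1_VALUES[0], SIM_K2_VALUES[0], SIM_K3_VALUES[0]])
    hi = 2.0 * np.array([SIM_K1_VALUES[-1], SIM_K2_VALUES[-1], SIM_K3_VALUES[-1]])
    return ParamBounds(lo, hi)


DEFAULT_2TCM_INIT = TwoTCMParams(0.1, 0.1, 0.05, 0.03)


class AIFFitter:
    """Reusable least-squares fitter for Feng parameters in a window.

    Precomputes the frame-quadrature times of the window schedule and
    the per-injection shifted-time masks so that repeated fits (Monte
    Carlo repetitions, CLI batch runs) only pay for exponentials.
    """

    def __init__(
        self,
        frames: FrameSchedule,
        injections: InjectionSchedule,
        bounds: ParamBounds | None = None,
        init: FengParams | None = None,
        step: float = 0.01,
    ) -> None:
        if frames.n_frames < 4:
            raise ValueError("need at least 4 frames to fit 4 Feng parameters")
        self.frames = frames
        self.injections = injections
        self.bounds = bounds if bounds is not None else simulation_aif_bounds()
        init_arr = init.as_array() if init is not None else self.bounds.midpoint
        self._init = self.bounds.clip(init_arr)
        self._averager = FrameAverager(frames, step=step)
        t = self._averager.times
        self._shifted: list[tuple[np.ndarray, np.ndarray, float]] = []
        for t_inj, frac in zip(injections.times, injections.fractions):
            mask = t >= t_inj
            self._shifted.append((mask, t[mask] - t_inj, float(frac)))
        self._cache_x: bytes | None = None
        self._cache: tuple | None = None

    def _exponentials(self, x: np.ndarray) -> tuple:
        key = x.tobytes()
        if key == self._cache_x:
            return self._cache
        mu1, mu2 = x[2], x[3]
        exps = [
            (mask, ts, frac, np.exp(-mu1 * ts), np.exp(-mu2 * ts))
            for mask, ts, frac in self._shifted
        ]
        self._cache_x = key
        self._cache = tuple(exps)
        return self._cache

    def model_frames(self, x: np.ndarray) -> np.ndarray:
        """Frame-averaged model curve for parameter vector (A1, A2, mu1, mu2)."""
        x = np.asarray(x, dtype=float)
        a1, a2 = x[0], x[1]
        values = np.zeros_like(self._averager.times)
        for mask, ts, frac, e1, e2 in self._exponentials(x):
            values[mask] += frac * (a1 * ts * e1 + a2 * (e2 - e1))
        return self._averager.average(values)

    def jacobian(self, x: np.ndarray) -> np.ndarray:
        """Analytic Jacobian of the frame model w.r.t. (A1, A2, mu1, mu2)."""
        x = np.asarray(x, dtype=float)
        a1, a2 = x[0], x[1]
        n = self._averager.times.size
        cols = np.zeros((4, n))
        for mask, ts, frac, e1, e2 in self._exponentials(x):
            cols[0][mask] += frac * ts * e1
            cols[1][mask] += frac * (e2 - e1)
            cols[2][mask] += frac * ts * e1 * (a2 - a1 * ts)
            cols[3][mask] += frac * (-a2 * ts * e2)
        return np.column_stack([self._averager.average(c) for c in cols])

    def fit(self, activity: np.ndarray) -> FitResult:
        """Fit the window samples; returns a flagged result, never raises."""
        y = np.asarray(activity, dtype=float)

        def residual(x: np.ndarray) -> np.ndarray:
            return self.model_frames(x) - y

        res = least_squares(
            residual,
            self._init,
            jac=self.jacobian,
            bounds=(self.bounds.lower, self.bounds.upper),
            method="trf",
            x_scale=np.maximum(np.abs(self._init), 1e-3),
            xtol=_TOL,
            ftol=_TOL,
            gtol=_TOL,
            max_nfev=_MAX_ITER * 5,
        )
        x = self.bounds.clip(res.x)
        # guard the mu1 > mu2 invariant (bounds normally keep it)
        if x[2] <= x[3]:
            x[2] = x[3] * (1 + 1e-9)
        return FitResult(
            estimate=FengParams.from_array(x),
            residual_ss=float(2.0 * res.cost),
            converged=bool(res.status > 0),
            n_iter=int(res.nfev),
            message=res.message,
        )


def fit_aif(
    samples: TimeActivityCurve,
    injections: InjectionSchedule,
    bounds: ParamBounds | None = None,
    init: FengParams | None = None,
) -> FitResult:
    """Fit Feng parameters to frame samples restricted to a window."""
    fitter = AIFFitter(samples.schedule, injections, bounds=bounds, init=init)
    return fitter.fit(samples.activity)


class TwoTCMFitter:
    """Reusable bounded NLS fitter for (K1, k2, k3) with fixed vb.

    The plasma input, its running integral and per-frame trapezoid
    quadrature weights are precomputed once for a given input function
    and set of fitting frames, so each repeated fit only evaluates the
    exponential convolution for trial (k2 + k3) values.  The Jacobian is
    analytic (the model is linear in K1 and smooth in k2, k3 through the
    convolution), which roughly halves the solver's function calls.
    """

    def __init__(
        self,
        frames: FrameSchedule,
        aif: Callable[[np.ndarray], np.ndarray],
        vb: float = 0.03,
        bounds: ParamBounds | None = None,
        init: TwoTCMParams | None = None,
        step: float = DEFAULT_GRID_STEP,
    ) -> None:
        if frames.n_frames < 3:
            raise ValueError("need at least 3 frames to fit 3 parameters")
        if not 0 <= vb < 1:
            raise ValueError("vb must lie in [0, 1)")
        self.frames = frames
        self.vb = float(vb)
        self.bounds = bounds if bounds is not None else simulation_2tcm_bounds()
        init_arr = (
            init.as_array() if init is not None else DEFAULT_2TCM_INIT.as_array()
        )
        self._init = self.bounds.clip(init_arr)
        self._step = step
        self._grid = _uniform_grid(float(frames.end[-1]), step)
        self._cp = np.asarray(aif(self._grid), dtype=float)
        self._t_cp = self._grid * self._cp
        self._cp_int = cumulative_trapezoid(self._cp, dx=step, initial=0.0)
        self._cp_frames = _frame_average_uniform(self._cp, step, frames)
        self._int_frames = _frame_average_uniform(self._cp_int, step, frames)
        # trapezoid quadrature weights restricted to grid points inside frames
        gidx, w, offsets = [], [], [0]
        for t0, dur in zip(frames.start, frames.duration):
            j0 = int(round(t0 / step))
            j1 = int(round((t0 + dur) / step))
            aligned = (
                abs(j0 * step - t0) < 1e-6 * max(1.0, t0)
                and abs(j1 * step - (t0 + dur)) < 1e-6 * (t0 + dur)
            )
            if not aligned:
                raise ValueError("frame boundaries must align with the grid step")
            n = j1 - j0 + 1
            wf = np.full(n, step / dur)
            wf[0] *= 0.5
            wf[-1] *= 0.5
            gidx.append(np.arange(j0, j1 + 1))
            w.append(wf)
            offsets.append(offsets[-1] + n)
        self._gidx = np.concatenate(gidx)
        self._w = np.concatenate(w)
        self._offsets = np.asarray(offsets[:-1])
        self._cache_x: bytes | None = None
        self._cache: tuple | None = None

    def _favg(self, values: np.ndarray) -> np.ndarray:
        """Frame means of a grid-sampled curve (precomputed quadrature)."""
        return np.add.reduceat(self._w * values[self._gidx], self._offsets)

    def _pieces(self, x: np.ndarray) -> tuple:
        """Frame-averaged convolution C(alpha) and its alpha-derivative."""
        key = x.tobytes()
        if key == self._cache_x:
            return self._cache
        alpha = x[1] + x[2]
        if alpha <= 0:
            conv_f = dconv_f = None
        else:
            conv = exp_conv(alpha, self._cp, self._step)
            conv_f = self._favg(conv)
            dconv = -(self._grid * conv - exp_conv(alpha, self._t_cp, self._step))
            dconv_f = self._favg(dconv)
        self._cache_x = key
        self._cache = (alpha, conv_f, dconv_f)
        return self._cache

    def model_frames(self, x: np.ndarray) -> np.ndarray:
        """Frame-averaged tissue curve for (K1, k2, k3) at fixed vb."""
        k1, k2, k3 = x
        alpha, conv_f, _ = self._pieces(np.asarray(x, dtype=float))
        if alpha <= 0:
            tissue = k1 * self._int_frames
        else:
            tissue = (k1 * k2 / alpha) * conv_f + (k1 * k3 / alpha) * self._int_frames
        return (1.0 - self.vb) * tissue + self.vb * self._cp_frames

    def jacobian(self, x: np.ndarray) -> np.ndarray:
        """Analytic Jacobian of the frame model w.r.t. (K1, k2, k3)."""
        k1, k2, k3 = x
        alpha, conv_f, dconv_f = self._pieces(np.asarray(x, dtype=float))
        one_m_vb = 1.0 - self.vb
        if alpha <= 0:
            d_k1 = one_m_vb * self._int_frames
            zero = np.zeros_like(d_k1)
            return np.column_stack([d_k1, zero, zero])
        d_k1 = one_m_vb * ((k2 / alpha) * conv_f + (k3 / alpha) * self._int_frames)
        d_k2 = (
            one_m_vb
            * k1
            * (
                (k3 / alpha**2) * conv_f
                + (k2 / alpha) * dconv_f
                - (k3 / alpha**2) * self._int_frames
            )
        )
        d_k3 = (
            one_m_vb
            * k1
            * (
                (-k2 / alpha**2) * conv_f
                + (k2 / alpha) * dconv_f
                + (k2 / alpha**2) * self._int_frames
            )
        )
        return np.column_stack([d_k1, d_k2, d_k3])

    def fit(self, activity: np.ndarray) -> FitResult:
        y = np.asarray(activity, dtype=float)

        def residual(x: np.ndarray) -> np.ndarray:
            return self.model_frames(x) - y

        res = least_squares(
            residual,
            self._init,
            jac=self.jacobian,
            bounds=(self.bounds.lower, self.bounds.upper),
            method="trf",
            x_scale=np.maximum(np.abs(self._init), 1e-3),
            xtol=_TOL,
            ftol=_TOL,
            gtol=_TOL,
            max_nfev=_MAX_ITER * 4,
        )
        x = self.bounds.clip(res.x)
        params = TwoTCMParams(float(x[0]), float(x[1]), float(x[2]), self.vb)
        alpha = params.k2 + params.k3
        ki = net_influx_rate(params) if alpha > 0 else None
        return FitResult(
            estimate=params,
            residual_ss=float(2.0 * res.cost),
            converged=bool(res.status > 0) and ki is not None,
            n_iter=int(res.nfev),
            message=res.message,
            ki=ki,
        )


def fit_2tcm(
    tac: TimeActivityCurve,
    aif: Callable[[np.ndarray], np.ndarray],
    vb: float = 0.03,
    bounds: ParamBounds | None = None,
    init: TwoTCMParams | None = None,
) -> FitResult:
    """Fit the irreversible 2TCM to tissue frames in the fitting windows."""
    fitter = TwoTCMFitter(tac.schedule, aif, vb=vb, bounds=bounds, init=init)
    return fitter.fit(tac.activity)


def fit_patlak(
    tissue: TimeActivityCurve,
    plasma: TimeActivityCurve,
    t_start: float = 15.0,
) -> tuple[float, float]:
    """Patlak slope (Ki, ml/g/min) and intercept by ordinary least squares.

    Uses Patlak points with frame midtime >= ``t_start`` (min), the
    pseudo-equilibrium portion of the plot; needs at least two points.
    """
    points = patlak_transform(tissue, plasma)
    late = points.midtime >= t_start
    if int(late.sum()) < 2:
        raise ValueError("need at least 2 Patlak points at/after t_start")
    coeffs = np.polynomial.polynomial.polyfit(points.x[late], points.y[late], 1)
    intercept, slope = float(coeffs[0]), float(coeffs[1])
    return slope, intercept
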