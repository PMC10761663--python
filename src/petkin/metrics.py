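"""Accuracy metrics for curve recovery and parameter estimation.

All curve metrics compare estimated curves against a single noiseless
truth curve on a shared time grid (by convention the 50 frame midtimes of
the canonical 60-min schedule, so errors are judged over the whole
acquisition regardless of which window was fitted).
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats

__all__ = [
    "auc_error",
    "auc_error_abs",
    "nrmse",
    "relative_error",
    "cv",
    "pearson_r",
]


def _as_reps(estimates: np.ndarray) -> np.ndarray:
    est = np.asarray(estimates, dtype=float)
    return est[None, :] if est.ndim == 1 else est


def _auc_errors_per_rep(estimates, truth, times) -> np.ndarray:
    est = _as_reps(estimates)
    truth = np.asarray(truth, dtype=float)
    times = np.asarray(times, dtype=float)
    auc_truth = np.trapezoid(truth, times)
    if auc_truth == 0:
        raise ValueError("truth curve has zero area under the curve")
    auc_est = np.trapezoid(est, times, axis=1)
    return (auc_est - auc_truth) / auc_truth * 100.0


def auc_error(estimates, truth, times) -> float:
    """Mean signed percentage AUC error over repetitions.

    ``estimates`` is ``(R, n)`` (or ``(n,)`` for a single repetition),
    ``truth`` and ``times`` are ``(n,)``; areas are trapezoid integrals
    on the shared grid.
    """
    return float(np.mean(_auc_errors_per_rep(estimates, truth, times)))


def auc_error_abs(estimates, truth, times) -> float:
    """Mean of the absolute per-repetition percentage AUC errors."""
    return float(np.mean(np.abs(_auc_errors_per_rep(estimates, truth, times))))


def nrmse(estimates, truth) -> float:
    """Normalised root-mean-square error averaged over repetitions.

    Per repetition: ``sqrt(mean(((est_i - truth_i)/truth_i)^2))`` over
    the grid points; points with exactly zero truth are excluded with a
    warning (the midtime grid of an injection-at-zero curve has none).
    """
    est = _as_reps(estimates)
    truth = np.asarray(truth, dtype=float)
    usable = truth != 0
    if not np.all(usable):
        warnings.warn(
            f"excluding {int((~usable).sum())} zero-truth point(s) from NRMSE",
            stacklevel=2,
        )
        est = est[:, usable]
        truth = truth[usable]
    rel_sq = ((est - truth) / truth) ** 2
    return float(np.mean(np.sqrt(np.mean(rel_sq, axis=1))))


def relative_error(estimate, truth) -> np.ndarray | float:
    """Percentage relative error ``100*(estimate - truth)/truth``."""
    truth_arr = np.asarray(truth, dtype=float)
    if np.any(truth_arr == 0):
        raise ValueError("relative error undefined for zero truth")
    out = 100.0 * (np.asarray(estimate, dtype=float) - truth_arr) / truth_arr
    return out if out.ndim else float(out)


def cv(estimates) -> float:
    """Coefficient of variation ``100*SD/mean`` (percent, ddof=1)."""
    est = np.asarray(estimates, dtype=float)
    mean = est.mean()
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    return float(100.0 * est.std(ddof=1) / mean)


def pearson_r(x, y) -> float:
    """Pearson product-moment correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two points for a correlation")
    return float(stats.pearsonr(x, y).statistic)
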