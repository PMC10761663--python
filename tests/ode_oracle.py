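"""Independent oracle for the tissue model: direct ODE integration.

Integrates the two-compartment system

    dCf/dt = K1*Cp(t) - (k2 + k3)*Cf,   dCb/dt = k3*Cf,

together with the running integral of the measured signal
``C_T = (1 - vb)(Cf + Cb) + vb*Cp`` so that exact frame averages come out
of the solver, with no convolution anywhere.  Integration is piecewise
between injection times (where the input has kinks).
"""

import numpy as np
from scipy.integrate import solve_ivp


def ode_frame_averages(params, aif, schedule, injections, rtol=1e-9, atol=1e-12):
    k1, k2, k3, vb = params.k1, params.k2, params.k3, params.vb

    def rhs(t, y):
        cp = float(aif(t))
        cf = y[0]
        ct = (1.0 - vb) * (cf + y[1]) + vb * cp
        return (k1 * cp - (k2 + k3) * cf, k3 * cf, ct)

    t_end = float(schedule.end[-1])
    boundaries = np.unique(np.concatenate([[0.0], schedule.start, schedule.end]))
    kinks = [t for t in injections.times if 0.0 < t < t_end]
    edges = np.unique(np.concatenate([[0.0, t_end], kinks]))
    cumulative = {0.0: 0.0}
    y = np.zeros(3)
    for a, b in zip(edges[:-1], edges[1:]):
        t_eval = boundaries[(boundaries > a) & (boundaries <= b)]
        sol = solve_ivp(
            rhs,
            (a, b),
            y,
            method="LSODA",
            t_eval=np.unique(np.append(t_eval, b)),
            rtol=rtol,
            atol=atol,
            max_step=0.25,
        )
        assert sol.success, sol.message
        for t, s in zip(sol.t, sol.y[2]):
            cumulative[float(t)] = s
        y = sol.y[:, -1]
    out = np.empty(schedule.n_frames)
    for i, (t0, dur) in enumerate(zip(schedule.start, schedule.duration)):
        out[i] = (cumulative[float(t0 + dur)] - cumulative[float(t0)]) / dur
    return out
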