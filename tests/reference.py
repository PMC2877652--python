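"""Independent fixed-step RK4 reference for the flare-cycle system.

Deliberately self-contained: the right-hand side is re-coded here in plain
scalar arithmetic from the model description (it does not call the
package), so agreement between this integrator and the package's adaptive
piecewise solver cross-checks both the equations and the integration.
"""

from __future__ import annotations

import numpy as np


def reference_rhs(y, c):
    """dy/dt for state y=(I,P,D,A) and a flat parameter dict c."""
    I, P, D, A = y
    inhib = 1.0 / (1.0 + (A / c["A_inf"]) ** 2)
    hill = D * D / (c["k_id"] * c["k_id"] + D * D)
    return (
        (c["s_i"] + c["s_id"] * hill) * inhib - c["k_ip"] * I * P,
        (c["k_pi"] * I + c["k_pp"] * P + c["k_pd"] * D) * inhib - c["mu_p"] * P,
        (c["k_dip"] * I * P + c["k_dp"] * P) * inhib - c["mu_d"] * D,
        c["s_a"] + c["k_ap"] * P + c["k_ad"] * D - c["mu_a"] * A,
    )


def rk4_piecewise(params_dict, breakpoints, interval_levels, y0, h=0.01):
    """Classic RK4 with fixed step h, restarted at each breakpoint.

    ``interval_levels`` is a list of (s_i, s_id, s_a) triples, one per
    interval between consecutive breakpoints. Returns (times, states) with
    one row per breakpoint (including the start).
    """
    y = tuple(float(v) for v in y0)
    times = [float(breakpoints[0])]
    states = [y]
    for (a, b), (s_i, s_id, s_a) in zip(
        zip(breakpoints[:-1], breakpoints[1:]), interval_levels
    ):
        c = dict(params_dict, s_i=s_i, s_id=s_id, s_a=s_a)
        n = int(round((b - a) / h))
        step = (b - a) / n
        for _ in range(n):
            k1 = reference_rhs(y, c)
            y1 = tuple(yi + 0.5 * step * ki for yi, ki in zip(y, k1))
            k2 = reference_rhs(y1, c)
            y2 = tuple(yi + 0.5 * step * ki for yi, ki in zip(y, k2))
            k3 = reference_rhs(y2, c)
            y3 = tuple(yi + step * ki for yi, ki in zip(y, k3))
            k4 = reference_rhs(y3, c)
            y = tuple(
                yi + step / 6.0 * (a1 + 2 * a2 + 2 * a3 + a4)
                for yi, a1, a2, a3, a4 in zip(y, k1, k2, k3, k4)
            )
        times.append(float(b))
        states.append(y)
    return np.array(times), np.array(states)


def max_rel_supnorm_error(ref_states: np.ndarray, test_states: np.ndarray) -> float:
    """Per-state sup-norm of the difference relative to the reference's
    sup-norm, maximised over the four states."""
    errs = []
    for j in range(4):
        scale = max(np.max(np.abs(ref_states[:, j])), 1e-12)
        errs.append(np.max(np.abs(ref_states[:, j] - test_states[:, j])) / scale)
    return float(max(errs))
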