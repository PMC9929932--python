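"""Independent brute-force oracles used by the tests.

These deliberately avoid scipy.optimize and the package's own vectorized
implementations: fits are coarse-to-fine grid searches over the model
parameters, and summary statistics are explicit Python loops.
"""

from __future__ import annotations

import math

import numpy as np


def grid_search_recovery(t, y, n_refine=3, n_pts=21):
    """Coarse-to-fine grid search for RFI(t) = floor + (plateau-floor)(1-e^{-kt}).

    Returns (floor, plateau, k, resolution) where resolution is the final
    per-parameter grid spacing (floor_step, plateau_step, k_step).
    """
    f_lo, f_hi = -0.2, 1.0
    p_lo, p_hi = 0.0, 1.5
    k_lo, k_hi = 1e-4, 2.0
    best = None
    for _ in range(n_refine):
        floors = np.linspace(f_lo, f_hi, n_pts)
        plateaus = np.linspace(p_lo, p_hi, n_pts)
        ks = np.geomspace(k_lo, k_hi, n_pts)
        best = None
        for fl in floors:
            for pl in plateaus:
                if pl < fl:
                    continue
                for k in ks:
                    model = fl + (pl - fl) * (1.0 - np.exp(-k * t))
                    sse = float(np.sum((model - y) ** 2))
                    if best is None or sse < best[0]:
                        best = (sse, fl, pl, k)
        _, fl, pl, k = best
        f_step = (f_hi - f_lo) / (n_pts - 1)
        p_step = (p_hi - p_lo) / (n_pts - 1)
        k_ratio = (k_hi / k_lo) ** (1.0 / (n_pts - 1))
        # zoom to +/- 2 steps: parameters are correlated, so the conditional
        # optimum can sit outside a one-step box around the coarse minimum
        f_lo, f_hi = fl - 2 * f_step, fl + 2 * f_step
        p_lo, p_hi = max(pl - 2 * p_step, 0.0), pl + 2 * p_step
        k_lo, k_hi = k / k_ratio**2, k * k_ratio**2
    return fl, pl, k, (f_step, p_step, k * (k_ratio - 1.0))


def grid_search_logistic(t, y, n_refine=3, n_pts=21):
    """Grid search for I(t) = A / (1 + e^{-r (t - t_mid)}).

    Returns (A, r, t_mid, (A_step, r_step, t_step))."""
    y_max = float(np.max(y))
    a_lo, a_hi = 0.5 * y_max, 1.5 * y_max
    r_lo, r_hi = 1e-4, 1.0
    m_lo, m_hi = float(t[0]), float(t[-1])
    for _ in range(n_refine):
        amps = np.linspace(a_lo, a_hi, n_pts)
        rates = np.geomspace(r_lo, r_hi, n_pts)
        mids = np.linspace(m_lo, m_hi, n_pts)
        best = None
        for a in amps:
            for r in rates:
                for m in mids:
                    with np.errstate(over="ignore"):  # exp overflow -> model 0, correct limit
                        model = a / (1.0 + np.exp(-r * (t - m)))
                    sse = float(np.sum((model - y) ** 2))
                    if best is None or sse < best[0]:
                        best = (sse, a, r, m)
        _, a, r, m = best
        a_step = (a_hi - a_lo) / (n_pts - 1)
        m_step = (m_hi - m_lo) / (n_pts - 1)
        r_ratio = (r_hi / r_lo) ** (1.0 / (n_pts - 1))
        a_lo, a_hi = a - 2 * a_step, a + 2 * a_step
        r_lo, r_hi = r / r_ratio**2, r * r_ratio**2
        m_lo, m_hi = m - 2 * m_step, m + 2 * m_step
    return a, r, m, (a_step, r * (r_ratio - 1.0), m_step)


def grid_search_decay(t, y, t0, n_refine=3, n_pts=41):
    """Grid search for I(t) = A e^{-r (t - t0)} (onset fixed at t0).

    Returns (A, r, (A_step, r_step))."""
    y_max = max(float(np.max(y)), 1e-12)
    a_lo, a_hi = 0.25 * y_max, 2.0 * y_max
    r_lo, r_hi = 1e-5, 1.0
    for _ in range(n_refine):
        amps = np.linspace(a_lo, a_hi, n_pts)
        rates = np.geomspace(r_lo, r_hi, n_pts)
        best = None
        for a in amps:
            for r in rates:
                model = a * np.exp(-r * (t - t0))
                sse = float(np.sum((model - y) ** 2))
                if best is None or sse < best[0]:
                    best = (sse, a, r)
        _, a, r = best
        a_step = (a_hi - a_lo) / (n_pts - 1)
        r_ratio = (r_hi / r_lo) ** (1.0 / (n_pts - 1))
        a_lo, a_hi = a - 2 * a_step, a + 2 * a_step
        r_lo, r_hi = r / r_ratio**2, r * r_ratio**2
    return a, r, (a_step, r * (r_ratio - 1.0))


def loop_rfi(roi, bg, n_pre):
    """RFI by explicit per-frame loop."""
    i_pre = sum(roi[:n_pre]) / n_pre
    i_bgpre = sum(bg[:n_pre]) / n_pre
    return [(roi[i] - bg[i]) / (i_pre - i_bgpre) for i in range(n_pre, len(roi))]


def loop_mean_velocity(times, xs, ys):
    """Mean of per-interval velocities (µm/min) by explicit loop."""
    vels = []
    for i in range(1, len(times)):
        d = math.hypot(xs[i] - xs[i - 1], ys[i] - ys[i - 1])
        vels.append(d / (times[i] - times[i - 1]))
    return sum(vels) / len(vels) * 60.0


def loop_msd(xs, ys, max_lag):
    """Time-averaged MSD per integer lag by explicit loop."""
    n = len(xs)
    out = {}
    for k in range(1, max_lag + 1):
        acc = 0.0
        for i in range(n - k):
            acc += (xs[i + k] - xs[i]) ** 2 + (ys[i + k] - ys[i]) ** 2
        out[k] = acc / (n - k)
    return out


def loop_max_project(stack):
    """Per-pixel maximum over z by explicit triple loop."""
    nz, nr, nc = stack.shape
    out = np.empty((nr, nc))
    for r in range(nr):
        for c in range(nc):
            m = stack[0, r, c]
            for z in range(1, nz):
                if stack[z, r, c] > m:
                    m = stack[z, r, c]
            out[r, c] = m
    return out


def loop_path_length(xs, ys):
    acc = 0.0
    for i in range(1, len(xs)):
        acc += math.hypot(xs[i] - xs[i - 1], ys[i] - ys[i - 1])
    return acc
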