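"""Independent reference implementations used only to check ventwave.

These deliberately use brute-force routes (fine-step explicit Euler,
nested-loop sums of squares, textbook formulas) so they share no code with
the package paths they validate.
"""

from __future__ import annotations

import numpy as np


def euler_simulate(settings, lung, duration, dt=1e-5):
    """Fine-step explicit-Euler integration of the circuit-lung model.

    The ideal relief valve is realised by clamping circuit pressure to the
    phase's set pressure after every step.
    """
    C, R, Cc = lung.C_rs, lung.R_aw, settings.circuit_compliance
    F = settings.bias_flow * 1000.0 / 60.0
    Ti, T = settings.Ti, settings.breath_period
    n = int(round(duration / dt))
    t = np.arange(n) * dt
    P = settings.set_PEEP
    v = 0.0
    out_p = np.empty(n)
    out_q = np.empty(n)
    out_v = np.empty(n)
    for i in range(n):
        tl = t[i] % T
        pset = settings.set_PIP if tl < Ti else settings.set_PEEP
        q = (P - settings.set_PEEP - v / C) / R
        out_p[i], out_q[i], out_v[i] = P, q, v
        P += dt * (F - q) / Cc
        v += dt * q
        if P > pset:
            P = pset
    return {"time": t, "pressure": out_p, "flow_mls": out_q, "volume": out_v}


def breath_vt_and_tpip(time, pressure, volume, breath_index, period, Ti):
    """V_T and time-to-peak-pressure of one breath on any sampled trace."""
    lo = breath_index * period
    m = (time >= lo - 1e-12) & (time < lo + period - 1e-12)
    tl = time[m] - lo
    p = pressure[m]
    v = volume[m]
    insp = tl < Ti
    vt = float(v[insp].max() - v[0])
    t_pip = float(tl[np.argmax(p)])
    return vt, t_pip


def welch_by_hand(a, b):
    """Textbook Welch statistic and Satterthwaite df."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
    t = (a.mean() - b.mean()) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va ** 2 / (a.size - 1) + vb ** 2 / (b.size - 1))
    return t, df


def split_plot_ss_by_hand(y):
    """Nested-loop sums of squares for a balanced group x subject x time array.

    ``y`` has shape (a, n, b). Returns the five SS terms as a dict.
    """
    a, n, b = y.shape
    grand = y.mean()
    ss_group = ss_subj = ss_time = ss_gt = ss_err = 0.0
    for g in range(a):
        m_g = y[g].mean()
        ss_group += n * b * (m_g - grand) ** 2
        for s in range(n):
            m_gs = y[g, s].mean()
            ss_subj += b * (m_gs - m_g) ** 2
    for t in range(b):
        m_t = y[:, :, t].mean()
        ss_time += a * n * (m_t - grand) ** 2
    for g in range(a):
        m_g = y[g].mean()
        for t in range(b):
            m_gt = y[g, :, t].mean()
            m_t = y[:, :, t].mean()
            ss_gt += n * (m_gt - m_g - m_t + grand) ** 2
    for g in range(a):
        m_g = y[g].mean()
        for s in range(n):
            for t in range(b):
                m_gs = y[g, s].mean()
                m_gt = y[g, :, t].mean()
                ss_err += (y[g, s, t] - m_gs - m_gt + m_g) ** 2
    return {"group": ss_group, "subject": ss_subj, "time": ss_time,
            "group_x_time": ss_gt, "error": ss_err}


def central_difference_slope_max(x, dt, phase_slice):
    """Max first derivative by plain central differences on the raw signal."""
    seg = x[phase_slice]
    d = np.gradient(seg, dt)
    return float(d.max())
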