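"""Continuous bias-flow ventilator / patient-circuit / single-compartment lung simulator.

Model
-----
Two pressure nodes connected by the airway resistance:

* circuit node (compliance ``C_circ``): charged by the constant bias flow F,
  discharged into the lung, and capped by an ideal relief valve at the
  phase's set pressure (set PIP during inspiration, set PEEP during
  expiration)::

      C_circ * dP_circ/dt = F - Q_lung - Q_valve,   P_circ <= P_set

* lung node (compliance ``C_rs``)::

      dV/dt = Q_lung = (P_circ - PEEP - V/C_rs) / R_aw

Airway-opening pressure equals circuit pressure; flow is measured at the
airway opening (``Q_lung``). Phase switching is clock-driven (Ti, rate) --
the modelled subjects are apnoeic and intubated, so there is no
spontaneous-effort trigger.

Within each valve state the system is linear, so each breath is integrated
exactly: the valve-closed solution is a secular-plus-exponential closed form
(the system matrix has eigenvalues 0 and -1/tau_a), the valve-open lung is a
single exponential, and the valve-opening instant is located by root-finding
on the closed form. Expiration pins the circuit at PEEP (ideal valve) and the
lung empties with time constant tau = R_aw * C_rs.
"""

from __future__ import annotations

import math
from dataclasses import asdict

import numpy as np
from scipy.optimize import brentq

from .core import LungModelParams, VentilatorSettings, WaveformRecording

__all__ = ["simulate_ventilation"]


class _ModeA:
    """Valve-closed dynamics: circuit charging while the lung fills.

    State expressed relative to set PEEP: x = P_circ - PEEP, v = lung volume.
    With q = x - v/C (pressure drop across R_aw),

        q(t)  = q_inf + (q0 - q_inf) * exp(-t/tau_a)
        v(t)  = v0 + [q_inf*t + tau_a*(q0 - q_inf)*(1 - exp(-t/tau_a))] / R
        x(t)  = q(t) + v(t)/C

    where tau_a = R*Ceq, Ceq = (1/C + 1/C_circ)^-1 and
    q_inf = F*R*C/(C + C_circ) (quasi-steady flow split between the two
    compliances).
    """

    def __init__(self, F: float, C: float, Cc: float, R: float,
                 x0: float, v0: float) -> None:
        self.C, self.R, self.v0 = C, R, v0
        ceq = 1.0 / (1.0 / C + 1.0 / Cc)
        self.tau = R * ceq
        self.q0 = x0 - v0 / C
        self.qinf = F * R * C / (C + Cc)

    def q(self, t):
        return self.qinf + (self.q0 - self.qinf) * np.exp(-t / self.tau)

    def v(self, t):
        decay = 1.0 - np.exp(-t / self.tau)
        return self.v0 + (self.qinf * t + self.tau * (self.q0 - self.qinf) * decay) / self.R

    def x(self, t):
        return self.q(t) + self.v(t) / self.C

    def flow(self, t):
        return self.q(t) / self.R


def _simulate_segment(settings: VentilatorSettings, lung: LungModelParams,
                      t_grid: np.ndarray, t0: float, v_init: float,
                      n_breaths: int):
    """Integrate ``n_breaths`` breaths starting at absolute time ``t0``.

    Returns (pressure, flow_mls, volume) sampled on ``t_grid`` (absolute
    times), the end-expiratory volume after the last breath, and per-breath
    valve-opening times (absolute s; NaN when set PIP was not reached).
    """
    C, R = lung.C_rs, lung.R_aw
    Cc = settings.circuit_compliance
    F = settings.bias_flow_mls
    dpip = settings.set_PIP - settings.set_PEEP
    Ti, T = settings.Ti, settings.breath_period
    tau_b = R * C

    pressure = np.empty_like(t_grid)
    flow = np.empty_like(t_grid)
    volume = np.empty_like(t_grid)
    open_times = np.full(n_breaths, np.nan)

    v0 = v_init
    for b in range(n_breaths):
        tb = t0 + b * T
        sel = (t_grid >= tb - 1e-12) & (t_grid < tb + T - 1e-12)
        tl = t_grid[sel] - tb  # local time within the breath

        mode_a = _ModeA(F, C, Cc, R, 0.0, v0)
        # locate valve opening within inspiration
        if mode_a.x(Ti) >= dpip:
            if mode_a.x(0.0) >= dpip:
                t_open = 0.0
            else:
                t_open = brentq(lambda t: mode_a.x(t) - dpip, 0.0, Ti,
                                xtol=1e-13, rtol=1e-15)
            open_times[b] = tb + t_open
        else:
            t_open = Ti  # valve never opens this breath

        v_open = float(mode_a.v(t_open))
        # valve-open lung filling toward C*dpip with time constant tau_b
        v_Ti = dpip * C + (v_open - dpip * C) * math.exp(-(Ti - t_open) / tau_b)

        ia = sel & (t_grid - tb < t_open)
        ib = sel & (t_grid - tb >= t_open) & (t_grid - tb < Ti - 1e-12)
        ie = sel & (t_grid - tb >= Ti - 1e-12)

        ta = t_grid[ia] - tb
        volume[ia] = mode_a.v(ta)
        flow[ia] = mode_a.flow(ta)
        pressure[ia] = settings.set_PEEP + mode_a.x(ta)

        tb_loc = t_grid[ib] - tb - t_open
        vb = dpip * C + (v_open - dpip * C) * np.exp(-tb_loc / tau_b)
        volume[ib] = vb
        flow[ib] = (dpip - vb / C) / R
        pressure[ib] = settings.set_PIP

        te = t_grid[ie] - tb - Ti
        ve = v_Ti * np.exp(-te / tau_b)
        volume[ie] = ve
        flow[ie] = -ve / (R * C)
        pressure[ie] = settings.set_PEEP

        v0 = v_Ti * math.exp(-(T - Ti) / tau_b)

    return pressure, flow, volume, v0, open_times


def simulate_ventilation(settings: VentilatorSettings, lung: LungModelParams,
                         duration: float, sample_rate: float = 200.0,
                         seed: int | None = None,
                         noise_sd: tuple[float, float, float] = (0.0, 0.0, 0.0),
                         subject_id: str = "sim", group_label: str = "",
                         v_init: float = 0.0) -> WaveformRecording:
    """Simulate pressure-limited continuous bias-flow ventilation.

    Parameters
    ----------
    settings, lung
        Ventilator settings and single-compartment lung parameters.
    duration
        Total simulated time (s); must cover at least one breath period.
    sample_rate
        Output grid rate (Hz); must resolve the inspiration with >= 20
        samples.
    seed
        Seed for the sensor-noise generator. Mandatory when any
        ``noise_sd`` entry is nonzero.
    noise_sd
        Additive Gaussian sensor noise SD per channel
        (pressure cmH2O, flow L/min, volume mL). Default noise-free.
    v_init
        Initial lung volume above the end-expiratory equilibrium (mL).

    Returns
    -------
    WaveformRecording
        Airway pressure (cmH2O), flow (L/min, + = inspiratory) and volume
        (mL above end-expiratory volume) on a uniform grid. ``meta`` carries
        the ground-truth settings, lung parameters, seed, and per-breath
        valve-opening times. If ``lung.surfactant_time`` is set, the
        compliance step is applied at the first inspiratory onset at or
        after that time (event recorded in ``meta['events']``).
    """
    if not (math.isfinite(duration) and duration > 0):
        raise ValueError("duration must be finite and positive")
    T = settings.breath_period
    if duration < T:
        raise ValueError(
            f"duration {duration} s is shorter than one breath period {T} s")
    if sample_rate * settings.Ti < 20:
        raise ValueError(
            "sample_rate too low to resolve the inspiration "
            f"(needs >= {20 / settings.Ti:.0f} Hz for Ti = {settings.Ti} s)")
    if any(s > 0 for s in noise_sd) and seed is None:
        raise ValueError("seed is mandatory when sensor noise is enabled")

    n_breaths = int(math.floor(duration / T + 1e-9))
    total_t = n_breaths * T
    n_samp = int(round(total_t * sample_rate))
    t_grid = np.arange(n_samp) / sample_rate

    events: list[dict] = []
    if lung.surfactant_time is not None and lung.surfactant_time < total_t:
        b_step = min(int(math.ceil(lung.surfactant_time / T - 1e-9)), n_breaths)
    else:
        b_step = n_breaths

    p1, f1, v1, v_end, ot1 = _simulate_segment(
        settings, lung, t_grid, 0.0, v_init, b_step)
    pressure, flow_mls, volume = p1, f1, v1
    open_times = ot1
    if b_step < n_breaths:
        lung2 = lung.after_surfactant()
        events.append({"t": b_step * T, "event": "surfactant",
                       "C_rs_before": lung.C_rs, "C_rs_after": lung2.C_rs})
        p2, f2, v2, v_end, ot2 = _simulate_segment(
            settings, lung2, t_grid, b_step * T, v_end, n_breaths - b_step)
        keep = t_grid >= b_step * T - 1e-12
        pressure = np.where(keep, p2, p1)
        flow_mls = np.where(keep, f2, f1)
        volume = np.where(keep, v2, v1)
        open_times = np.concatenate([ot1, ot2])

    flow_lpm = flow_mls * 60.0 / 1000.0
    if any(s > 0 for s in noise_sd):
        rng = np.random.default_rng(seed)
        pressure = pressure + rng.normal(0.0, noise_sd[0], n_samp)
        flow_lpm = flow_lpm + rng.normal(0.0, noise_sd[1], n_samp)
        volume = volume + rng.normal(0.0, noise_sd[2], n_samp)

    return WaveformRecording(
        time=t_grid, pressure=pressure, flow=flow_lpm, volume=volume,
        sample_rate=sample_rate, subject_id=subject_id, weight=lung.weight,
        group_label=group_label,
        meta={
            "settings": asdict(settings), "lung": asdict(lung),
            "seed": seed, "noise_sd": tuple(noise_sd),
            "valve_open_times": open_times.tolist(),
            "end_expiratory_volume": float(v_end),
            "events": events,
        },
    )
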