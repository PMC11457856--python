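"""Closed-loop ventilation protocol: V_T-directed PIP, PaCO2-directed rate,
inspiratory-time titration, and first-order CO2 kinetics.

The controller mirrors a lung-protective neonatal strategy: inspiratory time
starts at 0.5 s and is shortened when the terminal zero-flow plateau exceeds
20% of Ti; PIP is stepped +/-1 cmH2O toward a tidal-volume target (capped at
PIP_max); respiratory rate is stepped +/-5 /min to hold PaCO2 inside a target
band while Ti stays fixed; surfactant is modelled as a step increase in
compliance at a scheduled time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict, replace

import numpy as np

from .core import GasState, LungModelParams, VentilatorSettings, WaveformRecording
from .simulate import simulate_ventilation

__all__ = ["ProtocolConfig", "run_protocol", "titrate_Ti", "update_gas_state"]


def update_gas_state(state: GasState, V_T: float, rate: float,
                     dead_space: float, dt: float, k_CO2: float,
                     tau: float, apnoeic_ceiling: float = 130.0) -> GasState:
    """Advance PaCO2 by ``dt`` seconds of ventilation at (V_T, rate).

    Alveolar minute ventilation is ``rate * max(V_T - dead_space, 0)``
    (mL/min). PaCO2 relaxes first-order (time constant ``tau``) toward the
    equilibrium ``k_CO2 / V_A``; with no alveolar ventilation it relaxes
    toward ``apnoeic_ceiling`` instead. Saturating by construction: no
    error states.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    v_a = rate * max(V_T - dead_space, 0.0)
    target = k_CO2 / v_a if v_a > 0 else apnoeic_ceiling
    paco2 = target + (state.PaCO2 - target) * math.exp(-dt / tau)
    return GasState(PaCO2=paco2, alveolar_minute_ventilation=v_a)


def titrate_Ti(recording: WaveformRecording, breaths,
               threshold_fraction: float = 0.20,
               flow_tolerance: float = 0.1,
               margin: float = 0.02) -> np.ndarray:
    """Per-breath inspiratory-time titration by the terminal zero-flow rule.

    For each breath, the terminal span of the inspiration during which
    ``|flow| < flow_tolerance`` (L/min) is measured. If that span exceeds
    ``threshold_fraction * Ti`` (strict inequality), the returned Ti is
    shortened to the time at which flow fell below tolerance plus
    ``margin`` seconds; otherwise the observed Ti is returned unchanged.

    Parameters
    ----------
    breaths
        Sequence of :class:`~ventwave.core.BreathSegment`.

    Returns
    -------
    numpy.ndarray
        Recommended Ti (s), one entry per breath.
    """
    out = np.empty(len(breaths))
    for k, seg in enumerate(breaths):
        flow = recording.flow[seg.insp_onset_idx:seg.insp_end_idx + 1]
        t = recording.time[seg.insp_onset_idx:seg.insp_end_idx + 1]
        ti = seg.Ti
        if not np.any(np.abs(flow) >= flow_tolerance):
            raise ValueError(f"breath {k} has no inspiratory phase "
                             "(flow never exceeds tolerance)")
        above = np.nonzero(np.abs(flow) >= flow_tolerance)[0]
        last_above = above[-1]
        if last_above == flow.size - 1:
            out[k] = ti  # flow active through end-inspiration
            continue
        t_fall = t[last_above + 1] - t[0]  # first sub-tolerance sample
        span = ti - t_fall
        out[k] = (t_fall + margin) if span > threshold_fraction * ti else ti
    return out


@dataclass(frozen=True)
class ProtocolConfig:
    """Closed-loop targets and controller knobs."""

    target_VT_mlkg: float = 7.0
    paco2_band: tuple[float, float] = (45.0, 55.0)
    adjustment_interval: float = 30.0  # s between controller checks
    duration: float = 300.0  # s total
    sample_rate: float = 200.0
    noise_sd: tuple[float, float, float] = (0.0, 0.0, 0.0)
    pip_step: float = 1.0  # cmH2O per adjustment
    rate_step: float = 5.0  # breaths/min per adjustment
    vt_tolerance_mlkg: float = 0.5  # deadband around the V_T target
    rate_bounds: tuple[float, float] = (20.0, 100.0)
    initial_PaCO2: float = 55.0
    apnoeic_ceiling: float = 130.0

    def __post_init__(self) -> None:
        if self.adjustment_interval <= 0 or self.duration <= 0:
            raise ValueError("interval and duration must be positive")
        if self.paco2_band[0] >= self.paco2_band[1]:
            raise ValueError("paco2_band must be (low, high) with low < high")


def _measured_vt(rec: WaveformRecording, settings: VentilatorSettings) -> float:
    """Mean tidal volume of the last up-to-3 breaths, read off the clock grid."""
    T = settings.breath_period
    t_local = rec.time - rec.time[0]
    n_breaths = max(int((t_local[-1] + 1e-9) // T) + 1, 1)
    vts = []
    for b in range(max(0, n_breaths - 3), n_breaths):
        m = (t_local >= b * T - 1e-9) & (t_local < b * T + settings.Ti)
        if m.sum() < 2:
            continue
        v = rec.volume[m]
        vts.append(float(v.max() - v[0]))
    return float(np.mean(vts)) if vts else 0.0


def run_protocol(settings: VentilatorSettings, lung: LungModelParams,
                 protocol: ProtocolConfig, seed: int,
                 subject_id: str = "sim", group_label: str = ""):
    """Run a closed-loop ventilation epoch.

    Every ``adjustment_interval`` the controller steps PIP by ±1 cmH2O toward
    the V_T target (never above ``settings.PIP_max``) and the rate by ±5 /min
    toward the PaCO2 band (Ti fixed). The surfactant compliance step fires at
    ``lung.surfactant_time``. Unreachable targets are flagged in the log,
    never raised.

    Returns
    -------
    (WaveformRecording, list[dict])
        The concatenated recording and the event log (one dict per
        adjustment/event with timestamp).
    """
    rng = np.random.default_rng(seed)
    log: list[dict] = []
    chunks: list[WaveformRecording] = []
    gas = GasState(PaCO2=protocol.initial_PaCO2)
    cur = settings
    cur_lung = lung
    t_offset = 0.0
    v_carry = 0.0

    while t_offset < protocol.duration - 1e-9:
        chunk_t = min(protocol.adjustment_interval, protocol.duration - t_offset)
        if chunk_t < cur.breath_period:
            break
        # surfactant step scheduled inside this chunk -> pass relative time
        surf_rel = None
        if cur_lung.surfactant_time is not None:
            if t_offset <= cur_lung.surfactant_time < t_offset + chunk_t:
                surf_rel = cur_lung.surfactant_time - t_offset
        sim_lung = replace(cur_lung, surfactant_time=surf_rel)
        chunk_seed = int(rng.integers(2 ** 31))
        rec = simulate_ventilation(cur, sim_lung, chunk_t,
                                   sample_rate=protocol.sample_rate,
                                   seed=chunk_seed, noise_sd=protocol.noise_sd,
                                   subject_id=subject_id,
                                   group_label=group_label, v_init=v_carry)
        for ev in rec.meta["events"]:
            log.append({"t": t_offset + ev["t"], "param": "C_rs",
                        "event": "surfactant", "from": ev["C_rs_before"],
                        "to": ev["C_rs_after"], "reason": "scheduled surfactant"})
            cur_lung = cur_lung.after_surfactant()
        v_carry = rec.meta["end_expiratory_volume"]
        chunk_len = rec.time.size / protocol.sample_rate
        rec.time = rec.time + t_offset
        chunks.append(rec)
        t_offset += chunk_len

        vt = _measured_vt(rec, cur)
        gas = update_gas_state(gas, vt, cur.rate, cur_lung.dead_space,
                               chunk_len, cur_lung.CO2_production_constant,
                               cur_lung.CO2_time_constant,
                               protocol.apnoeic_ceiling)
        target_vt = protocol.target_VT_mlkg * cur_lung.weight
        tol = protocol.vt_tolerance_mlkg * cur_lung.weight
        new_pip = cur.set_PIP
        if vt < target_vt - tol:
            if cur.set_PIP + protocol.pip_step <= cur.PIP_max:
                new_pip = cur.set_PIP + protocol.pip_step
            else:
                log.append({"t": t_offset, "param": "PIP", "event": "flag",
                            "reason": "V_T target unreachable at PIP_max",
                            "measured_VT": vt, "target_VT": target_vt})
        elif vt > target_vt + tol and cur.set_PIP - protocol.pip_step > cur.set_PEEP:
            new_pip = cur.set_PIP - protocol.pip_step
        if new_pip != cur.set_PIP:
            log.append({"t": t_offset, "param": "PIP", "event": "adjust",
                        "from": cur.set_PIP, "to": new_pip,
                        "reason": f"measured V_T {vt:.2f} mL vs target {target_vt:.2f} mL"})
            cur = replace(cur, set_PIP=new_pip)

        lo, hi = protocol.paco2_band
        new_rate = cur.rate
        if gas.PaCO2 > hi:
            if cur.rate + protocol.rate_step <= protocol.rate_bounds[1]:
                new_rate = cur.rate + protocol.rate_step
            else:
                log.append({"t": t_offset, "param": "rate", "event": "flag",
                            "reason": "PaCO2 above band at maximum rate",
                            "PaCO2": gas.PaCO2})
        elif gas.PaCO2 < lo and cur.rate - protocol.rate_step >= protocol.rate_bounds[0]:
            new_rate = cur.rate - protocol.rate_step
        if new_rate != cur.rate:
            if not (0 < cur.Ti < 60.0 / new_rate):
                log.append({"t": t_offset, "param": "rate", "event": "flag",
                            "reason": "rate change would violate Ti < 60/rate; kept",
                            "PaCO2": gas.PaCO2})
            else:
                log.append({"t": t_offset, "param": "rate", "event": "adjust",
                            "from": cur.rate, "to": new_rate,
                            "reason": f"PaCO2 {gas.PaCO2:.1f} mmHg vs band {lo}-{hi}"})
                cur = replace(cur, rate=new_rate)

    time = np.concatenate([c.time for c in chunks])
    rec_all = WaveformRecording(
        time=time,
        pressure=np.concatenate([c.pressure for c in chunks]),
        flow=np.concatenate([c.flow for c in chunks]),
        volume=np.concatenate([c.volume for c in chunks]),
        sample_rate=protocol.sample_rate, subject_id=subject_id,
        weight=lung.weight, group_label=group_label,
        meta={"protocol": asdict(protocol), "seed": seed, "log": log,
              "final_settings": asdict(cur), "final_PaCO2": gas.PaCO2,
              "settings": asdict(settings), "lung": asdict(lung)},
    )
    return rec_all, log
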