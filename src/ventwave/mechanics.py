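"""Per-breath lung mechanics, energetics, ventilatory efficiency, and static
PV-curve analysis.

Energetics conventions: pressures in cmH2O and volumes in mL give energies in
cmH2O*mL, converted to joules with 1 cmH2O*mL = 98.0665e-6 J. The tidal
mechanical power integrates the inspiratory pressure-volume loop referenced
to the measured PEEP (isolating tidal energy from the PEEP baseline); an
atmosphere-referenced variant is available behind a flag. The respiratory-
system mechanical energy per breath uses the elastic closed form
0.5*dP*V_T + PEEP*V_T.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import CMH2O_ML_TO_J, BreathSegment, WaveformRecording

__all__ = [
    "BreathMechanics", "FitResult", "StaticPVCurve", "PVCurveResult",
    "VEIResult", "breath_mechanics", "fit_equation_of_motion",
    "energy_per_breath", "mp_tidal", "me_rs", "vei", "analyze_pv_curve",
    "calibrate_delta_VL", "mechanics_table",
]


@dataclass(frozen=True)
class BreathMechanics:
    PIP: float  # cmH2O
    PEEP_measured: float  # cmH2O
    dP: float  # cmH2O
    V_T: float  # mL
    V_T_mlkg: float
    C_dyn: float  # mL/cmH2O
    C_dyn_mlkg: float  # mL/cmH2O/kg
    Flow_peak: float  # L/min
    degenerate: bool = False  # zero-volume breath flagged, not raised


@dataclass(frozen=True)
class FitResult:
    C_fit: float  # mL/cmH2O
    R_fit: float  # cmH2O*s/mL
    P0: float  # cmH2O
    rms_residual: float  # cmH2O


@dataclass(frozen=True)
class VEIResult:
    VEI: float
    dP: float
    rate: float
    PaCO2: float
    K: float = 3800.0


@dataclass(frozen=True)
class StaticPVCurve:
    """Inflation-limb static pressure-volume maneuver (atmosphere upward)."""

    pressure_steps: np.ndarray  # cmH2O
    volumes: np.ndarray  # mL

    def __post_init__(self) -> None:
        object.__setattr__(self, "pressure_steps",
                           np.asarray(self.pressure_steps, dtype=float))
        object.__setattr__(self, "volumes",
                           np.asarray(self.volumes, dtype=float))
        if self.pressure_steps.size != self.volumes.size:
            raise ValueError("pressure and volume arrays must match")
        if self.pressure_steps.size < 2:
            raise ValueError("PV curve needs at least 2 points")
        if np.any(np.diff(self.pressure_steps) <= 0):
            raise ValueError("pressure steps must be strictly increasing")


@dataclass(frozen=True)
class PVCurveResult:
    TLC_mlkg: float  # volume at 35 cmH2O per kg
    chord_compliance_mlkg: dict  # (P_lo, P_hi) -> mL/cmH2O/kg
    extrapolated: bool


def breath_mechanics(recording: WaveformRecording, segment: BreathSegment,
                     weight: float | None = None) -> BreathMechanics:
    """Ratio-based per-breath mechanics.

    PIP is the breath's pressure maximum; PEEP is the pressure at
    inspiratory onset (robust to intrinsic PEEP); V_T is the volume change
    over the inspiration; C_dyn = V_T / dP. A zero-volume breath is flagged
    ``degenerate`` (C_dyn = 0) rather than raised; dP <= 0 raises.
    """
    w = recording.weight if weight is None else weight
    sl = slice(segment.insp_onset_idx, segment.exp_end_idx)
    p = recording.pressure[sl]
    pip = float(p.max())
    peep = float(recording.pressure[segment.insp_onset_idx])
    dp = pip - peep
    if dp <= 0:
        raise ValueError(f"non-positive driving pressure ({dp:.3f} cmH2O)")
    v_t = float(recording.volume[segment.insp_end_idx]
                - recording.volume[segment.insp_onset_idx])
    insp = slice(segment.insp_onset_idx, segment.insp_end_idx + 1)
    flow_peak = float(recording.flow[insp].max())
    degenerate = v_t <= 0
    v_t = max(v_t, 0.0)
    c_dyn = v_t / dp
    return BreathMechanics(PIP=pip, PEEP_measured=peep, dP=dp, V_T=v_t,
                           V_T_mlkg=v_t / w, C_dyn=c_dyn,
                           C_dyn_mlkg=c_dyn / w, Flow_peak=flow_peak,
                           degenerate=degenerate)


def fit_equation_of_motion(recording: WaveformRecording,
                           segment: BreathSegment) -> FitResult:
    """Least-squares single-compartment fit P_ao = V/C + R*Q + P0.

    Fitted over the whole breath (both phases). Requires >= 20 samples and a
    full-rank design; a design whose volume and flow columns are linearly
    dependent (to within 1e-10 relative singular value) raises.
    """
    sl = slice(segment.insp_onset_idx, segment.exp_end_idx + 1)
    p = recording.pressure[sl]
    v = recording.volume[sl]
    q = recording.flow[sl] * 1000.0 / 60.0  # mL/s
    if p.size < 20:
        raise ValueError("breath too short to fit (needs >= 20 samples)")
    a = np.column_stack([v, q, np.ones_like(v)])
    sv = np.linalg.svd(a, compute_uv=False)
    if sv[-1] < 1e-10 * sv[0]:
        raise ValueError("rank-deficient design: volume and flow are "
                         "linearly dependent over this breath")
    coef, *_ = np.linalg.lstsq(a, p, rcond=None)
    inv_c, r_fit, p0 = coef
    if inv_c <= 0:
        raise ValueError("non-physical fit: non-positive elastance")
    rms = float(np.sqrt(np.mean((a @ coef - p) ** 2)))
    return FitResult(C_fit=float(1.0 / inv_c), R_fit=float(r_fit),
                     P0=float(p0), rms_residual=rms)


def energy_per_breath(recording: WaveformRecording, segment: BreathSegment,
                      reference: str = "peep") -> float:
    """Inspiratory tidal energy E = integral (P_ao - P_ref) dV, in joules.

    Trapezoidal over the inspiration. ``reference="peep"`` (default)
    subtracts the pressure at inspiratory onset, isolating tidal energy;
    ``reference="atmosphere"`` integrates the absolute airway pressure. A
    negative result signals phase mislabelling and raises.
    """
    insp = slice(segment.insp_onset_idx, segment.insp_end_idx + 1)
    p = recording.pressure[insp]
    v = recording.volume[insp]
    if reference == "peep":
        p_ref = p[0]
    elif reference == "atmosphere":
        p_ref = 0.0
    else:
        raise ValueError(f"unknown energy reference {reference!r}")
    e_cmh2o_ml = float(np.trapezoid(p - p_ref, v))
    if e_cmh2o_ml < 0:
        raise ValueError("negative inspiratory energy: check phase labels")
    return e_cmh2o_ml * CMH2O_ML_TO_J


def mp_tidal(E_breath: float, rate: float, weight: float) -> float:
    """Tidal mechanical power, J/min/kg: per-breath energy x rate / weight."""
    if rate <= 0 or weight <= 0:
        raise ValueError("rate and weight must be positive")
    return E_breath * rate / weight


def me_rs(V_T: float, dP: float, PEEP: float, weight: float,
          formula: str = "elastic-peep") -> float:
    """Mechanical energy of the respiratory system per breath, J/kg.

    ``elastic-peep`` (default): (0.5*dP*V_T + PEEP*V_T), i.e. the tidal
    elastic energy plus the work done against the PEEP baseline.
    ``elastic``: tidal elastic term only. Formula selection is a config
    knob because published definitions differ.
    """
    if V_T <= 0 or dP <= 0 or weight <= 0 or PEEP < 0:
        raise ValueError("V_T, dP, weight must be positive; PEEP >= 0")
    if formula == "elastic-peep":
        e = 0.5 * dP * V_T + PEEP * V_T
    elif formula == "elastic":
        e = 0.5 * dP * V_T
    else:
        raise ValueError(f"unknown ME_RS formula {formula!r}")
    return e * CMH2O_ML_TO_J / weight


def vei(dP: float, rate: float, PaCO2: float, K: float = 3800.0) -> VEIResult:
    """Ventilatory efficiency index VEI = K / (dP * rate * PaCO2).

    Dimensionless; halves when any one input doubles.
    """
    if dP <= 0 or rate <= 0 or PaCO2 <= 0 or K <= 0:
        raise ValueError("all VEI inputs must be positive")
    return VEIResult(VEI=K / (dP * rate * PaCO2), dP=dP, rate=rate,
                     PaCO2=PaCO2, K=K)


def analyze_pv_curve(curve: StaticPVCurve, weight: float,
                     pressure_pairs=((0.0, 10.0), (10.0, 20.0), (20.0, 35.0)),
                     monotone_tolerance: float = 1e-6) -> PVCurveResult:
    """Total lung capacity and chord compliances from a static PV maneuver.

    TLC is the (interpolated) volume at 35 cmH2O per kg; if the maneuver
    stops short of 35 cmH2O the last chord is extended linearly and the
    result flagged ``extrapolated``. A non-monotone inflation limb (beyond
    ``monotone_tolerance`` x volume range) raises.
    """
    p, v = curve.pressure_steps, curve.volumes
    vrange = max(float(v.max() - v.min()), 1.0)
    if np.any(np.diff(v) < -monotone_tolerance * vrange):
        raise ValueError("non-monotone inflation limb beyond tolerance")
    extrapolated = p.max() < 35.0
    if extrapolated:
        slope = (v[-1] - v[-2]) / (p[-1] - p[-2])
        v35 = v[-1] + slope * (35.0 - p[-1])
    else:
        v35 = float(np.interp(35.0, p, v))
    chords = {}
    for lo, hi in pressure_pairs:
        if lo < p.min() or hi > max(p.max(), 35.0) or hi <= lo:
            continue
        v_lo = float(np.interp(lo, p, v))
        v_hi = v35 if (extrapolated and hi > p.max()) else float(np.interp(hi, p, v))
        chords[(lo, hi)] = (v_hi - v_lo) / (hi - lo) / weight
    return PVCurveResult(TLC_mlkg=v35 / weight, chord_compliance_mlkg=chords,
                         extrapolated=extrapolated)


def calibrate_delta_VL(global_eit_signal: np.ndarray, dZ_ref: float,
                       V_ref: float):
    """Scale an arbitrary-unit global EIT signal to mL.

    ``dZ_ref`` (au) and ``V_ref`` (mL) come from a static PV-curve reference
    point; the scale s = V_ref / dZ_ref applies to the whole series (origin
    preserved). Returns ``(signal_mL, s)``.
    """
    if dZ_ref <= 0:
        raise ValueError("dZ_ref must be positive")
    s = V_ref / dZ_ref
    return np.asarray(global_eit_signal, dtype=float) * s, s


def mechanics_table(recording: WaveformRecording, segments,
                    weight: float | None = None,
                    paco2: float | None = None,
                    vei_K: float = 3800.0,
                    me_formula: str = "elastic-peep",
                    mp_reference: str = "peep",
                    fit: bool = True) -> pd.DataFrame:
    """Per-breath mechanics/energetics table for a segmented recording.

    Rate is taken from each breath's own duration. VEI columns are filled
    when ``paco2`` is given. Degenerate breaths keep their flag; fit errors
    leave NaN in the fit columns.
    """
    w = recording.weight if weight is None else weight
    rows = []
    for b, seg in enumerate(segments):
        m = breath_mechanics(recording, seg, w)
        rate_b = 60.0 / seg.duration
        row = {
            "subject_id": recording.subject_id, "group": recording.group_label,
            "breath_index": b, "PIP": m.PIP, "PEEP": m.PEEP_measured,
            "dP": m.dP, "V_T_ml": m.V_T, "V_T_mlkg": m.V_T_mlkg,
            "C_dyn": m.C_dyn, "C_dyn_mlkg": m.C_dyn_mlkg,
            "Flow_peak_lpm": m.Flow_peak, "rate_bpm": rate_b,
            "degenerate": m.degenerate,
        }
        try:
            e = energy_per_breath(recording, seg, reference=mp_reference)
            row["E_breath_J"] = e
            row["MP_tidal_J_min_kg"] = mp_tidal(e, rate_b, w)
        except ValueError:
            row["E_breath_J"] = np.nan
            row["MP_tidal_J_min_kg"] = np.nan
        row["ME_RS_J_kg"] = (me_rs(m.V_T, m.dP, m.PEEP_measured, w, me_formula)
                             if not m.degenerate else np.nan)
        if fit:
            try:
                f = fit_equation_of_motion(recording, seg)
                row["C_fit"] = f.C_fit
                row["R_fit"] = f.R_fit
                row["fit_rms"] = f.rms_residual
            except ValueError:
                row["C_fit"] = row["R_fit"] = row["fit_rms"] = np.nan
        if paco2 is not None:
            row["VEI"] = vei(m.dP, rate_b, paco2, vei_K).VEI
        rows.append(row)
    return pd.DataFrame(rows)
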