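"""Core domain containers for ventilator waveform and regional ventilation analysis.

Units follow neonatal respiratory convention throughout the package:
pressure in cmH2O, flow in L/min (positive = inspiratory), volume in mL
above end-expiratory volume, compliance in mL/cmH2O, resistance in
cmH2O*s/mL, time in seconds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "VentilatorSettings",
    "LungModelParams",
    "WaveformRecording",
    "RegionalMap",
    "GasState",
    "EITFrameSeries",
    "BreathSegment",
    "CMH2O_ML_TO_J",
]

#: 1 cmH2O*mL expressed in joules.
CMH2O_ML_TO_J = 98.0665e-6


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


def _finite(*vals: float) -> bool:
    return all(math.isfinite(v) for v in vals)


@dataclass(frozen=True)
class VentilatorSettings:
    """Continuous bias-flow pressure-limited ventilator settings.

    The ventilator charges the patient circuit with a constant fresh-gas
    (bias) flow; an ideal relief valve caps circuit pressure at the set
    inflation target (PIP during inspiration, PEEP during expiration).
    Phase switching is clock-driven by ``Ti`` and ``rate``.
    """

    bias_flow: float  # L/min
    set_PIP: float  # cmH2O
    set_PEEP: float  # cmH2O
    Ti: float  # s
    rate: float  # breaths/min
    PIP_max: float = 40.0  # cmH2O ceiling for closed-loop adjustment
    circuit_compliance: float = 0.1  # mL/cmH2O

    def __post_init__(self) -> None:
        _require(
            _finite(self.bias_flow, self.set_PIP, self.set_PEEP, self.Ti,
                    self.rate, self.PIP_max, self.circuit_compliance),
            "ventilator settings must be finite",
        )
        _require(self.bias_flow >= 0, "bias_flow must be >= 0 L/min")
        _require(self.set_PEEP >= 0, "set_PEEP must be >= 0 cmH2O")
        _require(self.set_PIP > self.set_PEEP, "set_PIP must exceed set_PEEP")
        _require(self.rate > 0, "rate must be positive")
        _require(0 < self.Ti < 60.0 / self.rate,
                 "Ti must lie strictly inside the breath period 60/rate")
        _require(self.set_PIP <= self.PIP_max, "set_PIP must not exceed PIP_max")
        _require(self.circuit_compliance > 0, "circuit_compliance must be positive")

    @property
    def breath_period(self) -> float:
        return 60.0 / self.rate

    @property
    def bias_flow_mls(self) -> float:
        """Bias flow in mL/s."""
        return self.bias_flow * 1000.0 / 60.0


@dataclass(frozen=True)
class LungModelParams:
    """Single-compartment respiratory system with optional surfactant step.

    ``surfactant_time`` marks a step increase of compliance by
    ``surfactant_factor`` (only the mechanical consequence of surfactant is
    modelled). CO2 kinetics are first-order: PaCO2 relaxes toward
    ``k_CO2 / alveolar minute ventilation`` with time constant
    ``CO2_time_constant``.
    """

    C_rs: float  # mL/cmH2O
    R_aw: float  # cmH2O*s/mL
    weight: float  # kg
    surfactant_time: float | None = None  # s
    surfactant_factor: float = 1.0
    dead_space: float = 13.5  # mL: airway + apparatus, ~4.5 mL/kg at 3 kg
    CO2_production_constant: float = 22500.0  # mmHg*mL/min; PaCO2 = k/V_A
    CO2_time_constant: float = 60.0  # s

    def __post_init__(self) -> None:
        _require(_finite(self.C_rs, self.R_aw, self.weight,
                         self.surfactant_factor, self.dead_space,
                         self.CO2_production_constant, self.CO2_time_constant),
                 "lung parameters must be finite")
        _require(self.C_rs > 0, "C_rs must be positive")
        _require(self.R_aw > 0, "R_aw must be positive")
        _require(self.weight > 0, "weight must be positive")
        _require(self.surfactant_factor >= 1.0, "surfactant_factor must be >= 1")
        _require(self.dead_space >= 0, "dead_space must be >= 0")

    @property
    def time_constant(self) -> float:
        """Expiratory time constant tau = R_aw * C_rs (s)."""
        return self.R_aw * self.C_rs

    def after_surfactant(self) -> "LungModelParams":
        return replace(self, C_rs=self.C_rs * self.surfactant_factor,
                       surfactant_time=None, surfactant_factor=1.0)


@dataclass
class WaveformRecording:
    """Synchronized airway-opening pressure/flow/volume time series."""

    time: np.ndarray  # s, uniform grid
    pressure: np.ndarray  # cmH2O
    flow: np.ndarray  # L/min, positive = inspiratory
    volume: np.ndarray  # mL above end-expiratory volume
    sample_rate: float  # Hz
    subject_id: str = "subject"
    weight: float = 1.0  # kg
    group_label: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.pressure = np.asarray(self.pressure, dtype=float)
        self.flow = np.asarray(self.flow, dtype=float)
        self.volume = np.asarray(self.volume, dtype=float)
        n = self.time.size
        _require(self.pressure.size == n and self.flow.size == n
                 and self.volume.size == n, "channels must have equal length")
        _require(self.sample_rate >= 100.0, "sample_rate must be >= 100 Hz")
        _require(self.weight > 0, "weight must be positive")

    @property
    def n_samples(self) -> int:
        return self.time.size

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0]) if self.time.size else 0.0


@dataclass
class RegionalMap:
    """Per-pixel share of global tidal ventilation on an EIT-style grid.

    Row 0 is the most ventral row; column 0 is the subject's right side.
    ``regional_share`` sums to 1 over ``lung_mask`` and is 0 elsewhere.
    """

    regional_share: np.ndarray  # 2D, fraction per pixel
    lung_mask: np.ndarray  # 2D boolean
    pixel_gain: np.ndarray | None = None  # optional per-pixel gain (au per mL)

    def __post_init__(self) -> None:
        self.regional_share = np.asarray(self.regional_share, dtype=float)
        self.lung_mask = np.asarray(self.lung_mask, dtype=bool)
        _require(self.regional_share.shape == self.lung_mask.shape,
                 "regional_share and lung_mask shapes must match")
        _require(np.all(self.regional_share >= 0), "shares must be >= 0")
        _require(np.all(self.regional_share[~self.lung_mask] == 0),
                 "non-lung pixels must have zero share")
        total = self.regional_share[self.lung_mask].sum()
        _require(abs(total - 1.0) < 1e-9,
                 f"regional_share must sum to 1 over lung_mask (got {total})")
        if self.pixel_gain is not None:
            self.pixel_gain = np.asarray(self.pixel_gain, dtype=float)
            _require(self.pixel_gain.shape == self.lung_mask.shape,
                     "pixel_gain shape must match grid")


@dataclass(frozen=True)
class GasState:
    """Arterial CO2 state of the simulated subject."""

    PaCO2: float  # mmHg
    alveolar_minute_ventilation: float = 0.0  # mL/min

    def __post_init__(self) -> None:
        _require(self.PaCO2 > 0, "PaCO2 must be positive")
        _require(self.alveolar_minute_ventilation >= 0,
                 "alveolar minute ventilation must be >= 0")


@dataclass
class EITFrameSeries:
    """Pixel-grid ventilation time series (reconstructed EIT images).

    ``frames`` has shape (n_frames, n_rows, n_cols) with row 0 most ventral.
    """

    frames: np.ndarray
    times: np.ndarray  # s
    frame_rate: float  # Hz
    lung_mask: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.lung_mask = np.asarray(self.lung_mask, dtype=bool)
        _require(self.frames.ndim == 3, "frames must be (n_frames, rows, cols)")
        _require(self.frames.shape[0] == self.times.size,
                 "one timestamp per frame required")
        _require(self.frames.shape[1:] == self.lung_mask.shape,
                 "lung_mask shape must match frame grid")

    def global_signal(self) -> np.ndarray:
        """Sum over lung pixels per frame (the global ventilation signal)."""
        return self.frames[:, self.lung_mask].sum(axis=1)


@dataclass(frozen=True)
class BreathSegment:
    """Index/time boundaries of one breath within a parent recording."""

    insp_onset_idx: int
    insp_end_idx: int
    exp_end_idx: int
    insp_onset: float
    insp_end: float
    exp_end: float

    def __post_init__(self) -> None:
        _require(self.insp_onset_idx < self.insp_end_idx < self.exp_end_idx,
                 "breath indices must be strictly increasing")
        _require(self.insp_onset < self.insp_end < self.exp_end,
                 "breath times must be strictly increasing")

    @property
    def Ti(self) -> float:
        """Observed inspiratory duration (s)."""
        return self.insp_end - self.insp_onset

    @property
    def duration(self) -> float:
        return self.exp_end - self.insp_onset
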