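"""Seeded synthetic cohorts of ventilated preterm subjects.

A scenario states the bias-flow groups and the inter-subject parameter
distributions (log-normal, configured median and coefficient of variation
for compliance, resistance, and weight). Defaults describe a surfactant-
deficient preterm lamb: weight ~3 kg, respiratory-system compliance
~0.5 mL/cmH2O/kg, low airway+tube resistance, PEEP 8 cmH2O, Ti 0.5 s, rate
60/min, tidal-volume target 7 mL/kg, and instrument-level sensor noise.
Per-subject PIP is set (to 1 cmH2O resolution) so the single-compartment
plateau delivers the V_T target, mirroring clinical titration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .core import LungModelParams, VentilatorSettings, WaveformRecording
from .simulate import simulate_ventilation

__all__ = ["Scenario", "CohortSubject", "make_cohort"]


@dataclass(frozen=True)
class Scenario:
    """Cohort-generation configuration (the stated experimental world)."""

    groups: dict = field(default_factory=lambda: {"F4": 4.0, "F6": 6.0, "F8": 8.0})
    n_per_group: int = 5
    weight_median: float = 3.0  # kg
    weight_cv: float = 0.10
    crs_median: float = 1.5  # mL/cmH2O
    crs_cv: float = 0.20
    raw_median: float = 0.025  # cmH2O*s/mL
    raw_cv: float = 0.20
    set_PEEP: float = 8.0
    Ti: float = 0.5
    rate: float = 60.0
    PIP_max: float = 40.0
    circuit_compliance: float = 0.1
    target_VT_mlkg: float = 7.0
    duration: float = 30.0  # s per recording
    sample_rate: float = 200.0
    noise_sd: tuple = (0.1, 0.1, 0.1)  # cmH2O, L/min, mL
    surfactant_time: float | None = None
    surfactant_factor: float = 2.0
    co2_production_per_kg: float = 7500.0  # mmHg*mL/min/kg
    dead_space_per_kg: float = 4.5  # mL/kg, airway plus apparatus

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("scenario must define at least one flow group")
        if min(self.groups.values()) < 0:
            raise ValueError("bias flows must be >= 0 L/min")


@dataclass
class CohortSubject:
    """One simulated subject with its ground-truth generating parameters."""

    subject_id: str
    group: str
    settings: VentilatorSettings
    lung: LungModelParams
    recording: WaveformRecording
    seed: int

    def ground_truth(self) -> dict:
        gt = {"subject_id": self.subject_id, "group": self.group,
              "seed": self.seed}
        gt.update({f"settings.{k}": v for k, v in asdict(self.settings).items()})
        gt.update({f"lung.{k}": v for k, v in asdict(self.lung).items()})
        return gt


def _lognormal(rng: np.random.Generator, median: float, cv: float) -> float:
    if cv <= 0:
        return median
    sigma = np.sqrt(np.log1p(cv ** 2))
    return float(median * np.exp(rng.normal(0.0, sigma)))


def make_cohort(scenario: Scenario, n_per_group: int | None = None,
                seed: int = 0, matched: bool = False) -> list[CohortSubject]:
    """Generate a labelled cohort with retained ground truth.

    Parameters
    ----------
    n_per_group
        Subjects per flow group (defaults to ``scenario.n_per_group``);
        must be >= 2.
    matched
        When True, the same lung parameter draws (and noise seeds) are
        reused across flow groups, giving a matched-lungs comparison in
        which only bias flow differs between groups.

    The same ``seed`` always yields a bit-identical cohort.
    """
    n = scenario.n_per_group if n_per_group is None else n_per_group
    if n < 2:
        raise ValueError("n_per_group must be >= 2")
    rng = np.random.default_rng(seed)

    def draw_subject(idx: int):
        w = _lognormal(rng, scenario.weight_median, scenario.weight_cv)
        crs = _lognormal(rng, scenario.crs_median, scenario.crs_cv)
        raw = _lognormal(rng, scenario.raw_median, scenario.raw_cv)
        noise_seed = int(rng.integers(2 ** 31))
        return w, crs, raw, noise_seed

    draws = {}
    subjects: list[CohortSubject] = []
    group_names = list(scenario.groups)
    for gi, gname in enumerate(group_names):
        flow = scenario.groups[gname]
        for si in range(n):
            if matched and gi > 0:
                w, crs, raw, noise_seed = draws[si]
            else:
                w, crs, raw, noise_seed = draw_subject(si)
                draws[si] = (w, crs, raw, noise_seed)
            lung = LungModelParams(
                C_rs=crs, R_aw=raw, weight=w,
                surfactant_time=scenario.surfactant_time,
                surfactant_factor=(scenario.surfactant_factor
                                   if scenario.surfactant_time is not None else 1.0),
                dead_space=scenario.dead_space_per_kg * w,
                CO2_production_constant=scenario.co2_production_per_kg * w,
            )
            # clinical-style PIP titration: plateau V_T at target, 1 cmH2O steps
            pip = scenario.set_PEEP + scenario.target_VT_mlkg * w / crs
            pip = float(np.clip(round(pip), scenario.set_PEEP + 2, scenario.PIP_max))
            settings = VentilatorSettings(
                bias_flow=flow, set_PIP=pip, set_PEEP=scenario.set_PEEP,
                Ti=scenario.Ti, rate=scenario.rate, PIP_max=scenario.PIP_max,
                circuit_compliance=scenario.circuit_compliance)
            sid = f"{gname}_s{si:02d}"
            rec = simulate_ventilation(
                settings, lung, scenario.duration,
                sample_rate=scenario.sample_rate,
                seed=noise_seed, noise_sd=tuple(scenario.noise_sd),
                subject_id=sid, group_label=gname)
            subjects.append(CohortSubject(subject_id=sid, group=gname,
                                          settings=settings, lung=lung,
                                          recording=rec, seed=noise_seed))
    return subjects
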