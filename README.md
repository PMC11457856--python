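# ventwave

Ventilator-waveform, lung-mechanics, and regional-ventilation analysis for
pressure-limited **continuous bias-flow ventilation**, with a ground-truth
ventilator–circuit–lung simulator so every stage of the analysis can be
validated at desk scale.

## The problem

Most neonatal ventilators and T-piece resuscitators deliver pressure by
charging the patient circuit with a constant fresh-gas (*bias*) flow and
capping the pressure with a relief valve. The bias flow rate therefore sets
how *fast* inflation pressure and volume rise in the lung — the speed of
tidal lung motion — independently of the tidal volume, driving pressure, or
PEEP actually delivered. In the structurally immature preterm lung this
speed is a candidate injury mechanism (rheotrauma) distinct from volutrauma
and barotrauma. Quantifying it requires per-breath waveform metrics (time to
peak, maximum slopes), lung mechanics and energetics (C_dyn, ΔP, mechanical
power), ventilatory efficiency, and regional ventilation distribution from
electrical impedance tomography (EIT), compared across flow-rate groups.

`ventwave` is for respiratory physiologists and biomedical engineers who
need that analysis stack as a library: each stage is importable on its own,
and a built-in simulator supplies waveforms and EIT frames with known ground
truth for validation and power studies.

## The model

The simulator is a two-node lumped model. The circuit node (compliance
`C_circ`) is charged by the bias flow `F` and limited by an ideal relief
valve at the set pressure (PIP during inspiration, PEEP during expiration);
the lung is a single compartment (compliance `C_rs`, resistance `R_aw`):

    C_circ · dP_circ/dt = F − Q − Q_valve,   P_circ ≤ P_set
    dV/dt = Q = (P_circ − PEEP − V/C_rs) / R_aw

Within each valve state the system is linear and is integrated **exactly**
(closed form); phase switching is clock-driven (`Ti`, rate) since the
modelled subjects are apnoeic and intubated. Two consequences the analysis
exploits: peak inspiratory flow is bounded by the quasi-steady split
`F · C_rs/(C_rs + C_circ)` (≈ the set bias flow for a stiff circuit), and
expiration is a single exponential with time constant τ = R_aw·C_rs.

Derived metrics follow the field's standard definitions, e.g.

- `T_peak`, `Slope_max` — time to inspiratory peak and maximum first
  derivative (Savitzky–Golay) of the pressure/volume/flow waves,
- `MP_tidal = rate/weight · ∫insp (P_ao − PEEP) dV` — tidal mechanical power,
- `ME_RS = (0.5·ΔP·V_T + PEEP·V_T)/weight` — respiratory-system mechanical
  energy per breath,
- `VEI = 3800 / (ΔP · rate · PaCO2)` — ventilatory efficiency index,
- `CoV` — amplitude-weighted centroid of the EIT tidal image in % of the
  ventral→dorsal (or right→left) extent,

with a Welch-t / ANOVA+Tukey / repeated-measures comparison layer on top.

## Worked example

```python
import ventwave as vw

lung = vw.LungModelParams(C_rs=1.5, R_aw=0.025, weight=3.0)  # preterm, 3 kg
for flow in (4.0, 8.0):
    s = vw.VentilatorSettings(bias_flow=flow, set_PIP=22.0, set_PEEP=8.0,
                              Ti=0.5, rate=60.0, circuit_compliance=0.1)
    rec = vw.simulate_ventilation(s, lung, duration=10.0)
    m = vw.breath_mechanics(rec, vw.segment_breaths(rec)[3])
    print(flow, round(m.V_T, 2), round(m.Flow_peak, 2))
```

prints

```
4.0 20.99 3.75
8.0 21.0 7.5
```

— both flows deliver the same 7 mL/kg tidal volume and a peak inspiratory
flow ≈ 94% of the set bias flow, but the time to reach PIP is 301 ms at
4 L/min vs 133 ms at 8 L/min (`rec.meta["valve_open_times"]`): flow rate
changes the *speed* of lung motion, not the amount. The `examples/`
directory has one narrative script per capability (simulation, motion
metrics, mechanics/energetics, EIT regional analysis, cohort statistics,
full pipeline); each prints the numbers it computes and what they mean.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the complete pipeline from scratch on a seeded three-group synthetic
cohort (4/6/8 L/min): simulation → breath segmentation → motion metrics →
mechanics/energetics → synthetic-EIT regional metrics → cohort statistics →
report, and writes the results JSON. The properties the pipeline must
satisfy (simulator–oracle agreement, parameter recovery, bias-flow
monotonicity, energy bounds, EIT sum rules, statistical calibration,
end-to-end determinism) are asserted in `tests/test_acceptance.py`.

## Layout

- `src/ventwave/simulate.py` — circuit–lung simulator (exact piecewise-linear integration)
- `src/ventwave/protocol.py` — Ti titration, CO2 kinetics, closed-loop PIP/rate controller
- `src/ventwave/cohort.py`, `eit_synth.py` — seeded cohorts and synthetic EIT frames
- `src/ventwave/breaths.py` — segmentation and motion metrics
- `src/ventwave/mechanics.py` — mechanics, energetics, VEI, PV curve, ΔV_L calibration
- `src/ventwave/eit.py` — tidal images, CoV, relative aeration, silent spaces
- `src/ventwave/stats.py` — Welch t, ANOVA+Tukey, repeated-measures ANOVA
- `src/ventwave/io.py`, `pipeline.py` — CSV/YAML round trips and the end-to-end pipeline

See `docs/methods.md` for the model assumptions, parameter defaults with
units, numerical choices, and what the synthetic data does and does not
emulate.
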