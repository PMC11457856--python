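# Methods

## Ventilator–circuit–lung model

The simulator couples two pressure nodes through the airway resistance:

- **Circuit node** (compliance `C_circ`, mL/cmH2O): charged by a constant
  bias flow `F` (L/min, converted internally to mL/s) and limited by an
  ideal relief valve that holds `P_circ ≤ P_set`, where `P_set` is the set
  PIP during inspiration and the set PEEP during expiration.
- **Lung node**: a single compartment with compliance `C_rs` (mL/cmH2O) and
  resistance `R_aw` (cmH2O·s/mL); `dV/dt = Q = (P_circ − PEEP − V/C_rs)/R_aw`.
  Volume `V` is referenced to the end-expiratory equilibrium at PEEP.

Airway-opening pressure equals circuit pressure; the flow channel is the
lung flow measured at the airway opening. Phase switching is clock-driven
(`Ti`, rate): the intended subjects are apnoeic and intubated, so no
spontaneous-effort or triggering model is included.

**Assumptions and what they buy.** An *ideal* relief valve vents instantly,
so expiration starts with a pressure step to PEEP and the lung then empties
as a single exponential with τ = `R_aw·C_rs`; there is no expiratory-limb
resistance. A single lung compartment means no intercompartment pendelluft
and a single time constant. These idealisations make every downstream
quantity analytically predictable, which is what the validation suite needs.

**Integration.** Within each valve state the system is linear: valve-closed
dynamics have eigenvalues {0, −1/τ_a} with τ_a = `R_aw·(C_rs‖C_circ)`, giving
a secular-plus-exponential closed form; valve-open dynamics are a single
exponential. Each breath is therefore evaluated exactly on the output grid,
with the valve-opening instant located by bracketed root-finding
(`scipy.optimize.brentq`, xtol 1e−13) on the closed form. We chose exact
piecewise integration over an adaptive ODE solver because it is faster by
orders of magnitude (the full test suite simulates thousands of breaths) and
has no truncation error; the test suite still cross-checks it against an
independent 10 µs explicit-Euler integration.

Two closed-form consequences used by the tests:

- peak inspiratory flow equals the quasi-steady split
  `F·C_rs/(C_rs + C_circ)` (approached monotonically; never exceeded), and
- the time to reach set PIP is ≈ `ΔP·(C_rs + C_circ)/F`, which is what makes
  low bias flows slow lung motion at matched pressures.

## Parameter defaults (the stated world)

| parameter | default | units | rationale |
|---|---|---|---|
| weight | 3.0 (CV 10%) | kg | preterm lamb, ~0.85 gestation study window |
| C_rs | 1.5 (CV 20%) | mL/cmH2O | ≈0.5 mL/cmH2O/kg, surfactant-deficient preterm lung |
| R_aw | 0.025 (CV 20%) | cmH2O·s/mL | low airway resistance plus a 3.5–4 mm tracheal tube; τ ≈ 38 ms |
| C_circ | 0.1 | mL/cmH2O | see below |
| PEEP / PIP | 8 / titrated | cmH2O | lung-protective PEEP; PIP set so the plateau delivers the V_T target (1 cmH2O resolution, ceiling 40) |
| Ti / rate | 0.5 s / 60 min⁻¹ | | Ti commenced at 0.5 s and shortened when end-inspiratory zero flow exceeds 20% of Ti (strict inequality); rate titrated to the PaCO2 band |
| target V_T | 7 | mL/kg | lung-protective neonatal target |
| PaCO2 band | 45–55 | mmHg | permissive-hypercapnia band |
| dead space | 4.5 | mL/kg | airway plus apparatus |
| k_CO2 | 7500·weight | mmHg·mL/min | chosen so PaCO2 equilibrates at 50 mmHg at the V_T target and rate 60 (equivalent to VCO2 ≈ 9 mL/min/kg); emulates, not estimates, physiology |
| CO2 time constant | 60 | s | body CO2 store washout at this scale |
| sensor noise | 0.1 / 0.1 / 0.1 | cmH2O, L/min, mL | instrument-level additive Gaussian noise per channel |
| inter-subject CVs | log-normal | | median/CV parameterisation; CV 0 degenerates to the median subject |

**Circuit compliance.** The model's peak inspiratory flow is
`F·C_rs/(C_rs+C_circ)`. With a preterm `C_rs ≈ 1.5`, a circuit compliance of
1 mL/cmH2O would cap measured peak flow at 0.6·F, which contradicts the
observed behaviour of continuous bias-flow ventilators on such lungs (peak
inspiratory flow approximates the set bias flow). The default is therefore
`C_circ = 0.1` mL/cmH2O — the effective compressible volume between the
flow-control point and the airway-opening sensor — which puts peak flow at
0.94·F for the default lung. It is a plain configuration field; nothing in
the code depends on the default.

**CO2 kinetics.** PaCO2 relaxes first-order toward `k_CO2 / V_A` with
alveolar minute ventilation `V_A = rate · max(V_T − dead_space, 0)`; apnoea
(V_A = 0) relaxes toward a configured ceiling (default 130 mmHg). This is a
deliberately minimal gas-exchange emulator sufficient to close the
rate-titration loop; it has no shunt, no metabolic drift, and no oxygenation
model.

**Surfactant** is modelled solely as a multiplicative compliance step at a
scheduled time (default factor 2 at the configured dose time): only its
mechanical consequence is analysed downstream. The birth recruitment
maneuver is reduced to an optional initial high-PIP epoch via the protocol
controller; a full dynamic-PEEP schedule is not modelled.

## Analysis choices

**Breath segmentation** uses flow-threshold crossings with a hysteresis band
(default ±0.1 L/min, ≈1% of a typical bias flow) rather than the ventilator
clock, so the analyzer works on any recording. Crossings are detected on a
9-sample moving-average copy of the flow (sensor noise near zero flow would
otherwise split breaths) and then snapped to the raw-signal crossing so the
centred smoothing does not bias boundary positions; every boundary is the
last pre-transition sample, which keeps PEEP and V_T readings on the correct
side of transitions that complete within one sample. On noisy recordings the
detection threshold should sit a few noise SDs up (the pipeline default is
0.3 L/min against 0.1 L/min noise).

**Derivatives** (`Slope_max`) come from a centred Savitzky–Golay filter
(window 7 samples, order 2, configurable). Raw differencing is
noise-dominated at 200 Hz; the filter's bias on analytic test signals is
bounded in the test suite (<1% on a quarter-sine, <2% against central
differences on resolved simulator traces). Expiratory `Slope_max` is
reported as the maximum derivative *magnitude* during expiration. Peak and
slope ties break to the earliest sample (with a 1e−9 relative tolerance so
float jitter in the filtered derivative cannot mask a tie).

**Mechanics** are provided by two routes on purpose: the ratio `C_dyn =
V_T/ΔP` (with PEEP measured at inspiratory onset, robust to intrinsic PEEP)
and a least-squares fit of `P_ao = V/C + R·Q + P0` over the whole breath.
In this model the equation of motion holds exactly, so the fit recovers the
generating parameters to solver precision; on real data the two routes
differ and both are reported.

**Energetics.** `E_breath = ∫insp (P_ao − PEEP) dV` (trapezoidal), converted
at 1 cmH2O·mL = 98.0665e−6 J; `MP_tidal = E_breath·rate/weight`. The
PEEP-referenced form isolates tidal energy; it is a stated formula choice,
selectable in configuration, as is the `ME_RS` closed form
`0.5·ΔP·V_T + PEEP·V_T` (per kg) — published definitions of both quantities
vary, so the implementation treats the formula as configuration, not truth.
`VEI = K/(ΔP·rate·PaCO2)` with the standard K = 3800.

**EIT metrics.** The tidal image is the mean end-inspiratory minus
end-expiratory pixel difference over the breaths in the window (breaths
located on the lung-sum signal; negative pixels clipped with the count
reported). CoV is the amplitude-weighted centroid of the tidal image with
pixel-centre coordinates normalised to [0, 100] over the lung-mask bounding
box (0 = most ventral / subject's right); the word "geometric mean" used for
this quantity in the EIT literature is interpreted as this geometric centre,
with a literal log-scale mean available behind `method="log"`. Relative
aeration is region signal share over region pixel share (pixel-share-weighted
mean ≡ 1 over any partition). The unventilated fraction counts lung pixels
strictly below 10% (configurable) of the mean nonzero lung amplitude — a
silent-space convention; the threshold definition travels with the output.
Default regional partitions are bounding-box thirds (ventral/central/dorsal)
and halves (right/left).

**Statistics.** Welch t (with Satterthwaite df and 95% CI), one-way ANOVA
with Tukey HSD (studentized-range adjustment), and a balanced two-way
repeated-measures (split-plot) ANOVA: group tested against
subjects-within-group, time and group×time against the within-subject
residual. Unbalanced tables are rejected with guidance — the synthetic
cohorts are balanced by construction, and approximating REML on missing data
is out of scope. Degenerate strata (zero variance) return F = 0/p = 1 for
zero-SS terms rather than NaN. The summary battery dispatches by group
count (2 → Welch, ≥3 → ANOVA+Tukey), matching the reporting convention the
pipeline emulates. α = 0.05 throughout.

## What the generator emulates — and what a green test does not establish

The synthetic cohorts reproduce: flow-limited pressurisation (slower
pressure/volume rise at lower bias flow at matched ΔP and V_T), matched
delivered V_T across flow groups via PIP titration, single-exponential
passive expiration identical across flow groups, first-order CO2 kinetics
closing the rate-titration loop, and heterogeneous regional ventilation
favouring the right and ventral lung with an optional silent fraction.

They do **not** emulate: spontaneous breathing or patient–ventilator
asynchrony, multi-compartment or volume-dependent mechanics, airway-closure
or recruitment hysteresis in the PV curve, EIT reconstruction artifacts
(inputs are reconstructed images by assumption), oxygenation, or any injury
biology. A green pipeline on this stated world establishes the *analysis*
is correct and calibrated, not that the physiological effect sizes are
realistic. One noise-dependent subtlety: on a noise-free clock-driven
simulator, the volume argmax is always the last inspiratory sample, so
group differences in T_peak(volume) only appear — as in real recordings —
once instrument noise makes the late-inspiratory plateau flat; monotonicity
checks therefore run at the default noise level.

## Numerical details

- Valve-opening times located to 1e−13 s; sampled channels evaluated from
  closed forms, not stepped.
- The flow channel is discontinuous at expiratory onset (ideal valve); no
  sampled quadrature can integrate across that step, so volume/flow
  consistency checks apply within the inspiration.
- Random draws: `numpy.random.default_rng`; seeds are mandatory arguments
  wherever noise is generated, and cohort/EIT seeds are derived from the
  pipeline seed via `SeedSequence.spawn`, keeping all derived seeds below
  2³¹. Identical (config, seed) reproduce byte-identical artifacts.
- Lognormal sampling uses median/CV parameterisation:
  σ = √ln(1+CV²), median preserved exactly.
- Unit constants: 1 L/min = 1000/60 mL/s; 1 cmH2O·mL = 98.0665e−6 J.

## Known limitations

- The relief-valve abstraction is a stated simplification of proprietary
  flow-titration mechanisms in commercial ventilators; the simulator is a
  physics cartoon of that class of device, not a digital twin.
- `fit_equation_of_motion` assumes the single-compartment form; on data from
  heterogeneous lungs the fitted C and R are effective values.
- The repeated-measures layer requires complete balanced tables.
- The protocol controller uses fixed step sizes (±1 cmH2O, ±5 breaths/min)
  and a deadband; it converges to within one step of the target, which is
  the intended clinical granularity, not an optimal controller.
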