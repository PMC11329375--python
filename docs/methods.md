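# Methods

This note documents the models implemented in `navloop`, their
assumptions, the defaults and why they were chosen, what the synthetic
data emulate (and what they do not), and the numerical choices that
matter for reproducing results.

## Channel forward model

A cell's Na⁺ current under voltage clamp is modelled as

```
I(t) = g_max · C_m · m∞(V) · [p + (1 − p)·h(t)] · (V − E_rev) + g_leak·(V − E_leak) + ε(t)
```

with `m∞` and `h∞` the Boltzmann activation and steady-state
inactivation curves `1/(1+exp((V½−V)/k))` (signed k: activation k > 0,
inactivation k < 0, matching the convention in which fitted slope
factors are printed), `h(t)` relaxing exponentially towards `h∞(V)`
with a single time constant `τ_inact`, a persistent fraction `p` of the
conductance that never inactivates, ohmic leak, and Gaussian white
current noise `ε`.

Assumptions and defaults:

* **Activation is instantaneous** (`m = m∞`). No activation kinetics
  are parameterised in the measurements this package reproduces; since
  the persistent current is read 20–25 ms after depolarisation and
  Na_v_1.5 activation settles in well under a millisecond, treating it
  as instantaneous changes nothing the pipelines measure.
* **`τ_inact` = 1.5 ms** (configurable) — typical for Na_v_1.5 near
  0 mV; the transient has decayed by >13 time constants at the start of
  the persistent window, so the window mean is persistent-only to ~1e-6.
* **`E_rev` from the Nernst equation for the recording solutions**:
  ~149 mM extracellular Na⁺ (144 mM NaCl plus NaOH titration to pH 7.2)
  against 5 mM pipette Na⁺ at 21 °C gives **+86.0 mV** (configurable).
* **Capacitance default 20 pF**, leak 1 nS to E_leak = 0 mV. Densities
  (pA/pF) make most results capacitance-invariant; 20 pF is a typical
  MDA-MB-231 whole-cell value and is also the value used in the
  acidification prediction.
* **Noise is Gaussian and white at the 50 kHz sampling rate, SD 1 pA.**
  No mains hum is modelled (hardware-filtered in practice) and no
  capacitive transients or series-resistance error are simulated.

Two protocols are generated, matching standard practice: activation
(hold −120 mV for 250 ms, 50 ms steps from −120 to +30 mV in 5 or
10 mV increments) and steady-state inactivation (250 ms prepulses over
the same range, then a 50 ms test pulse to −10 mV).

### P/6 sub-records

Each sweep carries six leak sub-records whose command excursion from
holding is scaled by −1/6 (hyperpolarising). Inverted subpulses are the
deliberate default: with depolarising subpulses the Boltzmann `m∞`
never quite reaches zero, and the ×6-amplified subthreshold channel
current (~0.3 pA per subsweep at −100 mV) would contaminate a ~6 pA
persistent signal by ~25%. Hyperpolarising subpulses keep the channels
shut (m∞(−140) ≈ 1e-5) and leave only a ≲0.5% artefact, which the
density inversion (below) accounts for exactly.

### Closed-form inversion from published densities

Cohort ground truth is stated in the units the analysis reports. For a
target peak and persistent density the generator solves the *measured*
current equation — including the steady window-current residue
`(1−p)h∞(V)`, the standing holding-level channel current removed by
baseline referencing, and the P/6 sub-record residue — for `g_max` and
`g_max·p`. All three artefact terms are linear in those two unknowns,
so the inversion is an exact 2×2 solve (with one fixed-point refinement
of the peak's argmax step). The zero-noise pipeline round trip is then
exact to <1e-4 relative, which is what makes zero-noise oracle tests
meaningful.

## Analysis pipeline

Order of operations per recording: baseline referencing (mean of the
10 ms before the analysed depolarisation — for the inactivation
protocol, before the *prepulse* — excluding the onset sample), P/6
subtraction, then the measurement.

* **Peak density**: most-negative current in the first 5 ms after
  depolarisation, after the **half peak-to-peak noise correction**
  (half the baseline-window range added towards zero). The correction
  compensates the extremum-selection bias of reading a peak off a noisy
  trace; restricting the search to 5 ms (the transient peaks within
  ~2 ms) keeps that bias matched to the correction, which is calibrated
  on a 10 ms window. For noise-dominated sub-threshold steps the two
  nearly cancel, so the corrected I–V decays to ≈0 below threshold.
* **Persistent density**: mean over the closed window [20 ms, 25 ms]
  after depolarisation, divided by capacitance, read at the 0 mV step.
  A window *mean* is unbiased under zero-mean noise, so the
  extremum-bias correction is deliberately **not** applied here —
  applying it would introduce, not remove, a bias of ~half the
  peak-to-peak noise (~25% of the signal at study noise).
* **Activation fits**: peak I–V → conductance `G(V)=I/(V−E_rev)` →
  normalised → Boltzmann fit with a **free amplitude**. Traces are
  post-filtered at 1 kHz (zero-phase 4-pole Butterworth) before peaks
  are read, as is standard when resolving small currents; the filter
  attenuates every step's transient by a common factor that the free
  amplitude absorbs. The free amplitude also removes the bias from
  normalising at a finite maximal voltage (m∞(+30) ≈ 0.985 ≠ 1).
* **Inactivation fits**: test-pulse amplitudes normalised to the
  −120 mV prepulse, fitted with a **free amplitude and floor**. The
  persistent component leaves a pedestal ≈ p that a fixed-form fit
  would fold into V½ and k. Amplitudes are read as the mean over the
  first 2 ms of the test pulse ("early mean") rather than a raw
  extremum: the window mean is exactly an affine function of prepulse
  availability h∞ (absorbed by the free amplitude/floor) and unbiased
  under noise, whereas a raw minimum over thousands of noisy samples
  carries a current-dependent selection bias that tilts the fitted
  slope by several percent. `inactivation_curve` also offers the
  conventional `amplitude="peak"` reading, which is exact on noiseless
  data.
* **Fit numerics**: single lmfit Boltzmann model, V½ initialised from
  the interpolated half-maximum crossing, |k| from a quarter of the
  0.25→0.75 crossing span, bounded to [1, 50] mV with the sign fixed by
  curve kind; convergence is reported, never silent.
* **Window current and availability**: pointwise `m∞·h∞` on a grid
  (peak location provably between the two V½ values), and per-cell
  `h∞(V_m)` at the reported resting potential −18.9 mV, averaged over
  cells. Published per-cell availabilities (1.9/4.9% at pH 7.2/6.2;
  2.1/10.3% at 7.2/6.0) come from the ten largest-current cells of the
  measured cohorts, whose individual fits are not published; evaluating
  h∞ at the cohort-mean parameters instead gives ≈0.07% and ≈1.0%, so
  these numbers are documented here but are not recovery targets.

## Stoichiometric acidification model

At steady intracellular Na⁺, the persistent influx is balanced by NKA
export at 3 Na⁺ per ATP. Glycolytic fermentation yields 2 ATP and 2
lactate per glucose; coupled to ATP hydrolysis this nets **one H⁺ per
glycolytic ATP** (the constructor rejects stoichiometries violating
`h_per_atp = lactate_per_glucose / atp_per_glucose`). The chain is

```
ECAR = |I_pers|·C_m / F / 3 · cells_per_well / volume / β · 60  (pH/min)
```

with β a single lumped buffering power (mol·L⁻¹·pH⁻¹) — appropriate
for the bicarbonate-free assay medium in which ECAR is reported in
mpH/min; no CO₂/bicarbonate chemistry and no oxidative-ATP model (the
channel blocker leaves oxygen consumption unchanged).

Defaults: 3.0×10⁴ cells per well, 180 µl assay volume, 20 pF, and
**β = 1.65×10⁻⁴ mol/L/pH**. The buffering power is the one constant of
the published calculation not printed in the main text; it is recovered
algebraically by inverting the published 1.3 mpH/min result given the
other stated constants, and sits in the range expected for weakly
buffered assay media (~0.17 mM/pH). With these defaults the chain
yields 1.298 mpH/min from −0.31 pA/pF.

The measured comparator uses the plate estimator: per well, the mean of
the last six timepoints (all of which must fall ≥15 min after
injection, outside the injection-artefact window); the effect is
mean(control) − mean(treated), with SEM over experimental repeats
(plates).

## Feedback model

Scalar extracellular-pH state:

```
d(pH_e)/dt = r·(pH_bath − pH_e) − g·ECAR(I_pers(pH_e))/1000
```

`I_pers(pH_e)` interpolates the two measured anchors (−0.31 pA/pF at
pH 7.2, −0.71 at 6.2) — linear in pH by default, clamped flat outside
[6.0, 7.4] to avoid extrapolation; a log-[H⁺]-linear alternative is
provided, since two points cannot identify the functional form. The
loop is closed through persistent current density only; an
availability-based modulation is not stacked on top because both
published effects derive from the same current change and combining
them would double-count. Single compartment, no spatial
core/periphery diffusion (the measured spatial pH gradient motivates
the model but is not simulated).

No relaxation rate `r` or gain `g` is published; both are user-supplied
and results are comparative statics. The steady state solves
`pH* = pH_bath − g·ECAR(pH*)/1000/r` by damped fixed-point iteration
(stop when the damped step < 1e-12, giving |pH − G(pH)| ≪ 1e-9 even
near |G′| → 1) with a Brent fallback on the guard interval
[5.5, pH_bath]; a numerical contraction check (|G′| < 1) asserts local
uniqueness. Dynamics use fixed-step classical RK4; a breach of the pH
guard [5.5, 8.0] raises, flagging step-size instability. The
amplification ratio divides the closed-loop acidification by the
open-loop value obtained with the current pinned at its bath-pH level;
it is ≥ 1 whenever the current map is non-increasing in pH.

## Calibrations

* **pH microelectrodes**: junction-potential offsets are measured every
  block of at most 12 tissue measurements and held piecewise-constant
  within a block (no interpolation — each offset is an empirical
  reading). A straight line is fitted by OLS to the offset-corrected
  voltage/pH calibration points and inverted analytically. Voltage is
  regressed on pH by default; the direction is configurable because
  with only 2–3 calibration points the choice is invisible, but with
  more noisy points the two regressions differ.
* **BCECF**: per-cell two-point line through the nigericin-clamped
  ratios at pH 7.0 and 8.0 (two points admit no other form), inverted
  at the resting ratio; the cohort value is the mean over cells. The
  per-cell map makes the calibration exact for any monotone dye
  response, heterogeneous loading included.
* **SBFI**: per-wavelength background subtraction before the 340/380
  ratio, five-well means per plate, treated/vehicle fold per repeat.
  Background subtraction is what makes the fold estimator unbiased;
  the uncorrected ratio is provably compressed towards 1. All ratio
  estimators are invariant to a common gain on both wavelengths.

## Allred scoring

Proportion bins follow the printed strict inequalities "<1/100" and
">2/3" with interior boundaries fixed by the declared convention
1/100 → 2, exactly 1/3 → 3, exactly 2/3 → 4, i.e. bins
0 / (0,1/100) / [1/100,1/10) / [1/10,1/3] / (1/3,2/3] / (2/3,1].
The printed labels do not state the boundary convention, so this is a
decision, documented and covered by boundary tests. Zero proportion
with nonzero intensity is rejected as inconsistent.

## Synthetic study conditions

The reproduction battery (`navloop.reproduce`, `scripts/acceptance.py`)
simulates at the sizes of the corresponding experiments: cohorts of 10
cells (11 for the peak comparison), three flux plates of six treated
and six control wells with a −9.8 mpH/min step, well noise SD
1.5 mpH/min, and a −5 mpH/min injection artefact decaying within
15 min; six fluorescence repeats of five wells with nonzero
per-wavelength backgrounds and 2% read noise; nine slice series of 12
alternating core/periphery measurements on a −58 mV/pH electrode with
2 mV/block offset drift and 0.5 mV read noise.

Per-cell biological jitter around the cohort-mean channel parameters is
V½ 1.5 mV, k 0.5 mV, peak density 1.0 pA/pF, persistent density
0.05 (pH 7.2) / 0.08 (pH 6.2) pA/pF, capacitance 2 pF; per-slice
regional pH spread is 0.3. These spreads are set deliberately below
the spread of published cohort statistics, which fold seal quality and
measurement error in on top of biology; the trace/read noise above
models the measurement side separately. Parameter-recovery checks
compare each cohort estimate with the realised generator truth of that
cohort (the mean of its drawn per-cell truths) within two cohort SEM.

**What passing tests show, and what they do not.** The synthetic data
exercise every estimator against a known truth, including the
bias-relevant artefacts (extremum-selection noise bias, P/6 noise
amplification, baseline channel current, injection artefacts,
electrode drift, fluorescence background). They do not emulate
series-resistance error, capacitive transients, correlated (1/f or
mains) noise, rundown or drift within a recording, cell-to-cell
correlation between gating and density, or proprietary file formats —
recovery on this generator is therefore a necessary, not sufficient,
condition for accuracy on real recordings.

## Known limitations

* The forward model's Boltzmann m∞ never reaches exactly zero, so even
  "shut" channels pass ~1e-3 pA/pF at strongly hyperpolarised
  potentials; pipelines and the density inversion account for this, but
  naive comparisons of raw traces to idealised currents will see it.
* The peak-density estimator retains a small (+0.2–0.4 pA/pF at study
  noise, i.e. ~2%) conservative bias towards zero: the half
  peak-to-peak correction is calibrated for flat small currents and
  overcorrects sharp transients. This mirrors the correction's stated
  conservative purpose and stays well inside cohort error.
* The feedback model's rate constants are not identifiable from the
  published measurements; only signs, orderings, and the amplification
  mechanism are meaningful outputs.
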