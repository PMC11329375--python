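# navloop

Quantitative toolkit for the positive-feedback loop between the
voltage-gated sodium channel **Na_v_1.5** and extracellular
acidification in breast cancer cells.

Breast carcinoma cells (notably triple-negative lines such as
MDA-MB-231) carry a small, non-inactivating **persistent Na⁺ current**
through Na_v_1.5 at their depolarised resting potential. That steady
Na⁺ influx must be pumped back out by the Na⁺/K⁺ ATPase (NKA) at a cost
of one glycolytic ATP per three Na⁺, and each glycolytic ATP nets one
exported H⁺ — so channel activity translates stoichiometrically into
extracellular acidification. Acidic extracellular pH in turn shifts the
channel's steady-state inactivation depolarised, enlarging the window
current and the persistent Na⁺ influx: a positive feedback loop that
concentrates acid (and invasion-permissive protease activity) at the
tumour's proliferating edge.

`navloop` implements every quantitative step of that chain as a tested,
reusable library with a CLI:

* **`navloop.synthetic`** — forward models for whole-cell voltage-clamp
  sweep families (instantaneous Boltzmann activation `m∞(V)`,
  exponentially relaxing inactivation `h(t) → h∞(V)` with τ ≈ 1.5 ms, a
  persistent fraction `p` that never inactivates, ohmic leak, P/6
  sub-records, Gaussian noise), extracellular-flux (Seahorse-style)
  plates, ratiometric plate fluorescence, and drifting pH-microelectrode
  series — all from declared ground truth, with closed-form inversion
  from target current densities to channel parameters.
* **`navloop.ephys`** — P/6 leak subtraction, half peak-to-peak noise
  correction, peak and persistent (20–25 ms window) current densities,
  conductance and availability curves, signed-slope Boltzmann fits
  `y = 1/(1+exp((V½−V)/k))`, window current, and channel availability
  `h∞(V_m)` at the resting potential.
* **`navloop.ecar`** — the stoichiometric chain
  `I_pers·C_m → Na⁺ flux → ATP demand (÷3) → H⁺ efflux (×1) → mpH/min`,
  plus the plate-based effect estimator (per-well mean of the last six
  timepoints, injection-artefact window excluded) and an
  order-of-magnitude comparison.
* **`navloop.feedback`** — the loop closed as a scalar pH_e model
  `dpH_e/dt = r(pH_bath − pH_e) − g·ECAR(I_pers(pH_e))/1000`, with
  damped fixed-point/bisection steady states, RK4 dynamics, and a
  closed-vs-open-loop amplification ratio.
* **`navloop.calibration`** — pH-microelectrode straight-line
  calibration with per-block junction-potential offsets, per-cell
  two-point (pH 7.0/8.0 nigericin) BCECF calibration, and
  background-subtracted SBFI 340/380 fold changes.
* **`navloop.ihc`** — modified Allred scoring (proportion bin 0–5 +
  intensity 0–3; totals ≤3 "low", ≥4 "high").

## Worked example

Simulate a ten-cell cohort at extracellular pH 7.2, run the full
patch-clamp pipeline, and chain the recovered persistent current into
the acidification prediction and the feedback model:

```python
import numpy as np
from navloop import synthetic as syn, pipelines as pl
from navloop.ecar import predict_ecar, order_of_magnitude_check
from navloop.feedback import FeedbackParams, steady_state, feedback_amplification

recs, truths = syn.make_cohort(7.2, "activation", n_cells=10, seed=42, increment_mv=5)
pers = pl.persistent_cohort(recs, step_mv=0.0)      # 20-25 ms window, 0 mV step
peak = pl.peak_cohort(recs)                          # corrected peak I-V minimum
v_half = np.array([f.v_half_mv for f in pl.activation_fits(recs)])

pred = predict_ecar(pers.mean())                     # stoichiometric chain
state = steady_state(FeedbackParams(gain=300.0))     # closed-loop pH_e
```

Output (seed 42):

```
persistent current density: -0.30 +/- 0.01 pA/pF
peak current density:       -13.1 +/- 0.3 pA/pF
activation V1/2:            -15.3 +/- 0.5 mV
predicted ECAR:             1.27 mpH/min
Na+ flux per cell:          6.30e-17 mol/s
vs measured 9.8 mpH/min:    ratio 7.7, within an order of magnitude: True
feedback steady state:      pH_e 6.82, persistent -0.46 pA/pF
feedback amplification:     2.010x
```

Reading the numbers: the cohort pipeline recovers the generating
densities and gating parameters (−0.31 pA/pF persistent, −13.5 pA/pF
peak, −15.2 mV activation V½) within cohort error; the recovered
persistent current predicts ≈1.3 mpH/min of Na_v_1.5-dependent
extracellular acidification per well, within an order of magnitude of
the ≈9.8 mpH/min change measured when the channel is blocked; and with
an appreciable loop gain, the pH dependence of the persistent current
roughly doubles the steady-state acidification relative to a
pH-insensitive channel.

The same pipelines are exposed on the command line:

```bash
navloop simulate recording --ph 7.2 --seed 1 --out rec
navloop ephys analyze --recording rec.csv --out fits.json
navloop ecar predict --density -0.31
navloop feedback --gain 300 --sweep 0:300:50 --out sweep.csv
navloop reproduce --seed 1 --out report.json
```

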