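# Methods

## Problem and overall design

Cytotoxic chemotherapy suppresses bone-marrow proliferation and causes
neutropenia, the dose-limiting toxicity of many regimens. The package
builds *individual* forecasting models of daily neutrophil counts under
arbitrary dosing schedules, in two stages:

1. a semi-mechanistic transit-compartment model of haematopoiesis
   (`hemnarx.friberg`) simulates a virtual patient population under
   randomized therapy scenarios (`hemnarx.cohort`);
2. for each patient, a small NARX recurrent network (`hemnarx.narx`) is
   trained on five scenarios, validated on two and tested on eleven,
   using transfer learning from one deliberately extreme "index" patient,
   square-root weight regularisation and BIC-controlled magnitude pruning
   (`hemnarx.training`).

Because the original clinical trial data cannot be redistributed, the
sparse-data retraining mode is exercised on a synthetic stand-in patient
(see *Synthetic fixtures* below).

## The haematopoiesis model

Five compartments: proliferating cells `Prol`, three transit
(maturation) compartments `T1..T3`, circulating cells `Circ`
(units 1e9 cells/L):

    dProl/dt = ktr·Prol·(1 − Edrug)·(Circ0/Circ)^γ − ktr·Prol
    dTi/dt   = ktr·(T(i−1) − Ti)
    dCirc/dt = ktr·(T3 − Circ)

with `ktr = 4/MTT` (three transit compartments, so the mean maturation
delay equals MTT). The feedback term `(Circ0/Circ)^γ` raises
proliferation when circulating counts fall below baseline. Drug effect is
Michaelis–Menten, `Edrug = Emax·Conc/(EC50 + Conc)`, with `EC50` fixed at
5.2 mg/L for the whole population (it is poorly identifiable against γ and
Emax). Drug concentration follows a one-compartment model: each
administration is a three-day zero-order infusion with first-order
elimination.

Numerical choices:

- LSODA (stiff/non-stiff switching) at rtol 1e-8 / atol 1e-10, integrated
  piecewise between infusion start/stop times where the right-hand side
  has kinks; daily output on integer days 0..299. A fixed-step RK4
  integration at dt = 0.001 d agrees to < 1e-4 relative error (tested).
- The feedback term clips `Circ` at 1e-6 (and logs the event) because
  `(Circ0/Circ)^γ` diverges as `Circ → 0`; the clip is never reached under
  the study's dose range.
- Calibration (`FribergCalibrator`) minimises squared error between log
  simulated and log observed counts over (γ, MTT, Emax, Circ0) with
  bounded multi-start least squares (default 5 seeded starts, bounds =
  population ranges widened ×2). Noise-free synthetic series are recovered
  to < 1 % relative error; under 5 % lognormal noise the median MTT error
  over 20 replicates stays below 15 % (tested).

Parameters whose published values are not recoverable from the source are
configuration defaults, not ground truth: etoposide elimination half-life
7 h, distribution volume 25 L/m² (doses are expressed per m² so body
surface area cancels), baseline `Circ0` = 5.0e9/L, and the neutropenia
grade thresholds (CTCAE convention: 2.0 / 1.5 / 1.0 / 0.5 × 1e9/L).

## Virtual population and therapy scenarios

The population is the full factorial grid of 8 × 8 × 8 = 512 parameter
combinations: γ equidistant in [0.1, 0.25], MTT equidistant in a
configurable range, Emax log-equidistant in [0.785, 3.14]. The MTT range
default is [3, 8] days — physiological transit times for cytotoxic-drug
myelosuppression models cluster around 3.5–5.6 days and the range widens
them symmetrically; the published range is not recoverable. The index
patient (transfer source) is γ = 0.33 (above the population maximum, for
deliberately extreme dynamics), Emax = 1.57, MTT at the grid maximum.

Eighteen scenarios of six administrations each are generated from a seed:
first dose day uniform on [28, 60] (keeping the network's warm-up window
drug-free), later gaps uniform on [7, 35] days (≥ one week apart), doses
continuous-uniform on [0.25, 4] × 375 mg/m², last infusion ending by
day 290. Scenarios 1–5 train, 6–7 validate, 8–18 test. The published
scenario table is not available; the seeded generator is the normative
replacement, so all scenario-dependent quantities reproduce in
distribution, not value-for-value.

## The NARX network

One hidden layer, linear output, no bias terms:

    ŷ_t = w_out · act( W_h · [ŷ_{t−1}..ŷ_{t−ny}, u_{t−1}..u_{t−nu}] )

The bias-free convention is pinned by the selected architecture's weight
count: 4·(21+28) + 4 = 200 exactly. Lags are ordered most-recent-first.
The input `u` is the daily drug effect scaled by the patient's Emax (the
analytic supremum of `Edrug`), so u = 1 means full suppression. Outputs
are log counts standardised per patient to zero mean / unit variance
using the training scenarios only. In closed-loop (parallel) operation
the first `ny` outputs are observed data; where no observed prefix
exists, the scaled baseline value is repeated (counts are constant before
the first dose by construction). Input lags reaching before day 0 are
zero (no exposure before the series starts).

## Training, regularisation, pruning, transfer

The objective is the mean closed-loop MSE over training scenarios
(warm-up prefix excluded) plus `α · Σ√|w|` with α = 3e-4. The square-root
penalty follows the stated design intent of driving small weights to zero
faster than L1/L2 would; an L1 fallback is available (`penalty="l1"`).
The subgradient at w = 0 is taken as 0, and |w| is floored at 1e-4 inside
the gradient to bound it.

Gradients backpropagate through the full unrolled 300-day closed-loop
recursion (no truncation — sequences are short, and a truncation option
would be dead code). Optimisation is Adam with early stopping on the
validation objective (restore-best). Defaults: learning rate 1e-2,
patience 300 epochs, ≤ 8000 epochs for the initial phase. These values
were chosen for convergence quality: at 1e-3 the optimiser is still far
from the loss floor after 8000 epochs on the index patient.

After the initial plateau, a **fine-tuning phase at one tenth of the
learning rate** runs before pruning starts, and every prune-step retrain
also uses the decayed rate (patience 100, ≤ 2000 epochs). This matters
numerically: near a plateau Adam's normalised steps keep unimportant
weights jittering at the order of the step size, so without decay they
never fall below the prune thresholds the penalty is meant to push them
under.

Model selection: `BIC = 2·nLL + k·ln(Ntr + Nval)` where k counts
*non-zero* weights (recomputed at every step), σ is profiled on the
training residuals, and Ntr/Nval count evaluated days only (the warm-up
prefix contributes zero residual by construction; including it would
shift every BIC by the same amount and is a flagged, immaterial
convention). Pruning thresholds grow geometrically, δ_k = 0.001·1.1^k;
each step zeroes weights with |w| < δ_k (masks are permanent), retrains
to plateau, and the loop stops at the first step whose BIC fails to
improve on the best so far; the best-BIC model is returned. A threshold
that removes no weight leaves the model unchanged; such steps advance the
schedule without re-evaluating the (tied) BIC, otherwise the loop would
halt as soon as a gap in the weight-magnitude spectrum exceeds one 1.1×
increment.

Transfer learning warm-starts each population patient from the index
patient's weights *and mask*; pruning then continues from δ_0, so an
individual's wf can only shrink relative to the index model. Each
patient's data are scaled with that patient's own scaler.

Sparse-data retraining (the clinical mode) takes a transfer-trained
model, applies one static prune at δ = 0.003, freezes the mask, and runs
Adam at a low rate (1e-4) with the loss evaluated only at observed days.

Hyperparameter search is a seeded random search (neurons 2–12, memories
14–42 days, α log-uniform 1e-7–1e-1, activation ∈ {sigmoid, tanh, linear,
relu}) scored by index-patient BIC after plateau training — a
reduced-budget version of the original search; the shipped defaults
(4 neurons, ny = 21, nu = 28, sigmoid, α = 3e-4) are the selected
configuration and are used everywhere.

The small-network backprop (closed-loop forward pass and reverse-mode
adjoint) is implemented directly over numpy arrays with numba kernels;
with ~200 weights and 300-day sequences an epoch costs well under a
millisecond, which is what makes the population runs cheap.

## Problem sizes used by the shipped experiments

- Index patient: full 18-scenario training, repeated over 3 seeds.
- Population transfer: a seeded 3 × 3 × 3 sub-grid (27 patients) using
  fixed axis indices {0, 4, 7} — minimum, middle and maximum of each
  8-point axis — so correlation estimates see the full parameter range.
  The full 512-patient factorial run is supported
  (`transfer_population(..., patient_ids=None)`) and takes proportionally
  longer (~6 s per patient after the one-off numba compilation).
- Acceptance reproduction (`scripts/acceptance.py`) uses exactly these
  sizes and reports them in its output.

## Synthetic fixtures and what passing tests show

- `toy-narx-planted`: series generated by a known 5-weight NARX network;
  training recovers MSE < 1e-3 with a comparably sparse network. Shows
  the optimiser/pruner can identify a planted sparse model, not that real
  dynamics are identifiable.
- `two-cycle-patient`: a synthetic stand-in for a real patient on a
  21-day cycle (six equal standard doses starting day 28), observed
  roughly twice a week with 10 % lognormal noise. The generating model
  uses **five** maturation compartments while the calibration model has
  three: real patients are never inside the calibration model class, and
  this structural mismatch leaves the cycle-stationary residual pattern
  that sparse retraining is supposed to pick up. With an in-class
  generator the calibrated mechanistic model is already near-optimal and
  retraining can only chase noise — the experiment would be vacuous.
- `mini-population`: the 27-patient sub-grid above.

The virtual data share none of the irregularities of clinical counts
(measurement dropout, infections, G-CSF rescue, inter-cycle drift), so
green tests demonstrate the machinery reproduces the simulation study,
not clinical performance.

## Known limitations

- Single drug-effect input channel; no multi-drug pharmacokinetics, no
  G-CSF or supportive-care modelling, no body-size covariates.
- Pruned weights are never reactivated.
- Scenario-dependent results reproduce only in distribution (the original
  scenario table is not available).
- MSE figures are on the standardised-log scale and depend on the
  per-patient scaler; they are not comparable across differently scaled
  data.
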