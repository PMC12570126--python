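# Methods

## Circuit model

The Giant Fiber (GF) → TTMn pathway is modelled as four iso-potential
Hodgkin–Huxley compartments. Compartment 0 receives the stimulus current;
compartments 0–1 and 1–2 are coupled by a symmetric axial conductance
`g_axial` (currents `g_axial·(V_i − V_j)`); compartment 3 (the motoneuron)
is driven from compartment 2 through the mixed electrochemical synapse.
Each compartment carries

    C_m dV/dt = −(I_Na + I_K + I_L + I_syn) + I_stim

with the canonical current forms I_Na = g_Na·m³h·(V − E_Na),
I_K = g_K·n⁴·(V − E_K), I_L = g_L·(V − E_L) and reversal potentials
E_Na = 65 mV, E_K = −74 mV, E_L = −85 mV. Gating variables relax first-order
toward Boltzmann steady states x_∞(V) = 1/(1 + e^{(V½−V)/k}) with
(V½, k) = (−53, 15) for n, (−40, 15) for m and (−62, −7) for h, and
Gaussian-bump time constants

    τ_n = 1.1 + 4.7·e^{−((−79−V)/50)²}   τ_m = 0.04 + 0.46·e^{−((−38−V)/30)²}
    τ_h = 1.2 + 7.4·e^{−((−67−V)/20)²}   (ms; V in mV).

The current exponents (m³h, n⁴) and the maximal conductances are not part
of the published parameter set; the exponents are the standard HH choice
and the conductances are package calibration products (below).

### Synapse

Chemical component: gate fraction `s` with
ds/dt = ((1 + tanh(V_pre/4))/2)·(1−s)/τ_rise − s/τ_decay,
τ_rise = 0.1 ms, τ_decay = 3 ms, and current
I_chem = g_syn·s·(V_post − V_syn) with g_syn = 0.1 (model units) and
V_syn = 0 mV (excitatory). Electrical component: ohmic coupling
I_gap = g_gap·(V_post − V_pre) applied to the motoneuron, with the exact
negative applied to the presynaptic compartment (charge conservation is
asserted in tests). The biological junction rectifies; an optional
rectified mode (conduction only when the presynaptic side is depolarized)
is provided but off by default, because the model equation being
reproduced is ohmic with s = 1.

Gap-junction conductance is read off the anatomical proxy `p` (% of
terminal volume occupied by gap-junction antibody label):

    g_gap(p) = L_min + (L_max − L_min)/(1 + e^{−k_sig·(p − x₀)})

with overrides g_gap(0) = 0 (no channels → no coupling) and
g_gap = L_max for p > 10% (saturation; at exactly p = 10% the sigmoid
value applies — the override is read as a strict inequality).

### Units

Voltages are mV and time is ms throughout. Currents and conductances are
"model units": only their ratios to C_m and to each other matter, matching
the convention in which g_syn = 0.1 is quoted without units.

## Numerical scheme

Forward Euler with a default step of dt = 0.01 ms. The published
description quotes a 1 ms step, which cannot be meant literally: τ_m
reaches 0.04 ms at its peak, making explicit Euler at 1 ms unstable by two
orders of magnitude; the bracketed 10 ms and 100 ms figures quoted with it
are read as the protocol durations (single-pulse and train runs,
respectively), which is how this package uses them. dt is configurable and
a convergence test asserts that halving it changes the noise-free latency
by under 2%.

Forward Euler is first-order: at dt = τ/20 the gating trajectory deviates
from the closed-form exponential by ~0.5–2% at intermediate times and
converges to x_∞ exactly; tests assert 3% pointwise tracking and 10⁻³
relative agreement after 10 e-folding times.

Other numerical choices:

* **Initial state** — each compartment starts at its resting fixed point
  (solved by bracketed root-finding on the steady-state current balance,
  gates at x_∞), so latency measurements carry no onset transient.
* **Spike detection** — upward crossing of 0 mV with a 2 ms refractory
  window; both configurable.
* **Latency** — time of the compartment-3 voltage peak minus that of the
  compartment-0 peak within the first-stimulus window; the peak sample is
  refined by a 3-point parabolic fit so latency is not quantized to the
  integration grid; equal maxima resolve to the earliest sample. If
  compartment 3 never spikes in the window, latency is a failure flag
  (`None`), never a number.
* **Response frequency** — a compartment-3 spike is attributed to the
  latest stimulus onset preceding it within one inter-stimulus interval
  (10 ms at 100 Hz); each onset counts at most one response; reported as
  % of onsets answered.
* **Divergence** — any non-finite or |V| > 500 mV state aborts the run
  with a diagnostic naming the compartment and time.

## Calibration of unpublished parameters

The source model's maximal conductances, C_m, axial coupling, sigmoid
constants (L_min, L_max, k_sig, x₀) and stimulus amplitude are not
published. They are treated as explicit configuration with defaults fixed
by the package's own calibration:

* Membrane: C_m = 1, g_Na = 50, g_K = 20, g_L = 2. The leak must be this
  strong because the shallow m-activation slope (k = 15 mV) produces a
  sizeable sodium window current; a classic 0.3 leak cannot hold the
  resting potential near E_L. At these values the resting potential is
  −84.6 mV and a suprathreshold pulse elicits exactly one spike.
* Stimulus: 1 ms pulses of amplitude 300 (model units), first onset at
  1 ms, plus zero-mean unit-SD Gaussian noise on every sample (the noise
  SD is the published "unit variance"; its strength relative to the pulse
  is otherwise unconstrained and is kept at 1).
* Circuit: g_axial = 6, chosen so the spike propagates 0→2 fast enough
  for a sub-millisecond end-to-end latency.
* Gap map: L_min = 0.01, L_max = 2.0, k_sig = 1.25 per %, x₀ = 6.2%.
  These place the measured genotype occupancies across the circuit's
  following-threshold transition: control-level occupancy (9.04%) lands in
  the saturating regime (g_gap ≈ 1.94, latency ≈ 0.75 ms, 100% following),
  the loss-of-function occupancy (5.31%) lands mid-transition (≈60%
  following — the response-decrement regime), and 1% occupancy (a
  gap-junction-null-like state) falls below threshold, leaving only the
  weak chemical component (g_syn = 0.1), which alone cannot fire the
  motoneuron.

`circuit.calibrate` re-derives such a configuration by deterministic grid
search over (pulse amplitude, g_axial, L_max), accepting the first grid
point whose seeded metrics meet the functional criteria: mean latency
< 1.00 ms and mean following ≥ 90% at p = 9.04%, and following ≤ 60% at
p = 1%. Infeasible criteria produce a report with the best metrics found,
never an exception.

## KS2D2S statistic

Genotype comparisons pair a physiological measure with the anatomical one:
(latency, gap-junction %) and (following %, gap-junction %). The
two-dimensional two-sample KS test uses the sample-point variant: for
origins at each data point of a sample, the maximal difference between the
two samples' open-quadrant fractions is taken, and D is the mean of the
two per-sample maxima. Points exactly on a quadrant boundary (including
the origin itself) count toward no quadrant; continuous data make such
ties measure-zero. D is symmetric, lies in [0, 1], and is invariant under
strictly monotone per-coordinate transformations applied jointly to both
samples — all asserted by tests against an independent brute-force
implementation.

The default p-value is the Fasano–Franceschini analytic approximation,
Q_KS(λ) with λ = D·√n_eff / (1 + √(1−r̄²)·(0.25 − 0.75/√n_eff)),
n_eff = n₁n₂/(n₁+n₂) and r̄ the mean Pearson correlation of the two
samples. The approximation is accurate in the decision-relevant small-p
regime and conservative-to-inaccurate for p ≳ 0.2; a seeded
label-permutation test (add-one estimator) is available as the exact
reference and is validated for type-I error calibration. Comparisons are
reported unadjusted: each genotype-versus-reference contrast is a
separate, independent test by design, so no multiplicity correction is
applied.

## Synthetic data generator

The generator emulates the study's unit-terminal tables: one row per
terminal with genotype, fly, side, phenotype class, latency (ms),
following frequency (%), and gap-junction occupancy (% terminal volume).
Per genotype, the three measures are drawn from a trivariate Gaussian and
clamped to their physical ranges. Two modelling choices matter:

* **Censored-moment matching.** Published group statistics describe
  range-limited data (following frequency has a hard 100% ceiling that
  wild-type groups sit against). Drawing from a Gaussian with the
  published moments and clamping would bias such groups, so the latent
  Gaussian parameters are obtained by inverting the censored-normal
  moment map per coordinate; the clamped output then reproduces the
  published mean and SD (verified to 4 standard errors at n = 10⁴). The
  clamped fraction is logged.
* **Correlation structure.** Lower occupancy goes with longer latency and
  worse following; the published record states the direction but no
  coefficients. Defaults are ρ(latency, gj) = −0.5 and
  ρ(following, gj) = +0.5, with ρ(latency, following) set to their
  product, which guarantees a positive semi-definite matrix for any valid
  pair. All three are configurable per genotype.

Genotypes whose group statistics were never published (e.g. the
gap-junction occupancy of the full-length-rescue group, all stats of the
ablation controls) carry assumed values consistent with the study's
qualitative descriptions; each such field is listed in the spec's
`assumed_fields` so downstream users can exclude them. Bilateral-terminal
fractions follow the reported phenotype frequencies (≈0.45 for
loss-of-function backgrounds, 0 for controls); the phenotype label does
not shift the generating distributions, matching the finding of no
functional separation between wild-type-appearing and bilateral terminals.

What the generator does **not** emulate: fly-level clustering of left and
right terminals (terminals are independent draws, as in the study's
unit-terminal statistics), non-Gaussian marginal shapes, and any
measurement error structure. Passing tests therefore demonstrate that the
pipeline recovers and compares *this* distributional family correctly,
not that the family matches the raw measurements in detail.

## Problem sizes

Default protocols are 10 ms (single pulse) and 100 ms (100 Hz train) at
dt = 0.01 ms — 10³–10⁴ Euler steps per run. Sweeps use 10 seeded
repetitions per occupancy; the permutation reference uses 199–10⁴
permutations depending on context; type-I calibration uses 1,000 null
replicates of 20-vs-20 samples. These sizes make the full test suite and
the acceptance script run in minutes on one core.

## Known limitations

* The gap junction is ohmic by default although the biological junction
  rectifies; the rectified mode changes only which side's depolarization
  opens the path, not the headline metrics at calibrated defaults.
* Terminal morphology (bilateral vs wild-type-appearing) has no
  biophysical counterpart in the four-compartment chain; it exists only
  as a label in the synthetic tables.
* The calibration criteria constrain the model at three occupancy points;
  between them the decrement curve's exact shape is a consequence of the
  sigmoid placement, not an independently fitted quantity.
* The analytic KS2D2S p-value should not be trusted above p ≈ 0.2; use
  the permutation mode when the decision is not clear-cut.
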