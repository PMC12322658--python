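# Methods

## Process model

The batch model tracks three dynamic states — cell density `c_b`
(arbitrary OD units), intracellular reporter protein `c_p` (arbitrary
fluorescence units) and glucose `c_g` (g/L) — under Monod growth,
growth-coupled saturating production, constant first-order degradation and
growth-proportional substrate uptake (see README for the equations).  EL222
copy number `n` is formally a fourth state with zero derivative; because it
is constant per strain it is carried alongside the integrated states rather
than wasting a solver dimension, and every trajectory reports it unchanged.

OD and fluorescence are left in instrument units throughout: the model's
claims are about dynamics and dose response, not absolute protein mass.
Glucose is in g/L, time in hours.  The substrate is labeled generically
("substrate uptake") — the kinetic form is carbon-source-agnostic, and the
package takes no position on glucose-vs-glycerol datasets.

The six kinetic parameters are functions of the experimental condition
(light intensity `I` in μmol m⁻² s⁻¹, copy number `n`); the package
estimates them per condition and then learns the maps `θ_i(I, n)` with
Gaussian processes — a hybrid model: mechanistic backbone, data-driven
parameter surfaces.

## Numerical integration

`simulate` uses scipy's LSODA (stiff-capable, adaptive) with rtol 1e-8 /
atol 1e-10 by default and an analytic 3×3 Jacobian.  The Monod form keeps
glucose analytically nonnegative, so there is no event handling; output
undershoots of `c_g` within `10·(atol + rtol·max|y0|)` (the solver's
local-error scale) are clamped to zero and anything more negative raises.
`c_g + Y_gb·c_b` is a linear invariant of the flow; the suite checks it is
preserved to integration tolerance (drift ≤ `10·(atol + rtol)·(1 + value)`)
on random parameter draws.  Calibration uses looser per-evaluation
tolerances (rtol 1e-6) for speed; final reported trajectories use defaults.

## Photometry

Per-OD fluorescence subtracts a media blank from both the strain and a
non-fluorescent wild-type control and divides each by its blank-corrected
OD before differencing; the result is invariant to any common additive
fluorescence offset and may be negative for sub-control wells (no
clamping — that is a caller decision).  Total fluorescence subtracts the
wild-type control directly.  Photon flux → irradiance uses CODATA
constants exactly; display rounding is left to callers.  The plate reader's
linear range is handled by flagging OD above a configurable threshold
(default 8), not by correcting it.  The table reader supports one blank per
condition tag, which covers both a single shared blank and time-paired
blanks (encode the time point in the tag); the package does not assert
which scheme a given dataset used.

## Per-condition calibration

The objective is a relative least-squares: for each channel (OD,
fluorescence) residuals between the simulated trajectory and all replicate
observations are pooled and divided by the channel's pooled mean-square
observation, so channels with different magnitudes (OD ~0.1–20,
fluorescence ~1e3–1e5) contribute comparably.  Replicates are fitted
jointly, not averaged, preserving the noise structure.  Initial states come
from the data: OD at the first time point (replicate mean), protein 0 at
induction start (dark pre-growth gives no expression; overridable), glucose
at the measured initial concentration.  Integration failures map to +inf so
the optimizer can route around non-integrable corners of the box.

Search runs in log10-parameter space (parameters are positive and span
orders of magnitude) with a canonical global-best particle swarm
(default swarm 40, 300 iterations, inertia 0.72, c1 = c2 = 1.49, reflecting
bounds, seeded), followed by a bounded Nelder-Mead simplex polish with up
to three restarts.  The polish exists because the (α, β) pair forms a long
flat valley — the data constrain mostly α/(β + μ) over the observed growth
rates — where population search localizes quickly but descends slowly; the
derivative-free simplex finishes the descent (noise-free objectives drop
from ~1e-5 to ~1e-13, all parameters within 0.1 %).  Tests and the
acceptance script run reduced budgets (swarm 16–20, 60–80 iterations,
polish capped at 1500–4000 evaluations), which the recovery checks show are
optimization-converged at the problem sizes used.

### Default bounds and identifiability

Default boxes: μ_max ∈ [0.01, 1] 1/h, k_g ∈ [0.005, 1] g/L,
α ∈ [1, 1e6] a.u./h, β ∈ [1e-3, 0.3] 1/h, d_p ∈ [1e-4, 0.5] 1/h,
Y_gb ∈ [0.1, 10] (g/L)/OD.  The upper bounds on the two half-saturation
constants are deliberately tight: a k_g comparable to the initial glucose
concentration, or a β comparable to μ_max, makes the corresponding
saturating law indistinguishable from a linear one over the observed data
and opens a flat likelihood ridge along which μ_max (with k_g) or α (with
β) drifts arbitrarily under measurement noise — the exact maximum-likelihood
point does the same, so no optimizer can fix it.  The bounds encode the
biological prior instead: yeast glucose half-saturations sit well below
1 g/L, and a production law that never saturates below the observed growth
rates carries no information about β.

Even so, α's estimate at 2 % measurement noise retains a ~15 % typical
error (β and d_p wobble propagate into it); μ_max, Y_gb are recovered to a
few percent wherever the batch completes within the measurement window.
Conditions with negligible growth (high dose × high copy number) identify
almost nothing beyond μ_max ≈ 0; their fitted values scatter and are
treated as noise by the surrogate stage.

## Gaussian-process surrogate

One independent multi-input single-output GP per parameter, Matérn-5/2
kernel with automatic relevance determination (one length scale per
feature), zero prior mean, hyperparameters ρ = (σ_f², ℓ_I, ℓ_n, σ_n²) by
maximizing the log marginal likelihood (L-BFGS-B in log-hyperparameter
space, 8 restarts, box [1e-4, 1e4] in scaled units, seeded; Cholesky with
a jitter ladder 1e-10 → 1e-6).

Scaling choices, all explicit package decisions:

* **Features**: intensity is log1p-compressed, then both features are
  divided by their design maxima (log1p(70), 8).  Dose response is
  Hill-like — steep below ~15 μmol m⁻² s⁻¹, flat above — so on a linear
  axis no single stationary length scale fits; the likelihood then picks a
  short one and posterior means collapse to the prior between the sparse
  high-intensity design points.  On the log axis one length scale serves
  the whole range.  Linear mode is available (`log_intensity=False`).
* **Labels**: modeled in log space and standardized there; predictions
  return exp of the posterior mean (the posterior median) with a
  delta-method variance.  Kinetic parameters are strictly positive and
  scatter multiplicatively, and the occasional order-of-magnitude outlier
  from a weakly identifying condition would dominate a raw-scale GP.
  Raw-label and non-standardized modes are retained
  (`log_labels=False`, `standardize_labels=False`); with raw labels the
  zero prior mean pulls strictly-positive parameters toward 0 off-data,
  which is why standardization is the default.
* **Predictive variance** is that of the latent parameter function;
  `include_noise=True` adds σ_n² for a new-fit predictive variance.
* Copy number is a continuous feature at prediction time (the GP maps
  R² → R); `Condition` itself stores exact integers.
* Non-positive posterior means (possible off-data in raw mode) are floored
  at the calibration box's lower bound with a warning.

The six GPs share the feature matrix and are trained independently — no
cross-parameter covariance.

## Hybrid prediction and the dose landscape

`predict_trajectory` composes the surrogate's posterior-mean parameters
with the ODE solver.  `scan_dose_landscape` evaluates final total protein
(and per-OD protein) after a 24 h batch from OD 0.1 / 10 g/L glucose over
an intensity grid per copy number, and reports the argmax intensity with a
plateau interval: all grid intensities whose objective is within 2 % of the
maximum.  The plateau convention exists because the landscape can be flat
near the optimum — a single argmax point would be spuriously precise.
Intensities outside the training hull are refused unless explicitly
requested (`allow_extrapolation=True`): the zero-mean GP reverts to the
label mean off-data, which makes extrapolated kinetics unphysical.

A caveat the synthetic studies expose: with a fixed 24 h horizon, final
protein depends sharply on whether glucose runs out just before the horizon
(protein decays at d_p once growth stops), so percent-level errors in the
μ_max surface can move the argmax between adjacent grid points.  The
plateau interval, not the point argmax, is the robust summary.

## Synthetic ground truth

The generator emulates the characterization design: 3 copy numbers
(1, 3, 8) × 6 intensities (0, 5, 10, 30, 50, 70 μmol m⁻² s⁻¹) × 3
replicates, measured at 0, 2, 4, 6, 8, 12, 15, 24 h from OD 0.1 in 1 %
(10 g/L) glucose with protein starting at 0.  The truth surface is

* induction: α = α₀ · [leak + (1−leak)·Hill(I; K_I(n), q)] with
  K_I(n) = 15/n μmol m⁻² s⁻¹ (more photosensor → half-activation at lower
  dose), Hill coefficient 2, 5 % dark leak;
* phototoxicity: both α and μ_max are damped by tox = 1/(1 + (I·n/75)²),
  an effective-dose logistic shared by growth and production;
* k_g = 0.5 g/L, β = 0.05 1/h, d_p = 0.02 1/h, Y_gb = 0.55 (g/L)/OD
  constant;
* μ₀ = 0.35 1/h in the dark, chosen so glucose is exhausted within the
  24 h window at the productive conditions — as in the real
  characterization, where growth plateaus and fluorescence then decays
  inside the measured window (this is also what makes Y_gb and the
  depletion-transient parameters identifiable at all).

These defaults put the true production-maximizing intensity near 50 / 17 /
6 μmol m⁻² s⁻¹ for n = 1 / 3 / 8 — the qualitative structure the real
system shows (single-copy strains peak at 50–70, eight-copy strains at
5–10).  Magnitudes are not calibrated to any measured dataset; only this
qualitative structure is asserted.

Measurement noise: multiplicative lognormal (median-unbiased, σ = 2 %) on
OD and fluorescence plus an additive Gaussian fluorescence floor
(50 a.u., plate-reader dark counts).  Per-replicate noise streams derive
deterministically from one master seed; the noiseless means are
seed-independent.

What the generator does **not** emulate: instrument nonlinearity at high
OD, well-to-well position effects, time-varying light (pulsing), secreted
protein, evaporation, or any bioreactor signal.  Passing recovery tests on
these fixtures therefore demonstrates the pipeline's statistical machinery
under the stated noise model, not robustness to real plate-reader
pathology.

## Problem sizes in the test suite

Recovery and end-to-end checks run at swarm 16–20 × 60–80 iterations with
polish budgets of 1500–4000 evaluations, 18-condition designs, and 5
master seeds; the GP stage uses 6–8 restarts.  These sizes were chosen so
the optimization error is negligible against the statistical error at 2 %
noise (verified by comparing against simplex fits started at the truth).

## Known limitations

* α, β, d_p are only weakly identified from OD + fluorescence alone; at
  2 % noise the α estimate's median error sits near 15 % even for the
  exact MLE.  Glucose time courses (not just the initial value) would
  sharpen all of them.
* Conditions with negligible growth return near-arbitrary α, β, d_p, Y_gb
  within bounds; the GP's noise variance absorbs but does not repair this.
* The GP prior mean (label mean in log space) is still a modeling choice;
  extrapolation beyond the design hull is deliberately gated.
* No time-varying light, no fed-batch, no secretion compartment, no
  closed-loop control; intensity is constant within a trajectory.
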