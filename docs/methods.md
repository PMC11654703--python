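# Methods

## Model

`ctxlds` fits a non-probabilistic linear dynamical system jointly to the
condition-averaged population responses of the two contexts of a
contextual evidence-integration task (attend-motion vs attend-color):

    x_k(t) = A_cx x_k(t-1) + B_cx^m u_k^m(t) + B_cx^c u_k^c(t)
    y_k(t) = C x_k(t) + d,        x_k(0) = x0_cx

with latent state `x` (dimension L), observations `y` (N neurons,
z-scored condition-averaged rates), condition `k`, context `cx`.  The
first observed bin is `y(1)`, built from `x(1)`; `x(0) = x0` precedes it,
matching the unrolled convolution form
`x(t) = A^t x0 + sum_{t'=1..t} A^{t-t'} B u(t')`.

Which blocks may differ across contexts defines four model classes —
{A,B}, {A,Bcx}, {Acx,B}, {Acx,Bcx}.  The initial condition is always
per-context; the loading `C`, bias `d`, input time courses and coherence
scalars are always shared.  `C` is orthonormalized post hoc through the
SVD-based similarity transform `T = S V^T` (predictions and eigenvalues
are invariant), so every dynamics analysis can be read in an isometric
latent basis.

### Input parameterization

Per input dimension there is one time course per evidence direction
(toward / away from the response field), shared across the three
coherence strengths of that direction, and six learned signed scalars,
one per coherence level: `u_i(t) = course_i,dir(t) * scalar_i,level`.
Conditions sharing a level share its trace.  The six scalars are learned
**per input dimension** (not per modality): with time-varying courses each
input dimension then contributes `2T + 6` parameters, which is the
reading consistent with the exact parameter counts the package
reproduces (14,605 / 13,215 for the 18- and 16-latent classes at
N = 727, T = 15, 3+3 inputs; the per-modality reading undercounts by 24).
A `time_varying=False` variant pins all courses at 1.

Because of the multiplicative degeneracy between `B` and `u`, every
reported input quantity uses the product `B u(t)`, never `u` alone.

### Objective and optimizer

Cost = reconstruction MSE (equal to the fraction of unexplained variance
on z-scored data) + `lambda_inp * sum_{t,k,cx} ||B_cx u||^2`.  Defaults
follow the reference protocol: ADAM, learning rate 0.009, `lambda_inp =
1e-5`, Gaussian init SD 0.01, minimum 5,000 / maximum 10,000 iterations,
stop when the cost change falls below 1e-5.  Gradients are exact
backprop-through-time expressions of the linear recurrence, written in
closed form (the model is bilinear in its parameter blocks); they are
validated against central finite differences to ~1e-8 relative error in
the test suite.

Numerical choice: the cost-change stopping rule is evaluated over a
100-iteration window rather than between successive iterations.  ADAM
traces show transient plateaus on which single-step differences cross any
threshold spuriously; with successive-step differences we observed stops
at ~2e-3 training MSE on noiseless data that continue to <1e-6 once past
the plateau.  An optional normality penalty `lambda_dyn ||A A^T - A^T
A||_F^2` (with `C` frozen to a previously fitted orthonormal loading)
supports normal-dynamics control fits.

### Tensor factor regression

The TFR factorizes the response tensor per context as
`Y ~= C core T_ind Q_ind P R`: an orthonormal loading, a per-context
core `core[l, lag, channel]` (channels = input dimensions + one baseline),
a fixed causal indicator `T_ind[t, t', lag] = 1 iff t - t' = lag`, a fixed
condition-routing indicator `Q_ind`, coherence scalars `P` (6 per input
dimension + baseline) and direction courses `R` (2 per input dimension +
baseline).  Direction/coherence cell counts use the *real* input
dimensionality (baseline handled by its own single cell), the reading
that reproduces the printed 12,438-parameter count at l = 14, 2+2 inputs.
Setting `core[:, lag, :] = A^lag B` with the baseline channel carrying
`A^(lag+1) x0` (paired with a delta-at-first-bin baseline course)
reproduces an LDS exactly, so the TFR's attainable error lower-bounds any
LDS of the same rank.  The TFR has no per-neuron bias; exact-nesting
comparisons add the LDS bias `d` back on the TFR side.  The core is
causal by construction of `T_ind`.  Default fitting is the same ADAM
protocol on the plain MSE; an alternating reference solver (reduced-rank
regression for `W = C*core` given the input factors, then linear least
squares for `P` and for `R`) cross-checks the gradient route on small
problems.

## Model selection

Leave-one-condition-out cross-validation: a fold removes one
(motion, color) condition from **both** contexts (36 folds on the 6x6
grid), refits, then forward-generates the held-out condition from the
refit `x0` and the coherence inputs identified from the other conditions
that share its levels (each level appears in 5 other conditions).  The
held-out observations never enter a gradient step — corrupting them
provably leaves the fit unchanged (leakage test).  Mean and SEM across
folds are reported per (class, dimensionality) grid point; folds whose
coherence level would vanish from the training set are skipped with a
warning (impossible on the full grid).  One seed per fold by default,
configurable.  Restart summaries average scalar derived quantities
(errors, norms, loads, angles), never raw eigenvectors, which carry
sign/rotation ambiguity.

## Dynamics characterization

* **Eigenmodes** `A = R Lam L`, `L = R^-1`; right eigenvectors unit norm,
  left eigenvectors the rows of `R^-1` (deliberately non-normalized so
  load arithmetic below is exact).  Deterministic ordering: descending
  |lambda|, ties by descending rotation frequency, then positive
  imaginary part first.  Near-defective matrices (eigenvector condition
  number > 1e8) trigger a warning.
* **Time constant** `tau = 50 ms / (-ln |lambda|)` — the 1/e decay time;
  |lambda| = 1 maps to infinity (integration mode); slow modes are
  |lambda| > 0.8 (tau > 224 ms).
* **Rotation frequency** `f = 20 * omega / (2 pi)` Hz at 50-ms bins, with
  omega the nonnegative eigenvalue phase; negative real eigenvalues
  alternate sign each bin and are assigned the Nyquist frequency 10 Hz.
  Histogram categories: <0.25, 0.25–1, >1 Hz.
* **Henrici index** `sqrt(||A||_F^2 - sum |lambda|^2) / ||A||_F` in
  [0, 1]; radicands below 1e-12 (relative) are floored to zero because the
  square root amplifies machine-epsilon cancellation error to ~1e-8.
* **Input loads**: per real mode `|l^T B u(t)|`; per conjugate pair
  `2 ||Re{l^T B u} Re{r} - Im{l^T B u} Im{r}||`, one shared value per
  pair.  The per-group contribution vectors sum to `B u(t)` exactly
  (machine precision), which the suite asserts.  Default report: the
  strongest positive coherence, averaged over the full trial (the
  averaging window is configurable; the reference analysis does not state
  one).
* **Impulse responses** `||x(t)||` from unit perturbations along random
  sphere directions (count = latent dimension, seeded), left
  eigenvectors, or input dimensions.
* **Observability Gramian**: `A^T Q A - Q + C^T C = 0` via the
  discrete Lyapunov solver, residual checked < 1e-8; top eigenvectors of
  `Q` are the most-amplifying directions.  Unstable models (spectral
  radius >= 1) are refused with the offending eigenvalue named.
  Controllability is reported as the rank of `[B, AB, ..., A^{L-1}B]`.
* **CD/CI decomposition**: condition-independent part = across-condition
  mean; condition-dependent part = remainder (sums back exactly); leading
  CD singular vector and unit CI vector per time/context.
* **Alignments**: |dot| with unit right eigenvectors for real modes,
  cosine of the minimum principal angle to the span{Re r, Im r} plane for
  pairs; reported non-negative.  Neuron-space vectors map through `C^T`.
* **Coherence demixing**: regress per-level input vectors on
  (coh, |coh|, 1); the two slope vectors, orthonormalized coherence-first,
  span the demixed plane; a (near-)zero magnitude component collapses the
  plane to 1D and is flagged rather than fabricated.

## Perturbation experiments

State perturbations displace the latent state once at the onset bin along
`C^T v` for an observation-space unit direction `v` (norm default 10,
onset default the first analyzed bin); with orthonormal `C` this is the
unique norm-consistent latent image.  For a linear model the effect
(perturbed minus unperturbed trajectory) is condition independent — the
code asserts this — and scales linearly with the norm.  A response is
*amplifying* when the effect norm rises above its onset value before
decaying; for normal dynamics this is impossible
(`||A^t v|| <= |lambda_max|^t`), so amplification along any data PC flags
non-normal recurrent dynamics.  Input perturbations zero one modality's
inferred input over a window (default 2 bins = 100 ms; the reference
description gives no length).

## Synthetic-data generator

The generator emulates the study's data shape: N neurons x 15 bins
(50 ms) x 36 conditions (6 signed motion x 6 signed color coherence
levels, strengths 0.05/0.15/0.5) x 2 contexts, z-scored per neuron over
all bins/conditions/contexts jointly (population SD; zero-variance
neurons raise by default, optionally dropped).  Defaults are desk scale:
N = 60, L = 8, 2+2 input dimensions — large enough to exercise every
analysis, small enough for seconds-scale fits; the published
N = 727 / L = 18 scale is a configuration choice.

The ground truth realizes a planned eigenvalue multiset exactly
(`A = R Lam_block R^-1`, conjugate pairs as scaled rotation blocks):
default plan 0.98 (near-integrator), 0.9 e^{±0.25i}, 0.85,
0.7 e^{±0.6i}, 0.6, 0.4 — a line-attractor-like slow mode plus slow and
intermediate rotational structure.  `non_normality` shears the eigenbasis
(`R = Q (I + sigma G_upper)`); 0 gives an exactly normal `A`.  Context
regimes: `input-switching` scales the irrelevant modality's input map by
`input_gain_irrelevant` (default 0.3) per context; `dynamics-switching`
redraws the eigenbasis per context (same spectrum); `both`; `none`.
Input courses are smooth transient bumps (rise by ~bin 3, decay after),
slightly later per extra input dimension; coherence scalars are linear in
signed coherence on even dimensions and in centered |coherence| on odd
dimensions, so each modality's realized drive genuinely spans its input
dimensionality and carries the signed/magnitude mixture the demixing
analysis expects.  Observation noise is i.i.d. Gaussian on the rate scale
(default SD 0.1) added before z-scoring.

For the mechanism-contrast experiments, the strongly non-normal regime is
defined as shear 1.5: at this setting every sampled dynamics matrix is
transiently amplifying (largest singular value above 1) with a Henrici
index far from the near-normal regime — both properties are asserted in
the test suite across seeds.  Milder shear produces systems whose
amplification need not be visible along any single data PC, i.e. it does
not reliably realize the regime the contrast is about.

What the generator does **not** model: spiking/trial-level variability
(data are noiseless-dynamics plus Gaussian rate noise), pseudo-population
averaging structure, nonlinear saturation, non-stationary inputs beyond
the bump shape.  Passing tests therefore demonstrate correctness of the
estimation and analysis machinery under the model's own assumptions, not
robustness to the mismatch real recordings would add.

## Numerical choices and limitations

* Z-scoring window: per neuron over all times/conditions/contexts jointly
  (the reference analysis does not state one; this is the natural pooled
  default).
* Eigenvalue-plan slots beyond those specified are filled with uniform
  random real decays in [0.2, 0.6].
* The held-out forward generation uses the refit per-context `x0`
  (condition independent, hence identified without the held-out
  condition).
* Tiny systems (L ~ 3) show optimizer local minima in ~2/3 of inits;
  multi-restart (the standard protocol here) or a fixed converging seed
  addresses this; at L = 8 desk scale we did not observe it.
* LOOCV refits in the test/acceptance protocol run at reduced iteration
  budgets (1,200 max) — class orderings are decisive well before full
  convergence; single-model analyses use the full protocol.
* Analyses of near-defective dynamics matrices proceed with a warning up
  to eigenvector condition number 1e8.
* Serialized models carry their class metadata; indicator tensors are
  rebuilt on load, never stored.
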