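# ctxlds

Inference and characterization of **context-dependent computation** from
trial-averaged neural population responses.

In contextual decision tasks (e.g. discriminate the motion *or* the color
of a random-dots stimulus depending on a rule cue), prefrontal populations
integrate the relevant evidence and discard the irrelevant one.  Two
mechanistically opposite accounts both explain such data: the circuit can
**re-route its inputs** across contexts, or **reconfigure its recurrent
dynamics**.  `ctxlds` makes that contrast quantitative.  It fits
constrained linear dynamical systems (LDS) jointly to the z-scored,
condition-averaged response tensors of both contexts,

    x_k(t) = A_cx x_k(t-1) + B_cx^m u_k^m(t) + B_cx^c u_k^c(t)
    y_k(t) = C x_k(t) + d

where the model **class** — {A,B}, {A,Bcx}, {Acx,B}, {Acx,Bcx} — declares
which of the dynamics matrix `A` and input subspaces `B` may differ across
contexts (`x0` is always per-context; `C`, `d` and the input
courses/coherence scalars are always shared).  A tensor factor regression
(TFR) that strictly nests the LDS provides a model-free upper bound on the
attainable fit at a given rank.  The toolkit is aimed at systems/
computational neuroscientists working with condition-averaged population
recordings (PSTH tensors: neurons x time x conditions x contexts).

What the package provides:

* `synthetic_task` — ground-truth LDS generator emulating the contextual
  random-dots task structure (6x6 signed-coherence grid, 36 conditions,
  2 contexts, 50-ms bins, per-neuron z-scoring), with knobs for
  input-switching vs dynamics-switching regimes and non-normality.
* `lds_core` / `tfr_core` — data model, simulation, reconstruction, cost,
  SVD orthonormalization, exact parameter counting; TFR indicators,
  prediction and the exact LDS-to-TFR embedding.
* `fit_select` — ADAM fitting with hand-derived backprop-through-time
  gradients (validated against finite differences), multi-restart
  protocol, leave-one-condition-out cross-validation (LOOCV) and
  dimensionality sweeps, optional normal-dynamics penalty.
* `dynamics` — eigenmodes with decay time constants and rotation
  frequencies, Henrici non-normality index, input loads on left
  eigenvectors (with exact reconstruction of `B u(t)`), impulse responses,
  observability Gramian / most-amplifying modes, controllability, CD/CI
  decomposition, mode alignments, coherence/|coherence| demixed planes,
  input- and output-norm summaries.
* `perturb_report` — simulated causal experiments (state perturbations
  along data PCs, input switch-offs) that discriminate the mechanisms, a
  JSON-configured end-to-end pipeline, and a `ctxlds` CLI
  (`synth` / `fit` / `loocv` / `analyze` / `perturb` / `run`).

## Worked example

```python
import numpy as np
from ctxlds import GroundTruthSpec, generate_dataset, FitConfig, fit
from ctxlds.dynamics import eigenmodes, henrici_index

# synthetic task data from an input-switching ground truth:
# 60 neurons x 15 bins x 36 conditions x 2 contexts, z-scored
data, gt = generate_dataset(
    GroundTruthSpec(context_mode="input-switching", non_normality=0.5,
                    noise_sd=0.1, seed=42)
)

cfg = FitConfig(max_iter=4000, min_iter=2000, convergence_dcost=1e-6, seed=0)
res = fit(data, gt.class_spec, cfg)
print(f"class {res.class_spec.name}: train MSE {res.train_mse:.4f} "
      f"({res.n_iter} iterations)")

modes = eigenmodes(res.params.A_ctx(0))
print(f"Henrici index: {henrici_index(res.params.A_ctx(0)):.2f}")
for i in np.flatnonzero(modes.slow):
    print(f"slow mode |lambda|={abs(modes.eigvals[i]):.3f} "
          f"tau={modes.tau_ms[i]:.0f} ms  f={modes.freq_hz[i]:.2f} Hz")
```

Output:

```
class {A,Bcx}: train MSE 0.2086 (2135 iterations)
Henrici index: 0.46
slow mode |lambda|=0.979 tau=2411 ms  f=0.00 Hz
slow mode |lambda|=0.911 tau=534 ms  f=0.76 Hz
slow mode |lambda|=0.911 tau=534 ms  f=0.76 Hz
```

Reading: on z-scored data the MSE is the fraction of unexplained variance,
so the fitted context-dependent-input model explains ~79% of the variance
of this noisy synthetic dataset.  The recovered dynamics contain a
near-integrator (|lambda| close to 1: decay time constant beyond the
750-ms trial — the evidence-accumulation mode) plus a slow rotational
conjugate pair (~0.8 Hz), and the positive Henrici index reflects the
non-normal eigenbasis the data were generated with.  Slow modes are those
with |lambda| > 0.8, i.e. tau > 224 ms at 50-ms bins.

Model classes are compared with LOOCV (`ctxlds.loocv`), which refits with
one (motion, color) condition held out of both contexts and
forward-predicts it from the inputs shared with the remaining conditions;
mechanisms are further discriminated by simulated perturbations
(`ctxlds.perturb_report`): transient amplification of PC-aligned state
perturbations occurs under non-normal dynamics-switching but not under
near-normal input-switching solutions.

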