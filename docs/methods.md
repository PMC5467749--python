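# Methods

## Model

The package implements two networks over one shared architecture
description (layer sizes indexed with **0 = output** and `l_max` = input;
activation `linear`, `tanh`, or `logistic`; optional bias).

**Reference ANN.** A conventional MLP with pre-activations
`y_i(l) = Σ_j w_ij(l+1) f(y_j(l+1))`, trained by gradient ascent on the
(non-positive) objective `E = -1/2 Σ_i (s_out_i - y_i(0))²`.  The sign
convention keeps the ANN objective and the predictive-coding free energy
directly comparable: both are bounded above by 0 and maximized.  Error
terms follow the standard backprop recursion; gradients are the outer
product of postsynaptic error and presynaptic output.

**Predictive-coding network (PCN).** A layered Gaussian model
`P(x_i(l) | x(l+1)) = N(x_i(l); μ_i(l), Σ_i(l))` with
`μ_i(l) = Σ_j θ_ij(l+1) f(x_j(l+1))`.  Inference maximizes the free
energy `F = -1/2 Σ_l,i (x_i(l) - μ_i(l))²/Σ_i(l)` by evolving unclamped
nodes along `∂F/∂x`; the dynamics factor through prediction-error nodes
`ε = (x - μ)/Σ`, and learning is the local Hebbian rule
`Δθ_bc(a) = α ε_b*(a-1) f(x_c*(a))` applied at the relaxed state.  The
variances `Σ` are fixed parameters, never learned.  Bias terms are a
constant-output unit (index 0 in each weight matrix) with no error node.

Assumptions inherited from the model family: Gaussian noise at every
level, symmetric feedforward/feedback weights (a single `θ` store, so the
two directions are updated identically by construction), and fixed
diagonal variances (no lateral/covariance connections).

## Relaxation (inference phase)

Explicit Euler integration, initial step 0.2, with one adaptive policy
used everywhere:

* **Runaway check** — if the prospective maximum change in node activity
  (`step × max|dx/dt|`) exceeds twice the previously accepted change, the
  step is halved.  The factor-2 margin lets velocities grow legitimately
  while the state climbs toward a pass of a nonconvex landscape without
  triggering collapse.
* **Stagnation check** — every 50 accepted steps, if the maximum velocity
  has not decayed by at least 10%, the system is marginally stable at the
  current step (Euler amplification ≈ 1) and the step is halved.  If the
  halving does not restore decay by the next window, the slowness is a
  physical property of the landscape rather than a stability artefact:
  the halving is undone and stagnation-halving is disabled for the rest
  of the relaxation.
* **Ascent guarantee** — a trial step that would decrease F is retried
  with a halved step, so F is non-decreasing along every accepted
  trajectory.
* **Recovery** — after well-behaved steps the step grows by 10% toward
  its initial value, so a transient shrink early in the relaxation does
  not slow the whole integration.

Early designs that halved on *any* velocity increase and never re-grew
the step stalled in two reproducible ways (step driven to ~1e-300 by
float-level velocity noise; permanent slowdown after the initial
transient), which is why the policy above is stated in terms of activity
changes, windows, and recovery.

Stopping: either `max |∂F/∂x| < tolerance/Σ(0)` with tolerance 1e-6
(default; `Σ(0)` taken as the scalar shared by the output layer) up to a
cap of 1e6 iterations (the state is then returned with a warning flag,
not an error), or a fixed step count (20 for minibatch training, where
exact convergence per example would be wasteful).  Non-finite states
raise a divergence error carrying the iteration index.

A tolerance on the *gradient* bounds the error in *x* only up to the
conditioning of the fixed-point map.  Verification ensembles therefore
use half-scale Glorot-uniform weights, `U(±0.5·√(6/(n_in+n_out)))`,
which keep units responsive and the map's amplification below ~10; with
those draws the gradient tolerance 1e-6 yields state accuracy below 1e-5
(checked over 200 draws).

Relaxation supports a leading batch dimension (samples relax
independently but share the adaptive step — the step is then governed by
the stiffest sample, which is conservative), and can record a
`(iteration, step, F, max velocity)` trace exportable as CSV.

Hidden layers in learning mode start from the layerwise feedforward
prediction (in prediction mode all error nodes converge to zero, so this
pass *is* the prediction-mode fixed point); a full prediction-mode
relaxation from zeros also exists and is what the equivalence tests use.

## Variance scaling

Multiplying the variances of **all** levels by k leaves every fixed point
unchanged and rescales every `ε` by exactly 1/k (the velocity field is
scaled uniformly).  Multiplying the *output* variance alone also shifts
the learning-mode fixed point, so the 1/k rescaling of the errors holds
only asymptotically in large `Σ(0)` — on a 1-1-1 linear chain the errors
go as `1/(Σ+1)`, not `1/Σ`.  The test suite asserts the exact uniform
version at 1e-6 relative and the output-only version at 10% between
`Σ(0)` = 100 and 1000.  When minibatch training mixes variance settings,
error values are rescaled by `Σ(0)` before the weight update so the
effective learning rate is comparable across settings.

## Bidirectional association network

Two observed bottom nodes (`x_1(0)` = output sample, `x_2(0)` = input
sample), one unconstrained top node with a flat prior (the prior constant
never enters a gradient and is not represented), linear weights `θ_i`,
per-node variances `Σ_i(0)`.  Training clamps both bottom nodes, relaxes
the top node — a scalar linear ODE, implemented as a plain-float loop
with the same adaptive policy for an order-of-magnitude speedup over
array arithmetic — and applies `Δθ_i = α ε_i x(1)*` with α = 1.
Prediction clamps one bottom node and relaxes the rest; since the model
has zero intercept, one relaxation at unit input yields the whole
prediction line.

Variance settings for the direction trade-off experiment are
`equal = (1, 1)`, `large_output = (100, 1)`, `large_input = (1, 100)`;
the 100:1 ratio matches the large-variance regime used in minibatch
training.  Defaults: 2000 training and 100 test samples, 50 repetitions,
one pass over the data per repetition (the pass count is exposed as
`epochs`; a single pass already reaches the analytic slopes, and the
equal-variance setting has a scale-neutral direction along which `‖θ‖`
drifts, so extra passes change the scale, not the slope).  Per-repetition
initial weights are drawn `U(0.5, 1.5)` so learning is demonstrated from
an asymmetric start.  With unit learning rate the end-of-training slope
retains per-sample jitter (s.d. ≈ 0.15 for the equal setting); the
experiment reports means and standard errors over repetitions.

Baselines are computed from the data covariance: forward OLS slope
`cov/var(s_in)`, inverse regression re-expressed in the forward frame
`var(s_out)/cov`, and the leading eigenvector of the 2×2 covariance for
the principal axis.  For sum/difference data `s_in = a+b, s_out = a-b`
with `a ~ N(0,1), b ~ N(0,1/9)` the population values are 0.8, 1.25, 1.0.

## Minibatch training

Protocol defaults: logistic units with bias, weights
`U(±4·√(6/N))` with `N` the summed node count of the connected layers
(bias columns start at 0), batch size 20, Adam (β₁ = 0.9, β₂ = 0.999,
ε = 1e-8 — standard values) at learning rate 0.001 applied as gradient
ascent, 20 inference steps per PCN example, targets coded 0.97/0.03,
classification by output argmax.  PCN batches relax each example
independently (batched arrays) and average per-example increments before
the optimizer step.  Runs are pure functions of the seed; multi-run
aggregation reports per-epoch means and standard errors.

The digit-preprocessing path clips pixels into [0.05, 0.95] before the
inverse-logistic transform (the clipping constant γ = 0.05 is
configurable; raw 0/1 pixels must stay finite).  The MNIST reader
accepts local IDX files only and never downloads.

## Synthetic data: what it does and does not emulate

* `gen_tanh_chain` reproduces the noise-free two-weight task exactly
  (uniform inputs on [-5, 5] through `W1 tanh(W2 tanh(·))`); results on
  it transfer to the real task by construction.
* `gen_sum_diff` reproduces the sum/difference association task exactly
  (it *is* the generative model, not an approximation).
* `gen_synthetic_digits` is a stand-in for an image-classification set:
  isotropic Gaussian class clusters in 784 dimensions with soft one-hot
  targets.  It matches the *shape* of the problem (dimensionality, class
  count, target coding) but not image statistics — clusters are
  linearly separable and isotropic, so absolute error rates are not
  comparable to handwritten-digit benchmarks.  Tests built on it show
  that the ANN and PCN training loops track each other, not that either
  attains any particular benchmark accuracy.

## Scaled-down problem sizes

The heavier experiments run at reduced size, chosen so the full suite
completes in minutes on one core while keeping every qualitative
conclusion intact: the weight-grid sweep uses a 5×5 grid on
`[-2, 3]²` (bracketing the optimum at (1, 1); the plotted range of the
original figures is not recoverable from text, so the range is a
documented package choice) with 300 samples; the direction trade-off
uses 500 training samples per repetition; learning-curve proximity uses
500 examples with a 784-100-100-10 network for 10 epochs.

## Known limitations

* No learning of variances, no covariance or lateral connections, no
  spiking or positivity constraints, no convolutional/recurrent layers,
  no softmax/cross-entropy head.
* The adaptive Euler scheme is a robust fixed-point finder, not a
  high-order integrator; trajectories are not accurate solutions of the
  continuous-time dynamics, only their fixed points are.
* Gradient-tolerance stopping bounds state accuracy only through the
  conditioning of the fixed-point map (see above); strongly weighted
  networks can need tighter tolerances for the same state accuracy.
* Whether per-synapse local convergence detection suffices for learning
  is an open question not addressed here.
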