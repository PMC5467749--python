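# predcoding

Supervised **predictive-coding networks** with local Hebbian plasticity,
paired with the reference backpropagation network they approximate.

## The scientific problem

Error backpropagation updates each synapse using a global function of
activities and weights elsewhere in the network, which is hard to
reconcile with biological synapses that see only their own pre- and
postsynaptic activity.  A hierarchical Gaussian generative model offers a
way out.  Arrange latent variables in layers (index 0 = output, `l_max` =
input), with each level predicting the one below through weights `θ` and
an activation `f`:

    P(x_i(l) | x(l+1)) = N(x_i(l); μ_i(l), Σ_i(l)),
    μ_i(l) = Σ_j θ_ij(l+1) f(x_j(l+1))

Inference maximizes the free energy

    F = -1/2 Σ_l Σ_i (x_i(l) - μ_i(l))² / Σ_i(l)  ≤ 0

by relaxing each unclamped node along `∂F/∂x`, a computation mediated by
*prediction-error nodes* `ε_i(l) = (x_i(l) - μ_i(l)) / Σ_i(l)`:

    dx_b(a)/dt = -ε_b(a) + Σ_i ε_i(a-1) θ_ib(a) f'(x_b(a))

After relaxation, every weight changes by a purely local Hebbian product:

    Δθ_bc(a) = α · ε_b*(a-1) · f(x_c*(a))

Two exact/asymptotic correspondences with a conventional MLP trained by
backpropagation (objective `E = -1/2 Σ (s_out - y(0))²`, maximized) make
this network a biologically plausible approximation of backprop:

1. **Prediction mode** (only the input clamped): the relaxation fixed
   point satisfies `x* = y` — node for node the ANN forward pass — with
   all error nodes silent and `F* = 0`.
2. **Learning mode** (input and output clamped): the fixed-point errors
   obey the same recursion as the backprop deltas, and as the output
   variance `Σ(0)` grows (with the learning rate rescaled accordingly),
   the Hebbian update converges in direction to the backprop gradient.

A two-arm variant — two observed bottom nodes sharing one unconstrained
latent with a flat prior — learns *bidirectional* associations whose
character is set by the relative variances: equal noise gives the first
principal axis (total least squares), large output noise gives ordinary
forward regression (the backprop limit), large input noise gives inverse
regression.

## Package tour

| module | contents |
|---|---|
| `predcoding.ann` | reference MLP: forward pass, backprop deltas, gradients |
| `predcoding.pcn` | PCN: predictions, errors, free energy, adaptive-Euler relaxation, Hebbian updates |
| `predcoding.compare` | gradient-direction angles, weight-grid sweeps, equivalence reports |
| `predcoding.bidir` | two-arm bidirectional association network and regression/PCA baselines |
| `predcoding.data` | seeded generators, MNIST IDX reader and preprocessing, fixtures |
| `predcoding.train` | minibatch training loops (Adam/SGD), weight init, multi-run aggregation |
| `predcoding.cli` | `predcoding` command with `gen-data`, `train-ann`, `train-pcn`, `compare`, `angle-sweep`, `bidir` |

## Worked example

How close is the Hebbian update to the backprop gradient, and how does
the output variance control that?  On the two-weight tanh chain
(`s_out = tanh(tanh(s_in))`, 300 samples), compare the two update
directions at an off-optimum weight setting for increasing `Σ(0)`:

```python
import numpy as np
from predcoding import (MLPArchitecture, PCNParams, WeightMatrices,
                        equivalence_report, gen_tanh_chain)

ds = gen_tanh_chain(300, seed=0)
arch = MLPArchitecture((1, 1, 1), "tanh")
weights = WeightMatrices([np.array([[1.2]]), np.array([[0.8]])])
params = PCNParams.from_weights(arch, weights, 1.0)
print(equivalence_report(params, ds.s_in, ds.s_out, [1.0, 8.0, 256.0]))
```

```
   sigma0  max_abs_x_diff  angle_deg         abs_F
0     1.0        0.000003   0.987568  3.647131e-11
1     8.0        0.000001   0.170642  1.045337e-11
2   256.0        0.000001   0.004698  4.876979e-13
```

Reading the table: `max_abs_x_diff` is the prediction-mode gap between
the relaxed PCN state and the ANN forward pass (at solver tolerance —
the fixed points coincide), `abs_F` is the free energy there (its
maximum, 0, is attained when every error node is silent), and
`angle_deg` is the angle between the all-weights Hebbian increment and
the backprop gradient in learning mode: about 1° already at `Σ(0) = 1`,
collapsing to 0.005° as the output variance grows — the
predictive-coding update *becomes* backprop in this limit.

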