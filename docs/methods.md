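# Methods

`snndelays` implements and analyses feed-forward spiking networks in which
every synapse carries two learnable parameters — a weight and a conduction
delay — and in which connectivity itself can be learned by dynamic
pruning and rewiring under Dale's-law sign constraints.  This note
describes the model, the numerical choices, the synthetic study
conditions, and the limits of what the desk-scale experiments show.

## Neuron model

Hidden units are leaky integrate-and-fire neurons solved with a linear
Euler step:

    u_i[t] = (1 − Δt/τ) · u_i[t−1] · (1 − S_i[t−1]) + I_i[t] · Δt
    S_i[t] = Θ(u_i[t] − ϑ)

with membrane time constant τ = 10.05 timesteps, Δt = 1, and threshold
ϑ = 1 (dimensionless).  The
`(1 − S)` factor implements reset-to-zero: the stored membrane value is
the pre-reset one, and the reset is applied on the carry-over.  The
threshold boundary u = ϑ counts as a spike, which makes the forward pass
deterministic.

Θ is non-differentiable, so the backward pass substitutes an
arctan-family surrogate derivative

    Θ'(v) ≈ w / (1 + (π w v)²),  w = 5 by default,

the derivative of (1/π)·arctan(πwv): strictly positive, maximal at the
threshold, unit total mass.  The surrogate width is a free
hyperparameter; 5 is a common middle-of-the-road choice.

## Delay kernels

A synapse (j → i) with weight w and continuous delay d ∈ [0, T_d − 1] is
realised as a causal temporal kernel over lags n = 0…T_d:

    k[n] = w · c · exp(−½ ((n − T_d + d + 1)/σ)²),

with c chosen per synapse so Σ_n k[n] = w exactly (the kernel
redistributes the weight over time without changing its total).  Index
n = T_d is lag zero, so the bump is centred at lag d + 1: a spike takes
one conduction step plus d.  The postsynaptic current is the strict
causal convolution of the presynaptic spike train with this kernel, with
zero left-padding (silence before stimulus onset).

The kernel width σ is annealed during training: broad kernels let the
delay gradient see distant candidate lags; narrow ones sharpen each
synapse into an effectively discrete delay line.  The default schedule is
linear from σ_init to σ_min = 0.5 over the first 75% of epochs, then
constant.  At the reference scale (T_d = 25) σ_init = 12.5; at other
scales the package keeps the same ratio, σ_init = T_d/2.  Delays are
clamped into [0, T_d − 1] after every optimizer step so the kernel peak
stays inside the support.  Delays remain continuous at evaluation (no
rounding); normalisation c is recomputed from the current (d, σ) on every
forward pass so gradients flow through the kernel shape while the summed
weight stays exactly w.

## Structure learning

Sparse connectivity is reparameterised as w = s · max(θ, 0): a sign
matrix s fixed at creation and a trainable magnitude θ.  θ ≤ 0 means the
connection is dormant and contributes exactly zero.  Dropping is
implicit — the optimizer, helped by an L1 penalty λ·Σ max(θ, 0) on
active magnitudes, pushes useless magnitudes non-positive.  A rewiring
step then restores the fixed synapse budget by reactivating dormant
entries:

* gradient mode ranks dormant entries by dL/dθ and activates the k most
  negative (under the positive-magnitude convention only a negative
  gradient argues for activation);
* random mode reactivates k uniformly random dormant entries.

Because max(θ, 0) has zero true gradient on dormant entries, the ranking
uses the straight-through gradient s · dL/dw (exact on active entries);
the optimizer itself freezes dormant magnitudes.  Reactivated synapses
get θ = `theta_init`, their Adam moments are reset, and — when delays are
not being learned — a fresh random delay, which makes structure learning
a form of delay selection.  Ties in the ranking break toward the smallest
flat index, keeping runs reproducible.  No gradient noise is added.

Dale's law is imposed structurally: one random sign per presynaptic
neuron broadcast down its outgoing column, so every connection leaving a
neuron shares its sign and no training or rewiring step can violate the
constraint.

Defaults: rewiring every iteration with the instantaneous minibatch
gradient and `theta_init` = 1e−3.  The planted-structure experiment
instead rewires every 8 iterations, ranks by the gradient averaged since
the last event (a lower-variance regrowth signal), and uses
`theta_init` = 0.1 so a fresh synapse survives more than one Adam step
before the L1 drift can kill it; all three are exposed on
`RewirePolicy`/`TrainConfig`.

## Architecture and training

Input (C channels × T steps) → delayed convolution → per-channel batch
normalisation over batch and time → LIF population → dropout on hidden
spike trains (training only) → delayed convolution → non-spiking leaky
readout integrators (ϑ = ∞) → logits as the time-sum of readout voltage.
A cumulative-current readout is available as a config alternative.  The
readout coefficients are normalised by T·τ (a constant rescale of all
logits) so the softmax is not saturated at initialisation.

Training is backpropagation through time with the surrogate derivative,
cross-entropy plus the L1 term, Adam, a one-cycle schedule on the weight
learning rate and cosine annealing on the delay learning rate.  Because
no autodiff framework is used, the backward pass is written out
analytically; each block (kernel-parameter gradients, convolution
transpose, batch-norm backward, the LIF reverse recursion) is validated
in the test suite against finite differences or an independent
scalar-level chain-rule oracle.  Finite-difference agreement is exact on
smooth paths (output layer); gradients through spikes are surrogate
gradients by construction and are validated behaviourally (delay
recovery, loss descent).

The L1 coefficient may differ between the input layer and the output
layer (`l1_lambda_input`); the ablation uses a single small value.

## Synthetic study conditions

The generators emulate the statistical shape of the keyword-spotting
spectrograms the architecture targets (40 channels × 80 steps at
reference scale) without requiring any external audio.

* **Planted-delay tasks** — Bernoulli(rate) spike rasters and target
  currents produced by a known (weight, delay) matrix through an
  independent shift-and-sum oracle (lag d + 1, matching the kernel
  convention).  Delays uniform on [0, T_d − 1], weight magnitudes uniform
  on [0.5, 1.5] with random signs.
* **Class-pattern tasks** — each class is a template of (channel, lag)
  features with lags spanning up to T_d; each sample places 2-step bursts
  at a random global onset over Bernoulli background noise
  (rate 0.04 by default).  Class identity is decodable only by combining
  features at distinct lags, forcing temporal coincidence detection.  A
  matched-filter oracle that knows the true templates bounds decodability
  (> 0.95 at default noise; 100% noiseless).
* **Planted-structure tasks** — templates drawn from a designated channel
  subset; the remaining channels carry label-independent noise at a rate
  matched to the informative channels' average, so mean activity alone
  cannot reveal the informative set.

Problem sizes for the reference experiments were chosen so each runs in
minutes on one CPU:

| experiment | size |
|---|---|
| delay recovery | 20 pre × 5 post, T = 100, 2,000 samples, rate 0.1; 60 epochs |
| structure recovery | 24 channels (6 informative), 6 classes, 720 samples; 32 hidden, 87.5% sparse, 120 epochs |
| ablation + Moran shift | 16 channels × 40 steps, 10 classes, 800 samples; 64 hidden, 87.5% sparse, 3 seeds × 4 conditions, 60 epochs |

## Receptive fields and spatial statistics

The structural receptive field of an output class summarises where
excitation and inhibition arrive in input space and time.  Per hidden
neuron, a panel (input neurons × delay bins) gets one signed point per
active input synapse at its rounded delay (sign only by default; a
magnitude-carrying variant is available).  The class receptive field sums
these panels over hidden neurons, scaled by the hidden→output weight and
shifted by the rounded hidden→output delay, on a canvas of width
(T_d + 1) + T_d so no shift truncates mass.

Spatial autocorrelation is quantified with global Moran's I under
Queen's-case (8-neighbour) grid weights; all matrix cells, including
zeros, are cells of the grid.  Under no autocorrelation E[I] = −1/(N−1).
Because the ordering of input neurons is arbitrary, the package reports
the maximum I over 2,000 random row permutations, with the identity
permutation always included (so the maximum is never below the
unpermuted value).  Distributions of maxima (trained vs untrained
networks) are compared with a two-sided Mann–Whitney U test — exact for
small tie-free samples, tie-corrected normal approximation otherwise.

## Known limitations

* Desk-scale class-pattern tasks have far less structure than real
  speech spectrograms; passing tests demonstrate the mechanisms work and
  interact as designed, not performance on real audio.  An adapter for
  real recordings is deliberately out of scope.
* Structure-learning selectivity is equilibrium-limited: the surviving
  active set concentrates on informative channels mainly through the
  drop side (useful synapses resist the L1 drift), while regrowth is
  close to chance-level — consistent with the observation that
  gradient-guided reconnection barely beats random reconnection.  Under
  Dale's law the inhibitory half of the budget settles on noise channels
  (tonic inhibition is genuinely useful), which caps achievable
  precision; the measured concentration at 87.5% sparsity is roughly
  1.3–2× the chance rate, not more, and the package reports it honestly.
* Surrogate-gradient BPTT in NumPy is exact for the architecture here
  but does not scale to the reference 256-hidden, 20-class audio runs in
  reasonable desk time; all experiments are scaled down accordingly.
* Batch-norm uses per-batch statistics during training and running
  averages at evaluation; very small batches make the running estimates
  noisy.
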