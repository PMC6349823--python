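# Methods

This note documents the models, the simulated world, the numerical choices
and the known limitations of the `hhvg` package. It is the package's own
account of its science; every number quoted here is computed by the test
suite or by `scripts/acceptance.py`.

## The agent

The agent is an intrinsically motivated model-based learner in a
reward-free, deterministic world. Its only goal is to learn an accurate
forward model of that world from experience it must gather itself. Five
learned components interact:

* **Forward model** `P(S'|a, s; θ)`: a Gaussian whose mean is the
  locally-linear (bilinear) assembly `f(a,s) = A s + (Σ_ι a_ι B_ι) s + C a + o`,
  where the Jacobian blocks A (4×4), B (2×4×4), C (4×2) and the offset o are
  emitted by a residual MLP trunk reading the state. Its covariance is
  `J Σ J^T` with `J = A + Σ_ι a_ι B_ι` and a fixed isotropic base covariance
  `Σ = σ_s² I` (default σ_s = 0.01). The trunk reads the state only, so one
  trunk pass serves the whole action grid; the action enters through the
  bilinear assembly. This is the locally-linear-dynamics convention
  (embed-to-control style) and is the reading under which A, B, C are
  Jacobian approximations: with the head outputs held fixed,
  `∂f/∂s = A + Σ_ι a_ι B_ι` exactly.
* **Meta-model** `Q(S'|s; ψ)`: a Gaussian summary of where the agent tends
  to end up from `s`, marginalising over its own actions. Three disjoint,
  identically structured towers emit the mean, a positive spectrum `d`
  (Softplus) and a Householder vector `u`; the covariance is
  `H diag(d) H^T` with `H = I − 2uu^T/‖u‖²` — symmetric positive definite by
  construction, with O(k) inverse and log-determinant.
* **Devaluation** is fitting Q to the forward model's prediction under the
  running policy: minimising the closed-form Gaussian KL
  `L_mm = KL(P(·|a,s;θ) ‖ Q(·|s;ψ))` in ψ. A well-fit Q means outcomes are
  *boring*: already summarised.
* **Intrinsic reward** is devaluation *progress*:
  `R(a,s) = L_mm(ψ_before) − L_mm(ψ_after)` across one meta-model update —
  the agent is rewarded where its summary of the world just improved.
* **Value function** `v(s; ν)` is fitted policy evaluation on these rewards
  with a hard-copied target network, and the **policy** π(A|s; φ) is a
  121-way categorical over the 11×11 acceleration grid, trained by exact
  enumeration of the value-gradient objective
  `−E_{a~π}[R(a,s) + γ v(f(a,s); ν)]` (discrete actions make the expectation
  exact; the next state is the forward-model mean because the world is
  deterministic).

## Homeostasis, heterostasis, and the collapse dichotomy

Devaluation is homeostatic (it can be satiated), progress-seeking is
heterostatic (it self-perturbs). The package's central behavioural
diagnostic (`hhvg.experiments.policy_collapse_experiment`) alternates one
devaluation step and one policy step on a frozen state under two reward
choices. Rewarding the devaluation *objective* itself (interestingness
seeking) makes the policy objective linear in π with a quasi-static score
vector: gradient ascent on logits is self-reinforcing and the policy
collapses to a point mass (entropy → 0 within a few hundred alternations).
Rewarding devaluation *progress* is self-limiting — as Q equilibrates, the
per-action progress spread vanishes and the drive switches itself off — so
entropy stays near the maximum ln 121 ≈ 4.8 nats. The diagnostic uses plain
gradient descent (learning rate 0.5) for the policy precisely because the
argument is about reward *magnitudes*: an adaptive optimizer that
normalises gradient scale (Adam) erases the self-limiting property and
collapses both agents. For the same reason the training loop's policy
optimizer is plain SGD while all other components use Adam.

The same reconciliation appears analytically in the information
decomposition `E_π KL(P_a‖Q) = I(S';A|s) + KL(P_mix‖Q)` (mixture marginal
`P_mix = Σ_a π_a P_a`), which `hhvg.metrics.mi_kl_decomposition` verifies
numerically by Monte Carlo over the 121-component mixture.

## The world

A deterministic planar expansion of Mountain Car on the unit square:
state (x, y, ẋ, ẏ), positions bounded, velocities free, no external reward,
no terminal state. One attractor and three repellers add a radially
symmetric Gaussian-profile acceleration `±strength · exp(−r²/2σ_f²) · r̂`
to the chosen action (only the qualitative layout — one attractor, several
repellers, visitation biased toward the attractor — is essential; the force
law, coordinates and strengths are this package's own concrete choices,
fully config-driven). Integration is explicit Euler
(dt = 0.05, velocity before position). A wall clamps the violated axis and
zeroes that axis's velocity only, so sliding along walls — and corner
trapping — are possible; a config flag switches to zeroing both components.

Defaults: attractor (0.75, 0.75) strength 1.8; repellers (0.25, 0.75),
(0.75, 0.25), (0.25, 0.25) strength 1.5; σ_f = 0.25; start (0.5, 0.5);
viscous damping 0.5. The damping term is a deliberate addition: without an
energy sink, a uniform-random walker accumulates kinetic energy
indefinitely and sweeps the arena, and the attractor cannot capture it.
With damping, random diffusion (mean-zero actions) equilibrates at a small
velocity scale and the drift field dominates: uniform-random agents spend
>95% of their time inside the attractor's basin, while a directed policy
(sustained accelerations up to 2.0 > peak field strength 1.8) can still
escape any source. This realises the intended visitation bias — the world
is explorable by intent but not by chance.

## Variants and the benchmark

The pruning ladder removes components cumulatively: C/B (full agent),
C/PE (no meta-model; reward is forward-model learning progress
`‖s'−f‖²_before − ‖s'−f‖²_after`), PG/IRS (no value function; REINFORCE on
rewards replayed, time-synchronised, from a recorded C/B run), PG/GR
(REINFORCE on time-invariant N(0, 0.01²) surrogate rewards), P/RW (uniform
random policy), and Oracle (forward model trained on an exhaustive
state-action grid dataset with 0.8/0.16/0.04 train/test/validation splits).
All variants of one experiment share the environment, start state and
(where architectures coincide) seeded network initialisation. Scores are
error percentage: 100 × RMSE / (max pairwise distance among validation
next-states).

Since Eq-style per-action progress needs the meta-model, the C/PE policy
objective keeps only the value term of the enumeration; its realized
learning-progress rewards enter through value learning. PG variants apply
one REINFORCE update per environment step on the transition just executed,
with the reward drawn for that time step.

## Scale

Full-scale conditions (30,000 DAP steps, 30,000 post-DAP epochs, width-512
networks, 49×49×11×11×11×11 oracle grid, 128 runs) are config defaults but
are not what the tests run. The packaged benchmark
(`hhvg.experiments.run_ordering_experiment`) uses 2,000 DAP steps, 3,000
post-DAP epochs, width-64 networks, a 5×5×3×3×5×5 oracle grid (5,625
records), 3 seeds, model learning rate 1e-3 (short runs need a larger
constant rate than the full-scale default 1e-4), policy SGD rate 0.3, and
4,000 oracle training epochs, where an epoch is one optimizer step on one
sampled batch of 128. Post-DAP and oracle training use the
reduce-on-plateau schedule (×0.1 after 3,000 stale epochs, 0-indexed; on a
constant loss the first two reductions fire at epochs 3000 and 6000).

## Numerical choices

* Gradients are analytic throughout (no autodiff); every backward pass is
  finite-difference-checked in the tests.
* Xavier uniform initialisation for all trainable layers; Adam
  (β = 0.9/0.999) for models and values; plain SGD for policies (see above).
* A jitter of 1e-6 is added to the meta-model spectrum before inversion in
  the KL (Softplus outputs can underflow); the generic `gaussian_kl` instead
  raises on a singular covariance with a hint to add jitter.
* The offset head `o` is 4-dimensional by default; `o_scalar=True` gives a
  single element broadcast over the state coordinates.
* Policy enumeration runs on a 32-state sub-batch of the 128-sample batch
  (121 predicted next states per state make this the costly update).
* Value targets use a hard target-network copy every 100 gradient steps.
* The validation diameter is exact: brute force for small sets, convex-hull
  vertices for large ones (with a chunked brute-force fallback for
  degenerate geometry).
* Coverage metrics use a 50×50 positional grid, cells half-open with the
  top edge closed, natural-log entropy, and a Laplace-initialised counter
  (one phantom visit per cell) so coverage entropy starts exactly at
  ln 2500 ≈ 7.824 nats.
* The Mann-Whitney harness is one-sided with midrank ties at the
  Bonferroni-corrected α = 0.025 for the two planned comparisons.

## What the benchmark does and does not show

The synthetic world realises the benchmark's intended preconditions — visitation bias, a
time-limited self-assembled training set, and regions informative for model
learning that chance visits rarely reach — but the force law, strengths and
damping are this package's choices, and desk-scale runs are 15× shorter
with 8× narrower networks than the full-scale conditions. Results that are robust at this scale: the Oracle's
supervised benchmark beats every self-taught agent by a wide margin
(uniform state-action coverage is worth far more than any exploration
policy at these budgets); the uniform-random agent is captured by the
attractor; and the collapse dichotomy above. Results that are *not*
resolved at this scale: the ordering among the interactive variants. Two
reasons, both verified in pilots. First, at 2,000 steps the policies never
leave the near-uniform regime — the gentle SGD rate that preserves entropy
steers too slowly to produce directed exploration, while faster rates (or
an adaptive optimizer) collapse the policy into a stuck point mass, and
aggressive value propagation (higher γ, frequent target syncs, larger
value rates) diverges. Second, the world's dynamics are globally
near-linear (s' ≈ A₀s + C₀a plus a bounded field correction), so even a
buffer concentrated in the attractor basin identifies the global map;
validation error is instead dominated by high-speed boundary-clamp states
that no interactive desk-scale agent visits, and the position-coverage
differences that curiosity produces barely move the score. Separating the variants plausibly needs both far longer
runs (so slow policy learning can produce genuinely directed exploration)
and a field with stronger local structure, so that concentrated experience
stops generalising. The benchmark reports medians over seeds and should be read
as a qualitative reproduction at the extremes (Oracle vs interactive;
random-walk capture), not as a resolution of the full ablation ordering.

## Known limitations

* Gaussian beliefs only; mixture or flow meta-models are out of scope.
* The closed-form KL needs the 4×4 covariance machinery per sample; cost
  grows cubically with state dimension.
* No parallelism: N runs are independent processes.
* The replay database is held in memory (30k transitions is small); the
  FIFO capacity cap is available but off by default.
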