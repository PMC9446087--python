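# Methods

## Model

`epac` implements a hybrid actor-critic reinforcement learner in which
the two halves of the architecture learn by different mechanisms.

**Actor (Equilibrium Propagation).** The policy network is a recurrent
dynamical system with one hidden layer. Writing `s` for the observation,
`x_j` for hidden activations, `x_o` for output activations, the state
evolves by Euler-integrated leaky dynamics

    x_j <- x_j + h * (-x_j + p(sum_i w_ij s_i + gamma * sum_o w_oj x_o + b_j))
    x_o <- x_o + h * (-x_o + softmax_o(sum_j w_jo x_j + b_o))

with `p` a hard sigmoid and both layers reading previous-iteration
values. The softmax sits inside the dynamics, so the settled output
state is itself the action-probability vector; actions are sampled from
it directly.

Learning contrasts two fixed points per transition. The *free phase*
settles with only `s` applied (state written x-check). The *weakly
clamped phase* restarts from the free fixed point with an extra force
on the output units,

    ... + beta * A(s) * (a_o - x_o),

pulling the settled output toward the one-hot executed action `a`,
scaled by the temporal-difference advantage `A(s) = r + gamma_d V(s') - V(s)`
(terminal transitions use `A = r - V(s)`); the settled state is x-hat.
Weights then change by the single-phase contrastive rule

    dw_pre,post = (alpha / beta) * xhat_pre * (xhat_post - xcheck_post),

a local, Hebbian-style product of presynaptic clamped activity and the
postsynaptic phase contrast. The classical two-phase rule
`(alpha/beta) * (xhat_pre xhat_post - xcheck_pre xcheck_post)` is kept
as a comparison mode; the two coincide on the input-to-hidden block
because the input is clamped in both phases. Biases use the same rule
with presynaptic activity 1. Minibatch deltas are averaged, making the
learning rates batch-size invariant. A supervised clamping mode
(`beta * (T - x_o)` toward a target vector `T`) is included for testing
the clamped dynamics outside the reinforcement setting.

Positive advantage pulls the settled policy toward the executed action;
negative advantage pushes it away. In a gradient view, the update
approximates descent on the nudging cost `C = A/2 * ||a - x_out*||^2`
through the settled state: on small tied-feedback networks the measured
cosine between the contrastive update and the negative finite-difference
gradient of `C` is ~1.0 (see the acceptance suite).

**Critic (backpropagation).** `V(s)` is a one-hidden-layer perceptron
(same hard-sigmoid variant, linear output) trained by exact gradient
descent on the mean squared TD error `(y - V(s))^2`, `y = r` (terminal)
or `r + gamma_d V(s')`, with the target detached and one Adam step per
learning step (beta1 = 0.9, beta2 = 0.999, eps = 1e-8). There is no
target network; `y` is recomputed from the current critic at every
update. Gradients are verified against central finite differences.

**Loop.** Per environment step: settle the free phase on the current
observation, sample an action from the settled softmax state, store the
transition in a capacity-1000 FIFO replay buffer, and — once the buffer
holds one minibatch (20) — run one learning step on a uniformly sampled
batch: advantages from the pre-update critic, free + clamped settling of
the actor on the batch, contrastive actor update, then one critic Adam
step. A baseline agent of identical architecture trained purely by
backpropagation (advantage-weighted log-likelihood policy gradient with
Adam, same critic) is provided for comparison.

## Parameters

Per-task defaults (`epac.experiments.TASK_DEFAULTS`):

| task | actor | critic | alpha1 | alpha2 | beta | critic lr | free/clamped iters |
|---|---|---|---|---|---|---|---|
| cartpole | 4-256-2 | 4-256-1 | 1e-4 | 1e-4 | 0.02 | 1e-3 | 150 / 25 |
| acrobot | 6-256-3 | 6-256-1 | 1e-3 | 1e-3 | 0.02 | 1e-3 | 150 / 25 |
| lunarlander | 8-512-4 | 8-512-1 | 1e-4 | 2e-3 | 0.03 | 3e-4 | 180 / 25 |
| bandit | 1-16-2 | 1-16-1 | 0.05 | 0.05 | 0.02 | 1e-2 | 60 / 15 |

All tasks: replay capacity 1000, minibatch 20; step caps 1000
(cartpole, acrobot), 2000 (lunarlander). `alpha1`/`alpha2` are the
input-to-hidden / hidden-to-output actor learning rates; `beta` is
dimensionless nudging strength. The bandit row is this package's own
fixture scale, chosen so the closed-form optimal arm is recoverable
within a few hundred one-step episodes.

Quantities the architecture needs but the hyperparameter table does not
pin down are exposed in `EPConfig` with these defaults:

- **Euler step `h` = 0.5.** `h` does not move the fixed points, only the
  settling rate; 0.5 converges geometrically (contraction ~(1-h) per
  iteration) well within the 150/25 iteration budgets.
- **Feedback gain `gamma` = 1.0, tied feedback** (`w_oj = w_jo^T`).
  Symmetric unit-gain feedback is the convention for settling networks
  of this family; `gamma` scales how strongly the nudged output state
  recruits the hidden layer during the clamped phase (at `gamma = 0`
  the hidden contrast vanishes and input weights stop learning; at 0.5
  the hidden pathway learns too slowly to keep the policy
  state-dependent as output confidence grows). Untied (frozen random)
  feedback is available.
- **Initialization**: Glorot-uniform weights, zero biases, from a seeded
  generator.
- **Fixed iteration counts** rather than tolerance-based early stopping
  by default (`convergence_tol=None`), so runs are exactly reproducible;
  a tolerance can be set to enable early stopping.
- **Hard-sigmoid variants**: A = `clip(u, 0, 1)` (sparse, ReLU-like
  codes) for cartpole/lunarlander, B = `clip((u+1)/2, 0, 1)` (dense
  codes, linear at 0) for acrobot. Which published form maps to which
  task is not decidable from the source material; the assignment is
  config-exposed.

## Discounting and truncation

Two choices here departed from the most literal reading of the
advantage definition, and both were forced by observed instability:

- **Discount `gamma_d` = 0.99** (control tasks; `advantage()` itself
  defaults to the undiscounted form, and `discount=1.0` is a config
  switch). With `gamma_d = 1` the bootstrapped value scale is unbounded
  in episode length; under replay the critic's estimates were observed
  to swing far outside the feasible value range (estimates in
  [-25, 108] against true values in [1, 200]), producing advantage
  spikes of magnitude ~25 (nudge `beta*A` ~ 0.5). Both the EP actor and
  the BP baseline then collapse onto a saturated single-action policy
  within a few hundred episodes. The collapse is unrecoverable by
  construction: once the settled softmax reaches exactly (1, 0), the
  clamping force `beta*A*(a - x)` is identically zero for every
  advantage, so no corrective signal survives. At 0.99 both agents are
  stable and reproduce the qualitative comparison (BP fast and less
  stable, EP-BP slower and more consistent).
- **Truncation bootstrapping.** The bundled cart-pole ends episodes at
  the standard 200-step cap. A cap is not a failure: the state retains
  its value. Transitions that end an episode at the cap are therefore
  stored as non-terminal (TD targets bootstrap through them), while
  pole-fall transitions are true terminals. Treating the cap as
  terminal injects a large spurious negative advantage exactly on the
  best states (y = 1 vs V(s) ~ 86) as soon as the policy becomes good
  enough to reach the cap, and was observed to re-destabilize otherwise
  healthy runs.

## Environments and the synthetic fixture

- **CartPoleEnv**: self-contained cart-pole with the standard constants
  (gravity 9.8, cart 1.0 kg, pole 0.1 kg, half-length 0.5 m, force 10 N,
  Euler at tau = 0.02 s), v0 termination (|x| > 2.4, |theta| > 12 deg,
  200-step cap), +1 reward per step. Unit tests validate one step
  against independently hand-integrated equations of motion.
- **BanditEnv**: two-armed Bernoulli bandit, constant state [1.0],
  one-step episodes; arm 0 pays 1 with probability `p_better` (default
  0.9), arm 1 with `1 - p_better`. Optimal policy and optimal mean
  reward (`p_better`) are known in closed form, which makes it a
  parameter-recovery fixture: an agent that learns must drive its
  arm-0 probability toward 1.
- **GymAdapter**: lazy adapter for gym/gymnasium environments
  (Acrobot-v1, LunarLander-v2) behind the same
  `reset/step -> (state, reward, terminal)` contract.

What the fixtures do *not* emulate: stochastic environment transitions
(cart-pole noise enters only through the initial state), high-dimensional
or partially observed states, and reward sparsity/shaping found in
harder control suites. Passing tests on them shows the learning
machinery is correct and that the published cart-pole behavior is
reproduced; it does not certify performance on Acrobot/LunarLander,
which require an external gym install.

## Metrics

Per run: total reward per episode; the softmax probability assigned to
each executed action; the mean and **population** SD of reward over the
last 25% of episodes (floor(0.25 E) episodes, at least one). Across
seeds (8 by default): mean and standard error of the per-run
last-quartile means, and the average of per-run last-quartile SDs (the
stability measure). Logs persist as one CSV per run (episode,
total_reward, mean_action_prob, steps) plus a JSON report; recomputing
a report from the CSVs is bit-identical to computing it in memory.

## Numerical choices

- Settling runs in a compiled (numba) kernel; a pure-numpy single-step
  reference (`free_step`) defines the dynamics and the two are asserted
  equal in tests. Settling is deterministic; full runs replay
  bit-identically from a seed (all randomness flows from
  `numpy.random.SeedSequence(seed)`).
- Rows whose nudging coefficient `beta*A` is exactly zero keep the free
  fixed point as their clamped state: the force vanishes, the dynamics
  reduce to the free dynamics, and the steady state is unchanged by
  definition. This makes zero-advantage neutrality exact rather than
  approximate, at the cost of an (immaterial, ~1e-45) discontinuity
  against `A -> 0`.
- The softmax subtracts the row max before exponentiation; output
  states stay probability vectors under the Euler update for h <= 1.
- Divergence (non-finite state) raises an error naming the iteration
  and layer; with hard-sigmoid hidden units and softmax outputs the
  reachable states are bounded, so this guards against pathological
  weights rather than normal operation.
- The advantage identity `A = y - V(s)` is exact by construction
  (computed, not re-derived, from the same `y` and `V`).

## Problem sizes

The test and acceptance workloads use the bundled environments: the
cart-pole confidence check trains 700 episodes on two seeds with the
full published network sizes (the dominant cost, a few minutes per seed
via the compiled kernel); bandit runs use 400-500 one-step episodes;
oracle checks (finite differences, fine-step settling) run on 3-5-2 to
4-8-2 networks where brute force is exact and fast.

## Known limitations

- Acrobot and LunarLander run only through the gym adapter; their
  defaults are provided but untested here.
- The saturation trap described above is structural in
  advantage-nudged softmax dynamics: any configuration that lets
  confidence saturate before the policy is good cannot recover.
  The shipped defaults avoid it on most cart-pole seeds, but not all:
  across seeds a minority of runs can still saturate early onto a poor
  policy. Multi-seed reporting (8 runs by default) is part of the
  protocol for exactly this reason.
- The critic is a plain TD(0) learner under replay: no target network,
  no importance correction. This mirrors the architecture the package
  implements; it is not the most stable known variant.
- Undiscounted (`discount=1.0`) operation is faithful to the advantage
  definition but demonstrably unstable on the control tasks; it is
  exposed for completeness, not recommended.
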