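# epac — actor-critic reinforcement learning with an Equilibrium Propagation actor

Backpropagation is a powerful but biologically implausible learning
rule. Equilibrium Propagation (EP) is an alternative for settling
recurrent networks: apply the input, let the network relax to a fixed
point, then *weakly nudge* the outputs toward a target and relax again —
the local contrast between the two fixed points drives a Hebbian-style
weight update that approximates the backpropagated gradient. `epac`
brings this mechanism to reinforcement learning: an actor-critic agent
whose **policy network is trained by EP** and whose **value network is
trained by ordinary backpropagation**, for researchers studying
biologically plausible learning on classic control tasks.

## The learning rule

The actor settles free-phase activations x̌ (input only) and clamped
phase activations x̂, where the output units feel an extra force

    β · A(s) · (a − x_o),          A(s) = r + γ_d·V(s′) − V(s)

pulling them toward the executed action `a` scaled by the TD advantage
from the critic. Weights then update with the single-phase contrastive
rule

    Δw_pre,post = (α/β) · x̂_pre · (x̂_post − x̌_post)

(the classical two-phase form Δw = (α/β)(x̂_pre·x̂_post − x̌_pre·x̌_post)
is available as a comparison mode). The critic V(s) is a one-hidden-
layer perceptron minimizing (y − V(s))² by exact gradients and Adam.
Transitions are replayed from a capacity-1000 FIFO buffer in uniform
minibatches of 20. A baseline agent of identical architecture trained
purely by backpropagation is included.

Everything runs offline: a self-contained cart-pole (standard physics,
v0 rules) and a two-armed bandit fixture are bundled; Acrobot-v1 and
LunarLander-v2 work through a gym/gymnasium adapter when one is
installed.

## Worked example

Train the EP-BP agent on the bandit fixture (arm 0 pays with
probability 0.9, arm 1 with 0.1) and inspect what it learned:

```python
import numpy as np
from epac import make_config, run_training, settle_free

cfg = make_config("bandit", seed=0, episodes=500)
result = run_training(cfg)

r = result.rewards
print(f"mean reward, first 125 episodes: {r[:125].mean():.2f}")
print(f"mean reward, last 125 episodes:  {r[-125:].mean():.2f}")

phase = settle_free(result.actor, np.array([1.0]), cfg.ep)
print(f"learned P(better arm): {phase.free.x_out[0, 0]:.3f}")
```

prints

```
mean reward, first 125 episodes: 0.86
mean reward, last 125 episodes:  0.92
learned P(better arm): 1.000
```

The agent's reward rate climbs from near-chance toward the optimal 0.9,
and the settled softmax output — the policy itself — has converged on
the better arm.

The same from the shell, plus cart-pole:

```
epac train --task bandit --seed 0 --episodes 500 --out runs/
epac train --task cartpole --seed 0 --episodes 700 --out runs/
epac report --runs runs/
```

`train` writes one CSV per run (episode, total_reward,
mean_action_prob, steps); `report` aggregates runs into the evaluation
statistics: mean and SEM across seeds of the last-quartile mean reward,
and the cross-seed average of last-quartile reward SD (the stability
measure used to compare EP-BP with the BP baseline).

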