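"""End-to-end training loop: act, store, replay, update.

Each environment step the agent settles the actor's free phase on the
current observation, samples an action from the settled softmax output,
stores the transition, and (once the replay buffer holds a minibatch)
performs one learning step: TD targets and advantages from the current
critic, a contrastive actor update through free + clamped settling, then
one Adam step on the critic.  The actor update always reads critic
values taken *before* the critic's own update.

A baseline agent with the same architecture trained purely by
backpropagation (advantage-weighted log-likelihood policy gradient with
Adam) is provided for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Tuple

import numpy as np

from ._optim import AdamState
from .actor import (ActorParams, EPConfig, PhaseResult, hidden_activation,
                    settle_clamped, settle_free, softmax)
from .critic import CriticParams, critic_forward, critic_update
from .learning import LearningRates, advantage, apply_update, compute_update
from .replay import ReplayBuffer, Transition


@dataclass
class AgentConfig:
    """Everything needed to reproduce one training run."""

    task: str
    n_inputs: int
    n_actions: int
    n_hidden: int = 256
    critic_hidden: int = 256
    lr: LearningRates = field(default_factory=lambda: LearningRates(1e-4, 1e-4))
    critic_lr: float = 1e-3
    ep: EPConfig = field(default_factory=EPConfig)
    replay_capacity: int = 1000
    batch_size: int = 20
    episodes: int = 1000
    max_steps: int = 1000
    seed: int = 0
    algo: str = "ep_bp"          # or "bp_only"
    discount: float = 1.0
    bp_actor_lr: float = 1e-3    # baseline only
    tie_feedback: bool = True

    def __post_init__(self):
        if self.algo not in ("ep_bp", "bp_only"):
            raise ValueError(f"unknown algo {self.algo!r}")
        if self.batch_size < 1 or self.replay_capacity < self.batch_size:
            raise ValueError("need replay_capacity >= batch_size >= 1")


@dataclass
class EpisodeLog:
    """Per-episode record: total reward and the softmax probability the
    actor assigned to each action it executed."""

    episode: int
    total_reward: float
    action_probs: List[float]
    steps: int

    @property
    def mean_action_prob(self) -> float:
        return float(np.mean(self.action_probs))


def select_action(params: ActorParams, s: np.ndarray, cfg: EPConfig,
                  rng: np.random.Generator) -> Tuple[int, np.ndarray]:
    """Settle the free phase on ``s`` and sample from the settled output.

    Returns the sampled action index and the full probability vector
    (the settled output state).
    """
    phase = settle_free(params, s, cfg)
    probs = phase.free.x_out[0]
    if np.any(probs < -1e-9) or abs(probs.sum() - 1.0) > 1e-6:
        raise ValueError(f"settled output is not a probability vector: {probs}")
    p = np.clip(probs, 0.0, None)
    p = p / p.sum()
    a = int(rng.choice(len(p), p=p))
    return a, probs


class BPActor:
    """Feedforward softmax policy of the same layer sizes, trained by
    backpropagation: one Adam step on the advantage-weighted negative
    log-likelihood of the replayed actions."""

    def __init__(self, n_inputs: int, n_hidden: int, n_actions: int,
                 rng: np.random.Generator,
                 activation: str = "hard_sigmoid_A"):
        lim1 = np.sqrt(6.0 / (n_inputs + n_hidden))
        lim2 = np.sqrt(6.0 / (n_hidden + n_actions))
        self.w1 = rng.uniform(-lim1, lim1, size=(n_inputs, n_hidden))
        self.b1 = np.zeros(n_hidden)
        self.w2 = rng.uniform(-lim2, lim2, size=(n_hidden, n_actions))
        self.b2 = np.zeros(n_actions)
        self.activation = activation
        self.adam = AdamState.for_params(self._pdict())

    def _pdict(self) -> dict:
        return {"w1": self.w1, "b1": self.b1, "w2": self.w2, "b2": self.b2}

    def probs(self, S: np.ndarray) -> np.ndarray:
        S = np.atleast_2d(np.asarray(S, dtype=float))
        h = hidden_activation(S @ self.w1 + self.b1, self.activation)
        return softmax(h @ self.w2 + self.b2)

    def select_action(self, s: np.ndarray, rng: np.random.Generator
                      ) -> Tuple[int, np.ndarray]:
        p = self.probs(s)[0]
        p = np.clip(p, 0.0, None)
        p = p / p.sum()
        return int(rng.choice(len(p), p=p)), p

    def gradient(self, S: np.ndarray, actions: np.ndarray, adv: np.ndarray
                 ) -> dict:
        """Exact gradient of mean(-A * log pi(a|s)) over the batch."""
        S = np.atleast_2d(np.asarray(S, dtype=float))
        B = S.shape[0]
        u = S @ self.w1 + self.b1
        h = hidden_activation(u, self.activation)
        pi = softmax(h @ self.w2 + self.b2)
        onehot = np.zeros_like(pi)
        onehot[np.arange(B), actions] = 1.0
        dlogits = (adv[:, None] * (pi - onehot)) / B
        if self.activation == "hard_sigmoid_A":
            dact = ((u > 0.0) & (u < 1.0)).astype(float)
        else:
            dact = 0.5 * ((u > -1.0) & (u < 1.0)).astype(float)
        dh = dlogits @ self.w2.T
        du = dh * dact
        return {"w1": S.T @ du, "b1": du.sum(axis=0),
                "w2": h.T @ dlogits, "b2": dlogits.sum(axis=0)}

    def update(self, S, actions, adv, lr: float) -> None:
        self.adam.step(self._pdict(), self.gradient(S, actions, adv), lr)


def learn_step(actor: ActorParams, critic: CriticParams,
               buffer: ReplayBuffer, cfg: AgentConfig) -> str:
    """One replayed learning step for the EP-BP agent (in place).

    Returns ``"not_ready"`` (no-op) until the buffer holds a minibatch,
    otherwise ``"updated"``.
    """
    if not buffer.is_ready(cfg.batch_size):
        return "not_ready"
    S, a_idx, r, S_next, term = buffer.sample_arrays(cfg.batch_size)
    V_s = critic_forward(critic, S)
    V_sn = critic_forward(critic, S_next)
    adv = advantage(r, V_s, V_sn, term, discount=cfg.discount)
    onehot = np.zeros((cfg.batch_size, cfg.n_actions))
    onehot[np.arange(cfg.batch_size), a_idx] = 1.0
    phase = settle_free(actor, S, cfg.ep)
    settle_clamped(phase, actor, onehot, adv.A, cfg.ep)
    delta = compute_update(phase, S, cfg.lr, cfg.ep.beta)
    apply_update(actor, delta)
    critic_update(critic, S, adv.y, cfg.critic_lr)
    return "updated"


def bp_baseline_step(actor: BPActor, critic: CriticParams,
                     buffer: ReplayBuffer, cfg: AgentConfig) -> str:
    """Baseline learning step: policy-gradient actor, identical critic."""
    if not buffer.is_ready(cfg.batch_size):
        return "not_ready"
    S, a_idx, r, S_next, term = buffer.sample_arrays(cfg.batch_size)
    V_s = critic_forward(critic, S)
    V_sn = critic_forward(critic, S_next)
    adv = advantage(r, V_s, V_sn, term, discount=cfg.discount)
    actor.update(S, a_idx, adv.A, cfg.bp_actor_lr)
    critic_update(critic, S, adv.y, cfg.critic_lr)
    return "updated"


@dataclass
class TrainingResult:
    """Episode logs plus the trained models (for post-hoc evaluation)."""

    episodes: List[EpisodeLog]
    actor: object          # ActorParams or BPActor
    critic: CriticParams
    config: AgentConfig

    @property
    def rewards(self) -> np.ndarray:
        return np.array([e.total_reward for e in self.episodes])


def build_agent(cfg: AgentConfig):
    """Seeded construction of actor, critic, buffer and action RNG."""
    ss = np.random.SeedSequence(cfg.seed)
    k_actor, k_critic, k_action, k_buffer = ss.spawn(4)
    if cfg.algo == "ep_bp":
        actor = ActorParams.initialize(
            cfg.n_inputs, cfg.n_hidden, cfg.n_actions,
            np.random.default_rng(k_actor), tie_feedback=cfg.tie_feedback)
    else:
        actor = BPActor(cfg.n_inputs, cfg.n_hidden, cfg.n_actions,
                        np.random.default_rng(k_actor),
                        activation=cfg.ep.hidden_activation)
    critic = CriticParams.initialize(
        cfg.n_inputs, cfg.critic_hidden, np.random.default_rng(k_critic),
        activation=cfg.ep.hidden_activation)
    buffer = ReplayBuffer(cfg.replay_capacity,
                          seed=k_buffer.generate_state(1)[0] % (2 ** 31))
    action_rng = np.random.default_rng(k_action)
    return actor, critic, buffer, action_rng


def run_training(cfg: AgentConfig, env=None,
                 learning: bool = True) -> TrainingResult:
    """Run ``cfg.episodes`` episodes of at most ``cfg.max_steps`` steps.

    Fully seeded: the actor/critic initialization, action sampling,
    replay sampling and (when ``env`` is None) the environment all
    derive from ``cfg.seed``, so a given (config, seed) pair replays an
    identical episode log.  ``learning=False`` runs the policy without
    any parameter updates.
    """
    if env is None:
        from .envs import make_env
        env_seed = int(np.random.SeedSequence(cfg.seed).generate_state(2)[1]
                       % (2 ** 31))
        env = make_env(cfg.task, seed=env_seed)
    if getattr(env, "n_inputs", cfg.n_inputs) != cfg.n_inputs or \
            getattr(env, "n_actions", cfg.n_actions) != cfg.n_actions:
        raise ValueError(
            "environment state/action dimensions do not match config "
            f"(env: {env.n_inputs}/{env.n_actions}, "
            f"config: {cfg.n_inputs}/{cfg.n_actions})")
    actor, critic, buffer, action_rng = build_agent(cfg)
    logs: List[EpisodeLog] = []
    for ep_i in range(cfg.episodes):
        s = env.reset()
        total_r = 0.0
        probs_taken: List[float] = []
        steps = 0
        for j in range(cfg.max_steps):
            if cfg.algo == "ep_bp":
                a, probs = select_action(actor, s, cfg.ep, action_rng)
            else:
                a, probs = actor.select_action(s, action_rng)
            s_next, r, terminal = env.step(a)
            # a step-cap truncation ends the episode but the state keeps
            # its value, so the stored transition bootstraps through it
            truncated = bool(getattr(env, "truncated", False))
            buffer.push(Transition(s, a, r, s_next,
                                   terminal and not truncated))
            total_r += r
            probs_taken.append(float(probs[a]))
            steps += 1
            s = s_next
            if learning:
                if cfg.algo == "ep_bp":
                    learn_step(actor, critic, buffer, cfg)
                else:
                    bp_baseline_step(actor, critic, buffer, cfg)
            if terminal:
                break
        logs.append(EpisodeLog(ep_i, total_r, probs_taken, steps))
    return TrainingResult(logs, actor, critic, cfg)
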