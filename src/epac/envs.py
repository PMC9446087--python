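"""Environments speaking a minimal gym-like contract.

Contract: ``reset(seed=None) -> state`` (1-D float array) and
``step(action: int) -> (state, reward, terminal)``.  Environments expose
``n_inputs`` (state dimension) and ``n_actions``.

Two environments are bundled so nothing needs downloading: a two-armed
Bernoulli bandit (a one-step fixture whose optimal policy is known in
closed form) and the classic cart-pole balancing task with the standard
physics constants and the v0 termination rules.  Acrobot and LunarLander
are reachable only through :class:`GymAdapter` when a gym implementation
is installed.
"""

from __future__ import annotations

import math
from typing import Optional, Tuple

import numpy as np

State = np.ndarray


class BanditEnv:
    """Two-armed Bernoulli bandit with one-step episodes.

    The state is the constant vector [1.0].  Action 0 pays 1 with
    probability ``p_better``, action 1 with probability ``1 - p_better``;
    the optimal policy always pulls arm 0 and earns ``p_better`` per
    episode in expectation.
    """

    n_inputs = 1
    n_actions = 2

    def __init__(self, p_better: float = 0.9, seed: Optional[int] = None):
        if not 0.5 < p_better <= 1.0:
            raise ValueError(f"p_better must be in (0.5, 1], got {p_better}")
        self.p_better = p_better
        self._rng = np.random.default_rng(seed)
        self._state = np.array([1.0])

    def reset(self, seed: Optional[int] = None) -> State:
        if seed is not None:
            self._rng = np.random.default_rng(seed)
        return self._state.copy()

    def step(self, action: int) -> Tuple[State, float, bool]:
        if action not in (0, 1):
            raise ValueError(f"invalid action {action}")
        p = self.p_better if action == 0 else 1.0 - self.p_better
        r = 1.0 if self._rng.random() < p else 0.0
        return self._state.copy(), r, True


class CartPoleEnv:
    """Cart-pole balancing with the standard physics, v0 rules.

    State (x, x_dot, theta, theta_dot); two actions push the cart left
    or right with a fixed force.  Dynamics are Euler-integrated at
    tau = 0.02 s.  Reward is +1 every step; the episode ends when
    |x| > 2.4 m, |theta| > 12 degrees, or after 200 steps.
    """

    n_inputs = 4
    n_actions = 2

    gravity = 9.8
    masscart = 1.0
    masspole = 0.1
    length = 0.5           # half the pole length, m
    force_mag = 10.0
    tau = 0.02             # s
    x_threshold = 2.4
    theta_threshold = 12.0 * 2.0 * math.pi / 360.0
    max_steps = 200        # v0 episode cap

    def __init__(self, seed: Optional[int] = None):
        self._rng = np.random.default_rng(seed)
        self._state: Optional[np.ndarray] = None
        self._steps = 0
        #: True when the last step ended the episode at the step cap
        #: rather than by the pole falling.  A time-capped episode is a
        #: truncation: the state still has value, so TD targets should
        #: bootstrap through it instead of treating it as terminal.
        self.truncated = False

    def reset(self, seed: Optional[int] = None) -> State:
        if seed is not None:
            self._rng = np.random.default_rng(seed)
        self._state = self._rng.uniform(-0.05, 0.05, size=4)
        self._steps = 0
        self.truncated = False
        return self._state.copy()

    def step(self, action: int) -> Tuple[State, float, bool]:
        if self._state is None:
            raise RuntimeError("call reset() before step()")
        if action not in (0, 1):
            raise ValueError(f"invalid action {action}")
        x, x_dot, theta, theta_dot = self._state
        force = self.force_mag if action == 1 else -self.force_mag
        costheta = math.cos(theta)
        sintheta = math.sin(theta)
        total_mass = self.masscart + self.masspole
        polemass_length = self.masspole * self.length
        temp = (force + polemass_length * theta_dot ** 2 * sintheta) / total_mass
        thetaacc = (self.gravity * sintheta - costheta * temp) / (
            self.length * (4.0 / 3.0 - self.masspole * costheta ** 2 / total_mass))
        xacc = temp - polemass_length * thetaacc * costheta / total_mass
        x = x + self.tau * x_dot
        x_dot = x_dot + self.tau * xacc
        theta = theta + self.tau * theta_dot
        theta_dot = theta_dot + self.tau * thetaacc
        self._state = np.array([x, x_dot, theta, theta_dot])
        self._steps += 1
        fell = abs(x) > self.x_threshold or abs(theta) > self.theta_threshold
        terminal = fell or self._steps >= self.max_steps
        self.truncated = terminal and not fell
        return self._state.copy(), 1.0, terminal


class GymAdapter:
    """Adapter putting a gymnasium/gym environment behind the contract.

    Imported lazily: the bundled environments cover all tests, and the
    adapter is only needed when a gym implementation is installed (e.g.
    for Acrobot-v1 or LunarLander-v2).  Truncation is treated the same
    as termination.
    """

    truncated = False

    def __init__(self, env_id: str, seed: Optional[int] = None):
        try:
            import gymnasium as gym
        except ImportError:  # pragma: no cover - depends on host install
            try:
                import gym  # type: ignore
            except ImportError as exc:
                raise ImportError(
                    "GymAdapter requires gymnasium (or gym) to be installed"
                ) from exc
        self._env = gym.make(env_id)
        self._seed = seed
        self.n_inputs = int(np.prod(self._env.observation_space.shape))
        self.n_actions = int(self._env.action_space.n)

    def reset(self, seed: Optional[int] = None) -> State:
        if seed is None:
            seed = self._seed
            self._seed = None  # seed only the first reset by default
        out = self._env.reset(seed=seed)
        obs = out[0] if isinstance(out, tuple) else out
        return np.asarray(obs, dtype=float).ravel()

    def step(self, action: int) -> Tuple[State, float, bool]:
        out = self._env.step(int(action))
        if len(out) == 5:
            obs, r, terminated, truncated, _ = out
            done = bool(terminated or truncated)
            self.truncated = bool(truncated and not terminated)
        else:  # old gym API
            obs, r, done, _ = out
            self.truncated = False
        return np.asarray(obs, dtype=float).ravel(), float(r), bool(done)


_GYM_IDS = {"acrobot": "Acrobot-v1", "lunarlander": "LunarLander-v2"}


def make_env(task: str, seed: Optional[int] = None, **kwargs):
    """Environment factory by task name.

    'cartpole' and 'bandit' use the bundled implementations; 'acrobot'
    and 'lunarlander' go through the gym adapter.
    """
    task = task.lower()
    if task == "cartpole":
        return CartPoleEnv(seed=seed)
    if task == "bandit":
        return BanditEnv(seed=seed, **kwargs)
    if task in _GYM_IDS:
        return GymAdapter(_GYM_IDS[task], seed=seed)
    raise ValueError(f"unknown task {task!r}")
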