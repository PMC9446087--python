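"""Value network V(s): one hidden layer, trained by gradient descent on
squared TD error with Adam.

The hidden layer uses the same hard-sigmoid variant as the actor; the
output is linear (task values may be unbounded below, as in Acrobot).
The TD target y is treated as a constant — no gradient flows through the
parameters that produced it.  Gradients are exact (hand-derived
backprop) and checked against central finite differences in the tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ._optim import AdamState
from .actor import hidden_activation


@dataclass
class CriticParams:
    w1: np.ndarray  # (n_inputs, n_hidden)
    b1: np.ndarray  # (n_hidden,)
    w2: np.ndarray  # (n_hidden, 1)
    b2: np.ndarray  # (1,)
    activation: str = "hard_sigmoid_A"
    adam: Optional[AdamState] = None

    def __post_init__(self):
        if self.w1.shape[1] != self.w2.shape[0] or self.w2.shape[1] != 1:
            raise ValueError("critic shapes inconsistent")
        if self.adam is None:
            self.adam = AdamState.for_params(self._pdict())

    def _pdict(self) -> dict:
        return {"w1": self.w1, "b1": self.b1, "w2": self.w2, "b2": self.b2}

    def copy(self) -> "CriticParams":
        c = CriticParams(self.w1.copy(), self.b1.copy(), self.w2.copy(),
                         self.b2.copy(), self.activation)
        c.adam.t = self.adam.t
        c.adam.m = {k: v.copy() for k, v in self.adam.m.items()}
        c.adam.v = {k: v.copy() for k, v in self.adam.v.items()}
        return c

    @classmethod
    def initialize(cls, n_inputs: int, n_hidden: int,
                   rng: np.random.Generator,
                   activation: str = "hard_sigmoid_A") -> "CriticParams":
        lim1 = np.sqrt(6.0 / (n_inputs + n_hidden))
        lim2 = np.sqrt(6.0 / (n_hidden + 1))
        return cls(
            w1=rng.uniform(-lim1, lim1, size=(n_inputs, n_hidden)),
            b1=np.zeros(n_hidden),
            w2=rng.uniform(-lim2, lim2, size=(n_hidden, 1)),
            b2=np.zeros(1),
            activation=activation,
        )


def _act(u: np.ndarray, variant: str) -> np.ndarray:
    if variant == "identity":  # diagnostic mode: makes V linear in s
        return u
    return hidden_activation(u, variant)


def _act_deriv(u: np.ndarray, variant: str) -> np.ndarray:
    if variant == "identity":
        return np.ones_like(u)
    if variant == "hard_sigmoid_A":
        return ((u > 0.0) & (u < 1.0)).astype(float)
    if variant == "hard_sigmoid_B":
        return 0.5 * ((u > -1.0) & (u < 1.0)).astype(float)
    raise ValueError(f"unknown variant {variant!r}")


def critic_forward(params: CriticParams, s: np.ndarray) -> np.ndarray:
    """V(s) = w2' p(w1' s + b1) + b2; scalar for a single state,
    length-B vector for a (B, n_inputs) batch."""
    s_arr = np.asarray(s, dtype=float)
    single = s_arr.ndim == 1
    S = s_arr[None, :] if single else s_arr
    if S.shape[1] != params.w1.shape[0]:
        raise ValueError(
            f"state dimension {S.shape[1]} != {params.w1.shape[0]}")
    V = _act(S @ params.w1 + params.b1, params.activation) @ params.w2 \
        + params.b2
    V = V[:, 0]
    return float(V[0]) if single else V


def critic_loss(y, V_s) -> float:
    """Mean squared TD error over the minibatch."""
    y = np.asarray(y, dtype=float)
    V_s = np.asarray(V_s, dtype=float)
    return float(np.mean((y - V_s) ** 2))


def critic_gradient(params: CriticParams, S: np.ndarray, y: np.ndarray
                    ) -> dict:
    """Exact gradient of mean((y - V(s))^2) w.r.t. all parameters.

    y enters as data: the returned gradient is unaffected by whichever
    network produced it.
    """
    S = np.atleast_2d(np.asarray(S, dtype=float))
    y = np.asarray(y, dtype=float).reshape(-1)
    B = S.shape[0]
    u = S @ params.w1 + params.b1
    hidden = _act(u, params.activation)
    V = (hidden @ params.w2)[:, 0] + params.b2[0]
    dV = 2.0 * (V - y) / B              # d loss / d V, per sample
    dw2 = hidden.T @ dV[:, None]
    db2 = np.array([dV.sum()])
    dh = dV[:, None] * params.w2[:, 0][None, :]
    du = dh * _act_deriv(u, params.activation)
    grads = {"w1": S.T @ du, "b1": du.sum(axis=0), "w2": dw2, "b2": db2}
    for k, g in grads.items():
        if not np.all(np.isfinite(g)):
            raise FloatingPointError(f"non-finite critic gradient in {k}")
    return grads


def critic_update(params: CriticParams, S: np.ndarray, y: np.ndarray,
                  lr: float) -> CriticParams:
    """One Adam step on the squared TD error over the batch (in place)."""
    S = np.atleast_2d(np.asarray(S, dtype=float))
    if S.shape[0] == 0:
        raise ValueError("empty critic batch")
    grads = critic_gradient(params, S, y)
    params.adam.step(params._pdict(), grads, lr)
    return params
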