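"""The policy network as a settling dynamical system.

The actor is a three-layer recurrent network (input -> hidden -> output,
with output -> hidden feedback) whose state evolves by Euler-integrated
leaky dynamics toward a fixed point.  Learning contrasts two such fixed
points: a *free* phase, where only the observation drives the network,
and a *weakly clamped* phase, where the output units are additionally
nudged toward the executed action with a force proportional to the
temporal-difference advantage.  Hidden units use a hard sigmoid; the
output layer applies a softmax inside the dynamics, so the settled output
state is the action-selection probability vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ._kernels import HARD_SIGMOID_A, HARD_SIGMOID_B, settle_kernel

_VARIANTS = {"hard_sigmoid_A": HARD_SIGMOID_A, "hard_sigmoid_B": HARD_SIGMOID_B}


class SettlingDivergenceError(RuntimeError):
    """Non-finite network state during settling.

    Carries ``iteration`` and ``layer`` identifying where the state
    first left the finite range.
    """

    def __init__(self, iteration: int, layer: str):
        self.iteration = iteration
        self.layer = layer
        super().__init__(
            f"non-finite activations in layer {layer!r} at iteration {iteration}"
        )


@dataclass
class EPConfig:
    """Dynamics constants for the settling actor.

    h : Euler time-step of the leaky update, in (0, 1].
    beta : nudging strength of the clamped phase (> 0); the weight update
        divides by beta, so the contrast between phases is read out on a
        beta-independent scale.
    gamma_fb : scale of the output -> hidden feedback term (>= 0).
    iters_free, iters_clamped : iteration counts of the two phases.
    hidden_activation : 'hard_sigmoid_A' (clip(u, 0, 1)) or
        'hard_sigmoid_B' (clip((u + 1)/2, 0, 1)).
    convergence_tol : optional early-stop threshold on max |delta x|;
        None runs the fixed iteration counts, which keeps runs exactly
        reproducible.
    """

    h: float = 0.5
    beta: float = 0.02
    gamma_fb: float = 1.0
    iters_free: int = 150
    iters_clamped: int = 25
    hidden_activation: str = "hard_sigmoid_A"
    convergence_tol: Optional[float] = None

    def __post_init__(self):
        if not 0.0 < self.h <= 1.0:
            raise ValueError(f"h must be in (0, 1], got {self.h}")
        if self.beta <= 0.0:
            raise ValueError(f"beta must be positive, got {self.beta}")
        if self.gamma_fb < 0.0:
            raise ValueError(f"gamma_fb must be >= 0, got {self.gamma_fb}")
        if self.iters_free < 1 or self.iters_clamped < 1:
            raise ValueError("phase iteration counts must be >= 1")
        if self.hidden_activation not in _VARIANTS:
            raise ValueError(f"unknown hidden_activation {self.hidden_activation!r}")

    @property
    def variant_code(self) -> int:
        return _VARIANTS[self.hidden_activation]


@dataclass
class ActorParams:
    """Synaptic weights and biases of the actor.

    ``w_out_hid`` carries the output -> hidden feedback; with
    ``tie_feedback`` it is kept equal to ``w_hid_out.T`` after every
    update (symmetric feedback), otherwise it is an independent matrix.
    """

    w_in_hid: np.ndarray   # (n_inputs, n_hidden)
    w_hid_out: np.ndarray  # (n_hidden, n_outputs)
    w_out_hid: np.ndarray  # (n_outputs, n_hidden)
    b_hid: np.ndarray      # (n_hidden,)
    b_out: np.ndarray      # (n_outputs,)
    tie_feedback: bool = True

    def __post_init__(self):
        n_in, n_hid = self.w_in_hid.shape
        if self.w_hid_out.shape[0] != n_hid:
            raise ValueError("w_hid_out rows must match hidden size")
        n_out = self.w_hid_out.shape[1]
        if self.w_out_hid.shape != (n_out, n_hid):
            raise ValueError("w_out_hid must be (n_outputs, n_hidden)")
        if self.b_hid.shape != (n_hid,) or self.b_out.shape != (n_out,):
            raise ValueError("bias shapes inconsistent with weights")

    @property
    def n_inputs(self) -> int:
        return self.w_in_hid.shape[0]

    @property
    def n_hidden(self) -> int:
        return self.w_in_hid.shape[1]

    @property
    def n_outputs(self) -> int:
        return self.w_hid_out.shape[1]

    def retie(self) -> None:
        """Re-impose w_out_hid == w_hid_out.T (no-op when untied)."""
        if self.tie_feedback:
            self.w_out_hid = np.ascontiguousarray(self.w_hid_out.T)

    def copy(self) -> "ActorParams":
        return ActorParams(
            self.w_in_hid.copy(), self.w_hid_out.copy(), self.w_out_hid.copy(),
            self.b_hid.copy(), self.b_out.copy(), self.tie_feedback,
        )

    @classmethod
    def initialize(cls, n_inputs: int, n_hidden: int, n_outputs: int,
                   rng: np.random.Generator, tie_feedback: bool = True
                   ) -> "ActorParams":
        """Glorot-uniform weights, zero biases, from a seeded generator."""
        w_ih = _glorot(rng, n_inputs, n_hidden)
        w_ho = _glorot(rng, n_hidden, n_outputs)
        w_oh = np.ascontiguousarray(w_ho.T) if tie_feedback \
            else _glorot(rng, n_outputs, n_hidden)
        return cls(w_ih, w_ho, w_oh, np.zeros(n_hidden), np.zeros(n_outputs),
                   tie_feedback)


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


@dataclass
class NetworkState:
    """Batched activations at one settling iteration."""

    x_hid: np.ndarray  # (B, n_hidden)
    x_out: np.ndarray  # (B, n_outputs)
    t: int = 0

    def copy(self) -> "NetworkState":
        return NetworkState(self.x_hid.copy(), self.x_out.copy(), self.t)


@dataclass
class PhaseResult:
    """Settled states of a settling episode.

    ``free`` is the free-phase steady state (x-check); ``clamped``, when a
    clamped phase was run, the weakly-clamped steady state (x-hat) that
    used ``free`` as its initial condition.  ``input`` is the (batched)
    observation that was applied throughout.
    """

    free: NetworkState
    input: np.ndarray
    clamped: Optional[NetworkState] = None
    converged_free: bool = False
    converged_clamped: bool = False


def hidden_activation(u, variant: str = "hard_sigmoid_A"):
    """Hard-sigmoid nonlinearity of the hidden units (elementwise, total).

    Variant A is clip(u, 0, 1); variant B is clip((u + 1)/2, 0, 1).
    """
    u = np.asarray(u, dtype=float)
    if variant == "hard_sigmoid_A" or variant == HARD_SIGMOID_A:
        return np.clip(u, 0.0, 1.0)
    if variant == "hard_sigmoid_B" or variant == HARD_SIGMOID_B:
        return np.clip((u + 1.0) / 2.0, 0.0, 1.0)
    raise ValueError(f"unknown hidden activation variant {variant!r}")


def softmax(logits: np.ndarray) -> np.ndarray:
    """Row-wise softmax with max-subtraction (matches the settling kernel)."""
    logits = np.atleast_2d(np.asarray(logits, dtype=float))
    e = np.exp(logits - logits.max(axis=1, keepdims=True))
    return e / e.sum(axis=1, keepdims=True)


def _as_batch(s: np.ndarray) -> np.ndarray:
    s = np.asarray(s, dtype=float)
    return s[None, :] if s.ndim == 1 else s


def initial_state(params: ActorParams, batch: int) -> NetworkState:
    """Settling initial condition: zero hidden state, uniform output state."""
    return NetworkState(
        np.zeros((batch, params.n_hidden)),
        np.full((batch, params.n_outputs), 1.0 / params.n_outputs),
        t=0,
    )


def free_step(state: NetworkState, params: ActorParams, input: np.ndarray,
              cfg: EPConfig) -> NetworkState:
    """One Euler step of the free-phase dynamics (numpy reference).

    Both layers read previous-iteration activations on the right-hand
    side: the hidden update sees the old output state (scaled by
    gamma_fb) and the output update sees the old hidden state, passed
    through a softmax inside the leaky integration.
    """
    s = _as_batch(input)
    if not (np.all(np.isfinite(state.x_hid)) and np.all(np.isfinite(state.x_out))):
        layer = "hidden" if not np.all(np.isfinite(state.x_hid)) else "output"
        raise SettlingDivergenceError(state.t, layer)
    pre_hid = s @ params.w_in_hid + cfg.gamma_fb * (state.x_out @ params.w_out_hid) \
        + params.b_hid
    p_hid = hidden_activation(pre_hid, cfg.hidden_activation)
    sm = softmax(state.x_hid @ params.w_hid_out + params.b_out)
    x_hid = state.x_hid + cfg.h * (-state.x_hid + p_hid)
    x_out = state.x_out + cfg.h * (-state.x_out + sm)
    return NetworkState(x_hid, x_out, state.t + 1)


def _run_phase(params: ActorParams, state: NetworkState, s: np.ndarray,
               cfg: EPConfig, nudge: np.ndarray, anchor: np.ndarray,
               iters: int) -> tuple[NetworkState, bool]:
    tol = -1.0 if cfg.convergence_tol is None else float(cfg.convergence_tol)
    x_hid, x_out, it, maxdiff, diverged = settle_kernel(
        np.ascontiguousarray(state.x_hid), np.ascontiguousarray(state.x_out),
        np.ascontiguousarray(s),
        np.ascontiguousarray(params.w_in_hid),
        np.ascontiguousarray(params.w_hid_out),
        np.ascontiguousarray(params.w_out_hid),
        params.b_hid, params.b_out,
        cfg.h, cfg.gamma_fb, nudge, anchor, iters, cfg.variant_code, tol,
    )
    if diverged >= 0:
        layer = "hidden" if not np.all(np.isfinite(x_hid)) else "output"
        raise SettlingDivergenceError(state.t + diverged, layer)
    converged = bool(maxdiff < (cfg.convergence_tol if cfg.convergence_tol
                                else 1e-6))
    return NetworkState(x_hid, x_out, state.t + it), converged


def settle_free(params: ActorParams, input: np.ndarray, cfg: EPConfig
                ) -> PhaseResult:
    """Run the free phase to its steady state.

    Applies the observation and iterates ``cfg.iters_free`` Euler steps
    from the zero-hidden / uniform-output initial condition (early
    stopping only if ``cfg.convergence_tol`` is set).
    """
    s = _as_batch(input)
    state = initial_state(params, s.shape[0])
    nudge = np.zeros(s.shape[0])
    anchor = np.zeros((s.shape[0], params.n_outputs))
    free, conv = _run_phase(params, state, s, cfg, nudge, anchor,
                            cfg.iters_free)
    return PhaseResult(free=free, input=s, converged_free=conv)


def settle_clamped(phase: PhaseResult, params: ActorParams,
                   action: np.ndarray, advantage, cfg: EPConfig
                   ) -> PhaseResult:
    """Run the weakly-clamped phase from the free steady state.

    The output units receive an extra force ``beta * A * (a - x_out)``
    pulling them toward the one-hot executed action ``a``, scaled by the
    advantage ``A`` (pass the critic's value V instead of A for the
    value-nudged mode).  Rows whose nudging coefficient ``beta * A`` is
    exactly zero keep the free steady state: the force vanishes, the
    dynamics reduce to the free dynamics, and the steady state is by
    definition unchanged.

    ``action`` may be a single one-hot vector or a (B, n_outputs) one-hot
    matrix; ``advantage`` a scalar or a length-B vector.
    """
    if phase.free is None:
        raise ValueError("clamped phase requires a settled free phase")
    a = np.atleast_2d(np.asarray(action, dtype=float))
    B = phase.free.x_hid.shape[0]
    if a.shape[0] == 1 and B > 1:
        a = np.repeat(a, B, axis=0)
    if a.shape != (B, params.n_outputs):
        raise ValueError(f"action shape {a.shape} does not match batch")
    is_onehot = np.all(np.isin(a, (0.0, 1.0))) and np.all(a.sum(axis=1) == 1.0)
    if not is_onehot:
        raise ValueError("action must be one-hot over the output units")
    adv = np.broadcast_to(np.asarray(advantage, dtype=float), (B,)).copy()
    nudge = cfg.beta * adv
    active = nudge != 0.0
    clamped = phase.free.copy()
    conv = True
    if np.any(active):
        sub = NetworkState(np.ascontiguousarray(clamped.x_hid[active]),
                           np.ascontiguousarray(clamped.x_out[active]),
                           phase.free.t)
        settled, conv = _run_phase(
            params, sub, np.ascontiguousarray(phase.input[active]), cfg,
            np.ascontiguousarray(nudge[active]),
            np.ascontiguousarray(a[active]), cfg.iters_clamped)
        clamped.x_hid[active] = settled.x_hid
        clamped.x_out[active] = settled.x_out
        clamped.t = settled.t
    phase.clamped = clamped
    phase.converged_clamped = conv
    return phase


def settle_clamped_supervised(phase: PhaseResult, params: ActorParams,
                              target: np.ndarray, cfg: EPConfig
                              ) -> PhaseResult:
    """Supervised clamping mode: nudge force ``beta * (T - x_out)``.

    ``T`` is an arbitrary target vector (not necessarily one-hot); used
    for testing the clamped dynamics outside the reinforcement setting.
    """
    if phase.free is None:
        raise ValueError("clamped phase requires a settled free phase")
    T = np.atleast_2d(np.asarray(target, dtype=float))
    B = phase.free.x_hid.shape[0]
    if T.shape[0] == 1 and B > 1:
        T = np.repeat(T, B, axis=0)
    nudge = np.full(B, cfg.beta)
    settled, conv = _run_phase(params, phase.free.copy(), phase.input, cfg,
                               nudge, np.ascontiguousarray(T),
                               cfg.iters_clamped)
    phase.clamped = settled
    phase.converged_clamped = conv
    return phase
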