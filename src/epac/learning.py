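"""Advantage computation and the contrastive weight-update rules.

Two rules are provided.  The classical two-phase rule contrasts full
Hebbian products between the clamped and free fixed points,

    dw_pre,post = (alpha / beta) * (xhat_pre * xhat_post - xcheck_pre * xcheck_post),

while the single-phase rule keeps only the clamped presynaptic activity,

    dw_pre,post = (alpha / beta) * xhat_pre * (xhat_post - xcheck_post),

which is the form a neuron could compute locally in one phase if it
predicted its own free-phase activity; here the exact free-phase
activities stand in for those predictions.  On the input -> hidden block
the two rules coincide because the input is clamped in both phases.
Biases follow the same rule with presynaptic activity fixed at 1.
Minibatch deltas are averaged, so learning rates are batch-size
invariant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .actor import ActorParams, PhaseResult


@dataclass
class AdvantageEstimate:
    """TD-style advantage A = y - V(s) with y = r (terminal) or r + V(s')."""

    A: np.ndarray
    y: np.ndarray
    V_s: np.ndarray
    terminal: np.ndarray


@dataclass
class LearningRates:
    """Per-layer actor learning rates and the rule selector.

    alpha1 scales input -> hidden updates, alpha2 hidden -> output
    updates (and the corresponding biases).  Zero disables learning for
    that layer (useful for no-update control runs).
    """

    alpha1: float
    alpha2: float
    rule: str = "single_phase"

    def __post_init__(self):
        if self.alpha1 < 0 or self.alpha2 < 0:
            raise ValueError("learning rates must be non-negative")
        if self.rule not in ("single_phase", "two_phase"):
            raise ValueError(f"unknown rule {self.rule!r}")


@dataclass
class WeightDelta:
    d_w_in_hid: np.ndarray
    d_w_hid_out: np.ndarray
    d_b_hid: np.ndarray
    d_b_out: np.ndarray


def advantage(r, V_s, V_snext, terminal, discount: float = 1.0
              ) -> AdvantageEstimate:
    """TD target and advantage for one transition or a batch.

    y = r for terminal transitions, r + discount * V(s') otherwise
    (discount defaults to 1: the update rule uses the undiscounted
    one-step target); A = y - V(s).
    """
    r = np.asarray(r, dtype=float)
    V_s = np.asarray(V_s, dtype=float)
    V_snext = np.asarray(V_snext, dtype=float)
    terminal = np.asarray(terminal, dtype=bool)
    for name, v in (("r", r), ("V_s", V_s), ("V_snext", V_snext)):
        if not np.all(np.isfinite(v)):
            raise ValueError(f"non-finite {name} in advantage computation")
    y = np.where(terminal, r, r + discount * V_snext)
    return AdvantageEstimate(A=y - V_s, y=y, V_s=V_s, terminal=terminal)


def _check_phase(phase: PhaseResult):
    if phase.clamped is None:
        raise ValueError("weight update requires a settled clamped phase")


def single_phase_update(phase: PhaseResult, input: np.ndarray,
                        lr: LearningRates, beta: float) -> WeightDelta:
    """Single-phase rule: (alpha/beta) * xhat_pre * (xhat_post - xcheck_post).

    The presynaptic activity of the input -> hidden block is the clamped
    observation itself; bias deltas use presynaptic activity 1.  Deltas
    are averaged over the minibatch.
    """
    _check_phase(phase)
    s = np.atleast_2d(np.asarray(input, dtype=float))
    B = s.shape[0]
    dxh = phase.clamped.x_hid - phase.free.x_hid
    dxo = phase.clamped.x_out - phase.free.x_out
    return WeightDelta(
        d_w_in_hid=(lr.alpha1 / beta) * (s.T @ dxh) / B,
        d_w_hid_out=(lr.alpha2 / beta) * (phase.clamped.x_hid.T @ dxo) / B,
        d_b_hid=(lr.alpha1 / beta) * dxh.mean(axis=0),
        d_b_out=(lr.alpha2 / beta) * dxo.mean(axis=0),
    )


def two_phase_update(phase: PhaseResult, input: np.ndarray,
                     lr: LearningRates, beta: float) -> WeightDelta:
    """Classical contrastive rule: (alpha/beta) * (xhat xhat - xcheck xcheck)."""
    _check_phase(phase)
    s = np.atleast_2d(np.asarray(input, dtype=float))
    B = s.shape[0]
    xh_hat, xo_hat = phase.clamped.x_hid, phase.clamped.x_out
    xh_chk, xo_chk = phase.free.x_hid, phase.free.x_out
    return WeightDelta(
        d_w_in_hid=(lr.alpha1 / beta) * (s.T @ xh_hat - s.T @ xh_chk) / B,
        d_w_hid_out=(lr.alpha2 / beta) * (xh_hat.T @ xo_hat - xh_chk.T @ xo_chk) / B,
        d_b_hid=(lr.alpha1 / beta) * (xh_hat - xh_chk).mean(axis=0),
        d_b_out=(lr.alpha2 / beta) * (xo_hat - xo_chk).mean(axis=0),
    )


def compute_update(phase: PhaseResult, input: np.ndarray, lr: LearningRates,
                   beta: float) -> WeightDelta:
    """Dispatch on ``lr.rule``."""
    if lr.rule == "two_phase":
        return two_phase_update(phase, input, lr, beta)
    return single_phase_update(phase, input, lr, beta)


def apply_update(params: ActorParams, delta: WeightDelta) -> ActorParams:
    """Additive in-place update; re-ties the feedback weights afterwards."""
    if delta.d_w_in_hid.shape != params.w_in_hid.shape or \
            delta.d_w_hid_out.shape != params.w_hid_out.shape or \
            delta.d_b_hid.shape != params.b_hid.shape or \
            delta.d_b_out.shape != params.b_out.shape:
        raise ValueError("delta shapes do not match parameters")
    params.w_in_hid += delta.d_w_in_hid
    params.w_hid_out += delta.d_w_hid_out
    params.b_hid += delta.d_b_hid
    params.b_out += delta.d_b_out
    params.retie()
    return params
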