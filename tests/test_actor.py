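"""Settling dynamics: fixed points, nudging, numerical consistency."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epac import (ActorParams, EPConfig, NetworkState, PhaseResult,
                  SettlingDivergenceError, free_step, hidden_activation,
                  settle_clamped, settle_clamped_supervised, settle_free,
                  softmax)
from epac.actor import initial_state

from conftest import random_actor


@pytest.mark.parametrize("u, variant, expected", [
    (0.0, "hard_sigmoid_A", 0.0),
    (0.0, "hard_sigmoid_B", 0.5),
    (2.3, "hard_sigmoid_A", 1.0),
    (2.3, "hard_sigmoid_B", 1.0),
    (-1.5, "hard_sigmoid_A", 0.0),
    (-1.5, "hard_sigmoid_B", 0.0),
    (0.4, "hard_sigmoid_A", 0.4),
    (0.4, "hard_sigmoid_B", 0.7),
])
def test_hidden_activation_values(u, variant, expected):
    assert hidden_activation(u, variant) == pytest.approx(expected)


@given(st.floats(-1e6, 1e6))
@settings(derandomize=True)
def test_hidden_activation_bounded(u):
    for variant in ("hard_sigmoid_A", "hard_sigmoid_B"):
        assert 0.0 <= hidden_activation(u, variant) <= 1.0


def test_free_step_hand_arithmetic_hidden():
    # one hidden unit, all weights/biases zero, no feedback: the leaky
    # update pulls x_j = 0.5 halfway toward p(0) = 0 with h = 0.5
    p = ActorParams(np.zeros((1, 1)), np.zeros((1, 2)), np.zeros((2, 1)),
                    np.zeros(1), np.zeros(2))
    cfg = EPConfig(h=0.5, gamma_fb=0.0, iters_free=1)
    state = NetworkState(np.array([[0.5]]), np.full((1, 2), 0.5))
    out = free_step(state, p, np.array([0.0]), cfg)
    assert out.x_hid[0, 0] == pytest.approx(0.25)


def test_free_step_softmax_symmetric_fixed_point(cfg):
    # zero hidden->output weights: softmax(0, 0) = (.5, .5) is fixed
    p = ActorParams(np.zeros((3, 4)), np.zeros((4, 2)), np.zeros((2, 4)),
                    np.zeros(4), np.zeros(2))
    state = NetworkState(np.zeros((1, 4)), np.full((1, 2), 0.5))
    out = free_step(state, p, np.zeros(3), cfg)
    np.testing.assert_array_equal(out.x_out, [[0.5, 0.5]])


def test_free_step_matches_scalar_loop_oracle():
    """One Euler step on a random 3-4-2 net vs an index-by-index
    evaluation of the layer equations with python loops."""
    actor = random_actor(3, 4, 2, seed=7)
    cfg = EPConfig(h=0.3, gamma_fb=0.7)
    rng = np.random.default_rng(8)
    s = rng.normal(size=3)
    xh = rng.uniform(size=4)
    xo = np.array([0.3, 0.7])
    state = NetworkState(xh[None, :].copy(), xo[None, :].copy())
    out = free_step(state, actor, s, cfg)

    exp_h = np.empty(4)
    for j in range(4):
        u = sum(actor.w_in_hid[i, j] * s[i] for i in range(3))
        u += cfg.gamma_fb * sum(actor.w_out_hid[o, j] * xo[o] for o in range(2))
        u += actor.b_hid[j]
        exp_h[j] = xh[j] + cfg.h * (-xh[j] + min(max(u, 0.0), 1.0))
    logits = [sum(actor.w_hid_out[j, o] * xh[j] for j in range(4))
              + actor.b_out[o] for o in range(2)]
    z = [np.exp(l - max(logits)) for l in logits]
    sm = [v / sum(z) for v in z]
    exp_o = [xo[o] + cfg.h * (-xo[o] + sm[o]) for o in range(2)]
    np.testing.assert_allclose(out.x_hid[0], exp_h, atol=1e-12)
    np.testing.assert_allclose(out.x_out[0], exp_o, atol=1e-12)


def test_free_step_raises_on_nonfinite_state(cfg, small_actor):
    state = NetworkState(np.full((1, 8), np.inf), np.full((1, 2), 0.5))
    with pytest.raises(SettlingDivergenceError) as exc:
        free_step(state, small_actor, np.zeros(4), cfg)
    assert exc.value.layer == "hidden"


def test_settle_free_zero_net_fixed_point(cfg):
    p = ActorParams(np.zeros((3, 5)), np.zeros((5, 2)), np.zeros((2, 5)),
                    np.zeros(5), np.zeros(2))
    res = settle_free(p, np.zeros(3), cfg)
    np.testing.assert_array_equal(res.free.x_hid, np.zeros((1, 5)))
    np.testing.assert_array_equal(res.free.x_out, [[0.5, 0.5]])
    assert res.converged_free


def test_settle_free_matches_fine_step_long_run():
    """Coarse settling (h=0.5, 150 iters) lands on the same fixed point
    as a fine-step long run (h=0.05, 10000 iters)."""
    actor = random_actor(4, 8, 2, seed=42)
    s = np.random.default_rng(43).normal(size=4)
    coarse = settle_free(actor, s, EPConfig(h=0.5, iters_free=150))
    fine = settle_free(actor, s, EPConfig(h=0.05, iters_free=10000))
    np.testing.assert_allclose(coarse.free.x_hid, fine.free.x_hid, atol=1e-6)
    np.testing.assert_allclose(coarse.free.x_out, fine.free.x_out, atol=1e-6)


def test_settle_free_deterministic(cfg, small_actor):
    s = np.random.default_rng(1).normal(size=4)
    a = settle_free(small_actor, s, cfg)
    b = settle_free(small_actor, s, cfg)
    np.testing.assert_array_equal(a.free.x_hid, b.free.x_hid)
    np.testing.assert_array_equal(a.free.x_out, b.free.x_out)


def test_settle_free_matches_numpy_reference(cfg, small_actor):
    """The compiled settling kernel reproduces iterated numpy steps."""
    s = np.random.default_rng(5).normal(size=(3, 4))
    res = settle_free(small_actor, s, cfg)
    state = initial_state(small_actor, 3)
    for _ in range(cfg.iters_free):
        state = free_step(state, small_actor, s, cfg)
    np.testing.assert_allclose(res.free.x_hid, state.x_hid, atol=1e-12)
    np.testing.assert_allclose(res.free.x_out, state.x_out, atol=1e-12)


def test_fixed_point_residual(cfg, small_actor):
    """At the settled state, x_hid = p(pre) and x_out = softmax(pre)."""
    s = np.random.default_rng(2).normal(size=4)
    res = settle_free(small_actor, s, cfg)
    nxt = free_step(res.free, small_actor, s, cfg)
    assert np.max(np.abs(nxt.x_hid - res.free.x_hid)) < 1e-9
    assert np.max(np.abs(nxt.x_out - res.free.x_out)) < 1e-9


def test_early_stopping_tolerance(small_actor):
    cfg = EPConfig(h=0.5, iters_free=10_000, convergence_tol=1e-10)
    s = np.random.default_rng(3).normal(size=4)
    res = settle_free(small_actor, s, cfg)
    assert res.converged_free
    assert res.free.t < 10_000  # stopped well before the cap


def test_output_stays_probability_vector(cfg, small_actor):
    s = np.random.default_rng(4).normal(size=4)
    state = initial_state(small_actor, 1)
    for _ in range(60):
        state = free_step(state, small_actor, s, cfg)
        assert np.all(state.x_out >= 0)
        assert state.x_out.sum() == pytest.approx(1.0, abs=1e-12)


def test_zero_nudge_reproduces_free_phase_bitwise(cfg, small_actor):
    s = np.random.default_rng(6).normal(size=4)
    res = settle_free(small_actor, s, cfg)
    settle_clamped(res, small_actor, np.array([1.0, 0.0]), 0.0, cfg)
    np.testing.assert_array_equal(res.clamped.x_hid, res.free.x_hid)
    np.testing.assert_array_equal(res.clamped.x_out, res.free.x_out)


def test_clamped_step_hand_arithmetic():
    """Single output unit (softmax drive is identically 1): one nudged
    Euler step from x_o = 0.6 with a = 1, beta = 0.02, A = 1.3, h = 0.5
    gives 0.6 + 0.5*(-0.6 + 1.0 + 0.026*0.4) = 0.8052."""
    p = ActorParams(np.zeros((1, 1)), np.zeros((1, 1)), np.zeros((1, 1)),
                    np.zeros(1), np.zeros(1))
    cfg = EPConfig(h=0.5, beta=0.02, iters_free=1, iters_clamped=1)
    phase = PhaseResult(
        free=NetworkState(np.zeros((1, 1)), np.array([[0.6]])),
        input=np.zeros((1, 1)))
    settle_clamped(phase, p, np.array([1.0]), 1.3, cfg)
    assert phase.clamped.x_out[0, 0] == pytest.approx(0.8052)


def test_clamped_requires_one_hot_action(cfg, small_actor):
    s = np.zeros(4)
    res = settle_free(small_actor, s, cfg)
    with pytest.raises(ValueError, match="one-hot"):
        settle_clamped(res, small_actor, np.array([0.5, 0.5]), 1.0, cfg)


def test_nudge_response_linear_in_beta(small_actor):
    """The displacement of the clamped fixed point scales linearly with
    beta * A in the weak-nudging regime."""
    s = np.random.default_rng(9).normal(size=4)
    a = np.array([1.0, 0.0])
    disp = {}
    for beta in (0.04, 0.02, 0.01):
        cfg = EPConfig(h=0.5, beta=beta, iters_free=300, iters_clamped=300)
        res = settle_free(small_actor, s, cfg)
        settle_clamped(res, small_actor, a, 1.0, cfg)
        disp[beta] = np.linalg.norm(res.clamped.x_out - res.free.x_out)
    assert disp[0.04] / disp[0.02] == pytest.approx(2.0, rel=0.05)
    assert disp[0.02] / disp[0.01] == pytest.approx(2.0, rel=0.03)
    # and against the finite-difference slope at beta -> 0
    slope = disp[0.01] / 0.01
    assert disp[0.02] / 0.02 == pytest.approx(slope, rel=0.03)


def test_h_consistency(cfg):
    """Steady states computed with h and h/10 agree (same dynamics,
    different integrator resolution)."""
    for seed in range(5):
        actor = random_actor(4, 8, 2, seed=seed)
        s = np.random.default_rng(100 + seed).normal(size=4)
        a = settle_free(actor, s, EPConfig(h=0.5, iters_free=200))
        b = settle_free(actor, s, EPConfig(h=0.05, iters_free=2000))
        assert np.max(np.abs(a.free.x_hid - b.free.x_hid)) < 1e-4
        assert np.max(np.abs(a.free.x_out - b.free.x_out)) < 1e-4


def test_supervised_clamping_pulls_toward_target(cfg, small_actor):
    s = np.random.default_rng(11).normal(size=4)
    res = settle_free(small_actor, s, cfg)
    target = np.array([1.0, 0.0])
    settle_clamped_supervised(res, small_actor, target, cfg)
    moved = res.clamped.x_out[0] - res.free.x_out[0]
    assert moved[0] > 0 and moved[1] < 0  # toward T on both components


@pytest.mark.parametrize("kwargs", [
    dict(h=0.0), dict(h=1.5), dict(beta=0.0), dict(beta=-1.0),
    dict(iters_free=0), dict(iters_clamped=0), dict(gamma_fb=-0.1),
    dict(hidden_activation="relu"),
])
def test_epconfig_validation(kwargs):
    with pytest.raises(ValueError):
        EPConfig(**kwargs)


def test_softmax_rows_normalized():
    x = np.random.default_rng(12).normal(size=(5, 3)) * 10
    sm = softmax(x)
    np.testing.assert_allclose(sm.sum(axis=1), 1.0, atol=1e-12)
    assert np.all(sm > 0)
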