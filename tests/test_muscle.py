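"""Hill-model curves, activation dynamics and muscle-tendon equilibrium."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

from exogait.muscle import (MuscleModelError, MuscleParams, MuscleState,
                            activation_rate, active_force_length,
                            characteristic_curves, default_muscle_set,
                            equilibrium_residual, force_velocity,
                            joint_moments_from_muscles, passive_force_length,
                            tendon_force_length, FIBER_DAMPING)


@pytest.fixture(scope="module")
def soleus():
    return default_muscle_set()["soleus"]


def test_default_roster_and_spans():
    ms = default_muscle_set()
    assert len(ms.muscles) == 9
    span = ms.span_matrix()
    # anatomy: gastrocnemius spans knee and ankle; soleus only the ankle
    gi, si = ms.names.index("gastroc"), ms.names.index("soleus")
    assert span[gi, 1] and span[gi, 2] and not span[gi, 0]
    assert span[si, 2] and span[si, :2].sum() == 0
    for m in ms.muscles:
        assert m.mass > 0


def test_param_invariants_enforced():
    with pytest.raises(MuscleModelError):
        MuscleParams(name="bad", f_max=-1.0, l_m_opt=0.1, l_t_slack=0.2)
    with pytest.raises(MuscleModelError):
        MuscleParams(name="bad", f_max=100.0, l_m_opt=0.1, l_t_slack=0.2,
                     tau_act=0.1, tau_deact=0.05)


def test_curve_normalization_anchors(soleus):
    c = characteristic_curves(1.0, 0.0, 1.0, soleus)
    assert c["active_fl"] == pytest.approx(1.0)
    assert c["fv"] == pytest.approx(1.0)
    assert c["tendon_fl"] == pytest.approx(0.0, abs=1e-12)
    # maximal shortening extinguishes force
    assert force_velocity(-1.0) == pytest.approx(0.0, abs=1e-12)
    # passive curve reaches 1 at optimal length + passive strain
    l_at = 1.0 + soleus.passive_strain_at_fmax
    assert passive_force_length(l_at, soleus.passive_strain_at_fmax) == \
        pytest.approx(1.0, abs=1e-6)
    # tendon curve reaches 1 at slack + tendon strain
    assert tendon_force_length(1.0 + soleus.tendon_strain_at_fmax,
                               soleus.tendon_strain_at_fmax) == pytest.approx(1.0)


def test_force_velocity_monotone():
    v = np.linspace(-1.5, 1.5, 301)
    assert np.all(np.diff(force_velocity(v)) > 0)


def test_curves_reject_nonpositive_length(soleus):
    with pytest.raises(MuscleModelError):
        characteristic_curves(-0.1, 0.0, 1.0, soleus)


def test_activation_rate_contracts(soleus):
    assert activation_rate(0.5, 0.5, soleus.tau_act, soleus.tau_deact) == \
        pytest.approx(0.0)
    r = activation_rate(1.0, 0.0, soleus.tau_act, soleus.tau_deact)
    # fastest activation: roughly (e - a) / (tau_act * scale) with scale 0.5
    assert r == pytest.approx(1.0 / (soleus.tau_act * 0.5), rel=0.01)
    assert activation_rate(0.0, 1.0, soleus.tau_act, soleus.tau_deact) < 0
    with pytest.raises(MuscleModelError):
        activation_rate(1.4, 0.5, soleus.tau_act, soleus.tau_deact)


def test_activation_step_response_matches_ode_oracle(soleus):
    """Step e: 0 -> 1 at t=0; value at t = tau_act vs high-accuracy ODE."""
    f = lambda t, a: activation_rate(1.0, np.clip(a, 0, 1),
                                     soleus.tau_act, soleus.tau_deact)
    ref = solve_ivp(f, (0.0, soleus.tau_act), [0.0], rtol=1e-11, atol=1e-12)
    a_end = ref.y[0, -1]
    # crude fixed-step RK4 with the package's own rate reproduces the oracle
    n, h = 2000, soleus.tau_act / 2000
    a = 0.0
    for _ in range(n):
        k1 = f(0, a); k2 = f(0, a + h / 2 * k1)
        k3 = f(0, a + h / 2 * k2); k4 = f(0, a + h * k3)
        a += h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
    assert a == pytest.approx(a_end, abs=1e-6)
    assert 0.4 < a_end < 1.0  # a first-order-lag-like rise within one tau


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(0, 2 ** 31 - 1))
def test_activation_stays_in_bounds_under_any_excitation(seed):
    """Integrating the activation ODE under bounded excitation keeps a in [0,1]."""
    rng = np.random.default_rng(seed)
    e_knots = rng.uniform(0, 1, 8)
    tau_a, tau_d = 0.015, 0.060
    t_grid = np.linspace(0, 0.5, 2001)
    e = np.interp(t_grid, np.linspace(0, 0.5, 8), e_knots)
    a = rng.uniform(0, 1)
    h = t_grid[1] - t_grid[0]
    for i in range(len(t_grid) - 1):
        a = a + h * activation_rate(e[i], np.clip(a, 0, 1), tau_a, tau_d)
        assert -1e-6 <= a <= 1 + 1e-6


def test_equilibrium_isometric_identity():
    """Near-rigid tendon, optimal fiber, v = 0: f_t equals active + passive."""
    p = MuscleParams(name="toy", f_max=1000.0, l_m_opt=0.1, l_t_slack=0.2,
                     pennation_opt=0.0, tendon_strain_at_fmax=1e-6)
    a = 1.0
    f_expected = a * 1.0 + passive_force_length(1.0, p.passive_strain_at_fmax)
    state = MuscleState(activation=a, tendon_force_norm=f_expected)
    res, info = equilibrium_residual(state, l_mt=0.3, v_mt=0.0, params=p)
    assert abs(res) < 1e-3
    assert info["l_m_norm"] == pytest.approx(1.0, abs=1e-3)


def test_equilibrium_slack_case():
    """Inactive short fiber with slack tendon is (near) equilibrated at f=0."""
    p = MuscleParams(name="toy", f_max=1000.0, l_m_opt=0.1, l_t_slack=0.2,
                     pennation_opt=0.0)
    state = MuscleState(activation=0.0, tendon_force_norm=0.0)
    res, info = equilibrium_residual(state, l_mt=0.29, v_mt=0.0, params=p)
    assert info["l_m_norm"] < 1.0
    assert abs(res) < 0.02  # only the small residual passive term remains


def test_equilibrium_matches_independent_algebra():
    """Residual equals a from-scratch evaluation of the same algebra."""
    p = MuscleParams(name="toy", f_max=2000.0, l_m_opt=0.08, l_t_slack=0.25,
                     pennation_opt=0.2)
    rng = np.random.default_rng(5)
    for _ in range(20):
        a = rng.uniform(0, 1)
        f_t = rng.uniform(0.01, 1.2)
        d_f_t = rng.uniform(-20, 20)
        l_mt = rng.uniform(0.31, 0.36)
        v_mt = rng.uniform(-0.3, 0.3)
        res, _ = equilibrium_residual(
            MuscleState(activation=a, tendon_force_norm=f_t,
                        d_tendon_force_norm=d_f_t), l_mt, v_mt, p)
        # independent re-derivation with plain scalar math
        kt, e0t = 35.0, p.tendon_strain_at_fmax
        c1 = 1.0 / (np.exp(kt * e0t) - 1.0)
        l_t = p.l_t_slack * (1.0 + np.log(f_t / c1 + 1.0) / kt)
        v_t = p.l_t_slack * d_f_t / (kt * (f_t + c1))
        h = p.l_m_opt * np.sin(p.pennation_opt)
        proj = l_mt - l_t
        l_m = np.hypot(proj, h)
        cos_a = proj / l_m
        v_m = (v_mt - v_t) * cos_a
        ln = l_m / p.l_m_opt
        vn = v_m / (p.v_max * p.l_m_opt)
        expect = (a * active_force_length(ln) * force_velocity(vn)
                  + passive_force_length(ln, p.passive_strain_at_fmax)
                  + FIBER_DAMPING * vn) * cos_a - f_t
        # the implementation smoothly guards the along-tendon projection,
        # which offsets the exact algebra by O(guard_width^2 / proj)
        assert res == pytest.approx(expect, abs=5e-8)


def test_rigid_tendon_limit_of_fiber_length():
    """As tendon stiffness grows, fiber length -> l_mt - l_t_slack."""
    prev_gap = None
    for e0t in (0.05, 0.01, 0.002, 0.0005):
        p = MuscleParams(name="toy", f_max=1000.0, l_m_opt=0.1, l_t_slack=0.2,
                         pennation_opt=0.0, tendon_strain_at_fmax=e0t)
        state = MuscleState(activation=0.5, tendon_force_norm=0.5)
        _, info = equilibrium_residual(state, l_mt=0.305, v_mt=0.0, params=p)
        gap = abs(info["l_m_norm"] * p.l_m_opt - (0.305 - p.l_t_slack))
        if prev_gap is not None:
            assert gap < prev_gap
        prev_gap = gap
    assert prev_gap < 1e-4


def test_equilibrium_residual_is_smooth():
    """C1: finite-difference derivative is continuous across v = 0 and l = l_opt."""
    p = MuscleParams(name="toy", f_max=1000.0, l_m_opt=0.1, l_t_slack=0.2)

    def res_of(f_t):
        r, _ = equilibrium_residual(
            None, 0.302, 0.0, p, arrays=(0.5, f_t, 0.0))
        return r

    h = 1e-6
    f_grid = np.linspace(0.05, 1.0, 40)
    d = [(res_of(f + h) - res_of(f - h)) / (2 * h) for f in f_grid]
    assert np.max(np.abs(np.diff(d))) < 1.0  # no derivative jumps


def test_joint_moments_match_bruteforce_oracle():
    rng = np.random.default_rng(7)
    forces = rng.uniform(0, 2000, (15, 9))
    arms = rng.uniform(-0.06, 0.06, (15, 9, 3))
    got = joint_moments_from_muscles(forces, arms)
    expect = np.zeros((15, 3))
    for t in range(15):
        for d in range(3):
            for m in range(9):
                expect[t, d] += arms[t, m, d] * forces[t, m]
    np.testing.assert_allclose(got, expect, rtol=1e-12)
    # trivial anchors
    assert np.allclose(joint_moments_from_muscles(np.zeros((4, 9)),
                                                  arms[:4]), 0.0)
    one = joint_moments_from_muscles(np.array([[100.0]]),
                                     np.array([[[0.05, 0.0, 0.0]]]))
    assert one[0, 0] == pytest.approx(5.0)


def test_joint_moments_shape_mismatch():
    with pytest.raises(MuscleModelError):
        joint_moments_from_muscles(np.zeros((5, 9)), np.zeros((5, 8, 3)))
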