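"""Post-processing metrics: timing errors, powers, reserves, statistics."""

import numpy as np
import pandas as pd
import pytest

from exogait.reporting import (compare_devices, timing_error)


# ---------------------------------------------------------------------------
# EMG onset/offset timing error
# ---------------------------------------------------------------------------

@pytest.fixture()
def time_grid():
    return np.linspace(0.0, 1.1, 221)


def test_timing_error_identical_signals_zero(time_grid):
    sig = 0.5 + 0.4 * np.sin(2 * np.pi * time_grid / 1.1)
    assert timing_error(sig, sig, time_grid, shift=0.0) == pytest.approx(0.0)


def test_timing_error_complementary_binary_signals(time_grid):
    on_first = (time_grid < 0.55).astype(float)
    assert timing_error(on_first, 1.0 - on_first, time_grid, shift=0.0) == \
        pytest.approx(100.0, abs=1.0)


def test_timing_error_shift_moves_activation_later(time_grid):
    """An activation leading the EMG by the electromechanical delay scores ~0."""
    duration = time_grid[-1]
    phi = time_grid / duration
    emg = np.exp(np.cos(2 * np.pi * (phi - 0.4)) * 8 - 8)
    # activation that *leads* EMG by 75 ms: timing_error shifts it back
    lead = 0.075 / duration
    act = np.exp(np.cos(2 * np.pi * (phi - 0.4 + lead)) * 8 - 8)
    err_shifted = timing_error(act, emg, time_grid, shift=0.075)
    err_raw = timing_error(act, emg, time_grid, shift=0.0)
    assert err_shifted < err_raw
    assert err_shifted < 2.0


def test_timing_error_symmetric_and_scale_invariant(time_grid):
    rng = np.random.default_rng(8)
    a = np.abs(rng.standard_normal(time_grid.size))
    b = np.abs(rng.standard_normal(time_grid.size))
    e1 = timing_error(a, b, time_grid, shift=0.0)
    e2 = timing_error(b, a, time_grid, shift=0.0)
    assert e1 == pytest.approx(e2, abs=1e-9)
    # invariant to common rescaling of either series
    assert timing_error(3.7 * a, b, time_grid, shift=0.0) == pytest.approx(e1)
    assert timing_error(a, 0.2 * b, time_grid, shift=0.0) == pytest.approx(e1)


def test_timing_error_all_zero_conventions(time_grid):
    zero = np.zeros_like(time_grid)
    assert timing_error(zero, zero, time_grid) == pytest.approx(0.0)
    assert timing_error(zero, np.ones_like(zero), time_grid) == pytest.approx(100.0)


# ---------------------------------------------------------------------------
# device power and reserve metrics (on constructed solutions)
# ---------------------------------------------------------------------------

def _toy_solution(time, reserves=None, device_controls=None, gains=None,
                  mode="none", directions=None):
    from exogait.collocation import OCPSolution

    n = len(time)
    z = np.zeros((n, 9))
    return OCPSolution(
        time=time, activations=z, tendon_forces=z, excitations=z,
        d_tendon_forces=z,
        reserves=np.zeros((n, 3)) if reserves is None else reserves,
        device_controls=device_controls, gains=gains, param_scales=None,
        objective=0.0, objective_terms={}, max_defect=0.0,
        max_moment_residual=0.0, status="", success=True, n_iter=0,
        solve_time=0.0, device_directions=directions, device_mode=mode)


@pytest.fixture(scope="module")
def flat_cycle():
    """Constant-posture cycle with unit hip angular velocity."""
    from exogait.synthetic import SyntheticConfig, generate_gait_cycle

    cyc = generate_gait_cycle(SyntheticConfig(seed=0, n_samples=101, duration=1.0))
    cyc.joint_velocities = np.zeros_like(cyc.joint_velocities)
    cyc.joint_velocities[:, 0] = 1.0  # rad/s about the hip
    return cyc


def test_device_power_closed_form(flat_cycle):
    """tau = sin_+(2 pi t), omega = 1: averages match analytic integrals."""
    from exogait.devices import make_device
    from exogait.reporting import device_power_metrics

    t = flat_cycle.time
    spec = make_device("hf")
    mass = flat_cycle.body_mass
    u = np.clip(np.sin(2 * np.pi * t), 0.0, 1.0)[:, None]  # limit 1 N.m/kg
    sol = _toy_solution(t, device_controls=u, mode="single",
                        directions=("hip_flexion",))
    m = device_power_metrics(sol, flat_cycle, spec)
    # peak torque: 1.0 N.m/kg; positive power average of sin_+ = 1/pi
    assert m.peak_torque[0] == pytest.approx(1.0, rel=1e-3)
    assert m.average_positive_power[0] == pytest.approx(1.0 / np.pi, rel=1e-3)
    assert m.average_negative_power[0] == pytest.approx(0.0, abs=1e-9)
    assert m.peak_positive_power[0] == pytest.approx(1.0, rel=1e-3)


def test_device_power_matches_sample_loop_oracle(flat_cycle):
    from exogait.devices import DIRECTIONS, make_device
    from exogait.reporting import device_power_metrics

    rng = np.random.default_rng(3)
    spec = make_device("hf+ap/independent")
    t = flat_cycle.time
    u = rng.uniform(0, 1, (len(t), 2))
    sol = _toy_solution(t, device_controls=u, mode="independent",
                        directions=spec.directions)
    m = device_power_metrics(sol, flat_cycle, spec)
    mass = flat_cycle.body_mass
    for j, d in enumerate(spec.directions):
        dof, sign = DIRECTIONS[d]
        tau = sign * u[:, j] * spec.torque_limits[d] * mass
        power = tau * flat_cycle.joint_velocities[:, dof]
        assert m.peak_torque[j] == pytest.approx(np.abs(tau).max() / mass)
        pos = np.trapezoid(np.maximum(power, 0), t) / (t[-1] - t[0]) / mass
        neg = np.trapezoid(np.minimum(power, 0), t) / (t[-1] - t[0]) / mass
        assert m.average_positive_power[j] == pytest.approx(pos, rel=1e-9)
        assert m.average_negative_power[j] == pytest.approx(neg, rel=1e-9)
        assert m.average_positive_power[j] >= 0 >= m.average_negative_power[j]
        assert m.peak_positive_power[j] >= m.average_positive_power[j]


def test_unassisted_solution_gives_empty_device_metrics(flat_cycle):
    from exogait.devices import DeviceSpec
    from exogait.reporting import device_power_metrics

    sol = _toy_solution(flat_cycle.time)
    m = device_power_metrics(sol, flat_cycle, DeviceSpec())
    assert m.directions == ()
    assert m.peak_torque.size == 0


def test_reserve_metrics_arithmetic_and_oracle(flat_cycle):
    from exogait.reporting import reserve_metrics

    t = flat_cycle.time
    sol = _toy_solution(t)
    m = reserve_metrics(sol, flat_cycle)
    assert np.all(m.rms == 0.0) and m.max_ratio == 0.0

    # constant 1 N.m reserve against a known peak moment
    res = np.zeros((len(t), 3))
    res[:, 0] = 1.0
    sol = _toy_solution(t, reserves=res)
    m = reserve_metrics(sol, flat_cycle)
    peak_hip = np.max(np.abs(flat_cycle.net_moments[:, 0]))
    assert m.rms[0] == pytest.approx(1.0)
    assert m.rms_to_peak_ratio[0] == pytest.approx(100.0 / peak_hip, rel=1e-6)

    rng = np.random.default_rng(1)
    res = rng.standard_normal((len(t), 3))
    sol = _toy_solution(t, reserves=res)
    m = reserve_metrics(sol, flat_cycle)
    for d in range(3):
        expect = np.sqrt(sum(r * r for r in res[:, d]) / len(t))
        assert m.rms[d] == pytest.approx(expect, rel=1e-12)


# ---------------------------------------------------------------------------
# convergence-tolerance sensitivity
# ---------------------------------------------------------------------------

def test_tolerance_sensitivity_normalization(ground_truth):
    """Objectives are normalized by the tightest tolerance (exactly 1 there)
    and do not degrade when the tolerance tightens."""
    from exogait.collocation import OCPConfig
    from exogait.reporting import tolerance_sensitivity

    df = tolerance_sensitivity(ground_truth["cycle"],
                               ground_truth["muscle_set"],
                               tolerances=(1e-2, 1e-3, 1e-4),
                               config=OCPConfig(mesh_per_s=20.0))
    ref_row = df.loc[df["tolerance"].idxmin()]
    assert ref_row["normalized_objective"] == 1.0
    assert df["converged"].all()
    # tightening from 1e-3 to 1e-4 changes the objective by < 1%
    row = df.loc[np.isclose(df["tolerance"], 1e-3)].iloc[0]
    assert abs(row["normalized_objective"] - 1.0) < 0.01
    # non-increasing within solver noise
    ordered = df.sort_values("tolerance", ascending=False)
    assert np.all(np.diff(ordered["normalized_objective"]) < 0.01)


# ---------------------------------------------------------------------------
# device-comparison statistics
# ---------------------------------------------------------------------------

def _study_table(rng, n_subjects=5, n_devices=15, device_effects=None,
                 subject_sd=1.0, noise_sd=0.3):
    devices = [f"dev{i:02d}" for i in range(n_devices)]
    effects = device_effects if device_effects is not None \
        else np.zeros(n_devices)
    rows = []
    for s in range(n_subjects):
        bias = rng.normal(0, subject_sd)
        for j, dev in enumerate(devices):
            rows.append({"subject": f"S{s}", "device": dev,
                         "percent_change": -20 + effects[j] + bias
                         + rng.normal(0, noise_sd)})
    return pd.DataFrame(rows)


def test_compare_devices_consumes_75_observations():
    rng = np.random.default_rng(0)
    table = _study_table(rng)
    report = compare_devices(table)
    assert report.n_observations == 75
    assert len(report.pairwise) == 15 * 14 // 2


def test_no_differences_when_devices_identical():
    """Values identical across devices (subject-only variation): all null."""
    rng = np.random.default_rng(1)
    rows = []
    for s in range(5):
        bias = rng.normal(0, 1.0)
        for j in range(6):
            rows.append({"subject": f"S{s}", "device": f"dev{j:02d}",
                         "percent_change": -20 + bias})
    report = compare_devices(pd.DataFrame(rows))
    assert report.anova_p == pytest.approx(1.0)
    assert not any(p.significant for p in report.pairwise)
    assert all(p.estimate == pytest.approx(0.0, abs=1e-8)
               for p in report.pairwise)


def test_tukey_familywise_error_controlled_under_null():
    """Null simulations: the Tukey adjustment keeps familywise errors rare."""
    n_flagged = 0
    for seed in range(25):
        rng = np.random.default_rng(seed)
        table = _study_table(rng, n_devices=6, noise_sd=0.5)
        report = compare_devices(table)
        n_flagged += any(p.significant for p in report.pairwise)
    assert n_flagged <= 3  # nominal rate 5%, generous margin for 25 draws


def test_large_injected_effect_flagged_significant():
    rng = np.random.default_rng(2)
    effects = np.zeros(6)
    effects[0] = -12.0  # one device saves far more
    table = _study_table(rng, n_devices=6, device_effects=effects,
                         subject_sd=2.0, noise_sd=0.3)
    report = compare_devices(table)
    assert report.anova_p < 0.05
    flagged = {(p.device_a, p.device_b) for p in report.pairwise if p.significant}
    assert all(("dev00" in pair) for pair in flagged)
    assert len(flagged) == 5  # dev00 differs from every other device


def test_unbalanced_table_rejected():
    rng = np.random.default_rng(3)
    table = _study_table(rng, n_devices=4).iloc[:-1]
    with pytest.raises(ValueError):
        compare_devices(table)
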