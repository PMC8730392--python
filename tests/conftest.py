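"""Shared fixtures: synthetic datasets and cached optimal-control solutions.

The expensive objects (ground-truth dataset, collocation solutions) are
session-scoped so the whole suite pays for each solve once.
"""

from __future__ import annotations

import pytest

from exogait.collocation import OCPConfig, build_problem, solve
from exogait.synthetic import SyntheticConfig, generate_ground_truth_dataset

ACCEPTANCE_MESH = 50.0   # mesh intervals per second for production solves
COARSE_MESH = 20.0       # presolve mesh for the warm-start cascade


@pytest.fixture(scope="session")
def ground_truth():
    return generate_ground_truth_dataset(SyntheticConfig(seed=0))


@pytest.fixture(scope="session")
def gt_cycle(ground_truth):
    return ground_truth["cycle"]


@pytest.fixture(scope="session")
def muscle_set(ground_truth):
    return ground_truth["muscle_set"]


@pytest.fixture(scope="session")
def coarse_unassisted(gt_cycle, muscle_set):
    ocp = build_problem(gt_cycle, muscle_set, config=OCPConfig(mesh_per_s=COARSE_MESH))
    return solve(ocp)


@pytest.fixture(scope="session")
def unassisted_solution(gt_cycle, muscle_set, coarse_unassisted):
    ocp = build_problem(gt_cycle, muscle_set,
                        config=OCPConfig(mesh_per_s=ACCEPTANCE_MESH))
    return solve(ocp, warm_start=coarse_unassisted)


@pytest.fixture(scope="session")
def condition_suite(gt_cycle, muscle_set, unassisted_solution):
    from exogait.study import run_condition_suite

    return run_condition_suite(gt_cycle, muscle_set,
                               OCPConfig(mesh_per_s=ACCEPTANCE_MESH),
                               unassisted=unassisted_solution)


@pytest.fixture(scope="session")
def unassisted_tight(gt_cycle, muscle_set, unassisted_solution):
    """Unassisted solve at the tightened 1e-4 tolerance (shared reference)."""
    ocp = build_problem(gt_cycle, muscle_set,
                        config=OCPConfig(mesh_per_s=ACCEPTANCE_MESH,
                                         nlp_tol=1e-4))
    return solve(ocp, warm_start=unassisted_solution)


@pytest.fixture(scope="session")
def emg_ground_truth():
    # grid chosen so the tracking mesh coincides with the sampled data
    return generate_ground_truth_dataset(SyntheticConfig(seed=0, n_samples=56))


@pytest.fixture(scope="session")
def emg_calibration_result(emg_ground_truth):
    from exogait.calibration import calibrate_to_emg

    gt = emg_ground_truth
    return calibrate_to_emg(gt["muscle_set"], gt["cycle"],
                            config=OCPConfig(mesh_per_s=ACCEPTANCE_MESH))
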