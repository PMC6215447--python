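"""Shared fixtures.

Expensive pipeline artefacts (the synthetic limb, the repaired start
posture, its statics solution and forward-generated fabric) are built
once per session; tests treat them as read-only.
"""

import numpy as np
import pytest

from osteotraj import anatomy, kinematics, search, statics, synthfab


@pytest.fixture(scope="session")
def model():
    return anatomy.generate_synthetic_limb()


@pytest.fixture(scope="session")
def start_posture(model):
    return search.repair_posture(model, kinematics.START_POSTURE)


@pytest.fixture(scope="session")
def posed_start(model, start_posture):
    return kinematics.pose_limb(model, start_posture)


@pytest.fixture(scope="session")
def external_loads(model, posed_start):
    return statics.build_external_loads(posed_start, model)


@pytest.fixture(scope="session")
def activation_solution(model, posed_start, external_loads):
    return statics.solve_static_optimization(model, posed_start, external_loads)


@pytest.fixture(scope="session")
def joint_loads(model, posed_start, activation_solution, external_loads):
    return statics.joint_reactions(model, posed_start, activation_solution, external_loads)


@pytest.fixture(scope="session")
def principal_fields(model, start_posture):
    return search.compute_principal_fields(model, start_posture)


@pytest.fixture(scope="session")
def noiseless_fabric(model, start_posture):
    return synthfab.fabric_suite_from_posture(
        model, start_posture, synthfab.FabricGenSpec(noise_sd_deg=0.0, seed=0)
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260921)
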