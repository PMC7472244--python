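"""Shared fixtures: study-condition configurations and cached simulations.

Heavy simulations are session-scoped so the fusion filter runs once per
scenario and every test that needs the result reuses it.
"""

import numpy as np
import pytest

from margkin import align, fusion, preprocess, simdata


@pytest.fixture(scope="session")
def taf():
    return preprocess.get_config("TAF")


@pytest.fixture(scope="session")
def def_cfg():
    return preprocess.get_config("DEF")


@pytest.fixture(scope="session")
def squat_truth():
    return simdata.generate_ground_truth(simdata.make_motion_profile("squat"))


@pytest.fixture(scope="session")
def squat_noise_free(squat_truth, taf):
    """Noise-free squat with arbitrary seeded mounts, fused end to end."""
    mounts = simdata.random_mounts(42)
    recs = simdata.synthesize_marg(squat_truth, simdata.SensorErrorModel(), mounts)
    oris = {
        seg: fusion.estimate_orientation(preprocess.preprocess_recording(r, taf), taf)
        for seg, r in recs.items()
    }
    cal_idx = align.find_calibration_index(recs["foot"].gyro, recs["foot"].fs)
    angles = align.compute_joint_angles(oris, align.build_assignment(oris, cal_idx))
    return {"truth": squat_truth, "mounts": mounts, "recs": recs, "orientations": oris, "angles": angles}


@pytest.fixture(scope="session")
def shuffle_truth():
    return simdata.generate_ground_truth(simdata.make_motion_profile("shuffle_walk", n_strides=10))


@pytest.fixture(scope="session")
def shuffle_noise_free(shuffle_truth, taf):
    recs = simdata.synthesize_marg(shuffle_truth, segments=("foot",))
    foot = preprocess.preprocess_recording(recs["foot"], taf)
    ori = fusion.estimate_orientation(foot, taf)
    return {"truth": shuffle_truth, "foot": foot, "orientation": ori}


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
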