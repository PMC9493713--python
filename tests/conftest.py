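import numpy as np
import pytest

from osteokin import jcs_kinematics as jk
from osteokin import rigid_body as rb
from osteokin import synthetic_rig as sr

ONSET_FRAME = 50  # default jaw channel onset (100 ms at 500 fps)


@pytest.fixture(scope="session")
def rig():
    return sr.default_rig()

@pytest.fixture(scope="session")
def body_defs(rig):
    return sr.default_body_definitions(rig)

@pytest.fixture(scope="session")
def jcs_set(rig):
    return sr.default_jcs_set(rig)

@pytest.fixture(scope="session")
def endo_def():
    return sr.default_endocast()

@pytest.fixture(scope="session")
def clean_strike(rig):
    """Noiseless default strike (marker set, ground truth)."""
    config = sr.default_config(noise_sigma=0.0, seed=1)
    return sr.simulate_strike(rig, config)

@pytest.fixture(scope="session")
def clean_poses(clean_strike, body_defs):
    """Unfiltered rigid fits of the noiseless strike."""
    mset, _ = clean_strike
    return {b: rb.animate_body(d, mset) for b, d in body_defs.items()}

@pytest.fixture(scope="session")
def true_pose_series(clean_strike):
    _, gt = clean_strike
    return {b: gt.pose_series(b) for b in gt.poses}


def run_pipeline(mset, body_defs, filter_hz=35.0, refine_window=0, refine_order=3):
    """Canonical analysis chain: (poly-refine) -> filter -> rigid fit."""
    if refine_window > 1:
        coords = mset.coords.copy()
        bone = {m for d in body_defs.values() for m in d.marker_names}
        for j, name in enumerate(mset.markers):
            if name in bone:
                coords[:, j, :] = rb.smooth_trajectory_poly(
                    coords[:, j, :], refine_window, refine_order
                )
        mset = rb.MarkerTrajectorySet(
            fps=mset.fps, markers=list(mset.markers), coords=coords
        )
    if filter_hz and filter_hz > 0:
        mset = rb.filter_markers(mset, filter_hz)
    return {b: rb.animate_body(d, mset) for b, d in body_defs.items()}


def peak_channel_value(jcs_set, poses, joint, dof, zero_frame=ONSET_FRAME):
    """Signed extremum of one zeroed JCS channel."""
    j = jcs_set[joint]
    kin = jk.jcs_angles(j, poses[j.proximal_body], poses[j.distal_body])
    kin = jk.zero_offset(kin, zero_frame)
    c = kin.channel(dof)
    return float(c[np.argmax(np.abs(c))])
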