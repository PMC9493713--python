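"""Joint-coordinate-system kinematics and soft-tissue measures.

Relative bone motion is decomposed between paired anatomical coordinate
systems (ACS) in the fixed z-then-y-then-x Euler order under the right-hand
rule; rotations are reported in degrees, translations in the proximal-ACS
axes in cm.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._geometry import apply_hom, compose_zyx, decompose_zyx, inv_hom
from .errors import ConfigError, DegenerateMuscleError
from .rigid_body import PoseSeries


@dataclass
class JointCoordinateSystem:
    """Paired ACSs on a proximal and a distal body.

    ``acs_proximal``/``acs_distal`` are rigid transforms expressed in the
    respective bone-local frames.  The rotation order is immutable (zyx).
    """

    name: str
    proximal_body: str
    distal_body: str
    acs_proximal: np.ndarray  # 4x4, in proximal bone frame
    acs_distal: np.ndarray  # 4x4, in distal bone frame
    semantics: dict[str, str] = field(default_factory=dict)  # per-axis sign notes

    def __post_init__(self) -> None:
        self.acs_proximal = np.asarray(self.acs_proximal, dtype=float)
        self.acs_distal = np.asarray(self.acs_distal, dtype=float)
        for A in (self.acs_proximal, self.acs_distal):
            if A.shape != (4, 4):
                raise ConfigError("ACS poses must be 4x4 transforms")
            R = A[:3, :3]
            if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
                raise ConfigError("ACS rotation block must be orthonormal")


@dataclass
class EulerKinematics:
    """Six-DOF decomposition time series for one JCS.

    Channels: rz, ry, rx (degrees) and tx, ty, tz (cm).  After
    :func:`zero_offset` the reference frame reads 0 on all channels.
    """

    name: str
    fps: float
    rz: np.ndarray
    ry: np.ndarray
    rx: np.ndarray
    tx: np.ndarray
    ty: np.ndarray
    tz: np.ndarray
    valid: np.ndarray
    gimbal: np.ndarray
    zero_frame: int | None = None
    semantics: dict[str, str] = field(default_factory=dict)

    CHANNELS = ("rz", "ry", "rx", "tx", "ty", "tz")

    @property
    def n_frames(self) -> int:
        return len(self.rz)

    @property
    def time_ms(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.fps * 1000.0

    def channel(self, name: str) -> np.ndarray:
        if name not in self.CHANNELS:
            raise KeyError(name)
        return getattr(self, name)


def jcs_angles(
    jcs: JointCoordinateSystem, proximal: PoseSeries, distal: PoseSeries
) -> EulerKinematics:
    """Decompose distal-relative-to-proximal motion between the two ACSs.

    Per frame the relative transform is
    ``(pose_prox @ ACS_prox)^-1 @ (pose_dist @ ACS_dist)``; its rotation is
    split in zyx order.  Frames invalid in either pose series propagate;
    gimbal-adjacent frames (|cos ry| < 1e-6) are flagged, with rx pinned to 0
    by convention.
    """
    if proximal.n_frames != distal.n_frames:
        raise ConfigError("pose series must have the same frame count")
    if proximal.fps != distal.fps:
        raise ConfigError("pose series must share fps")
    F = proximal.n_frames
    out = {ch: np.full(F, np.nan) for ch in EulerKinematics.CHANNELS}
    valid = proximal.valid & distal.valid
    gimbal = np.zeros(F, dtype=bool)
    for f in np.nonzero(valid)[0]:
        world_p = proximal.transforms[f] @ jcs.acs_proximal
        world_d = distal.transforms[f] @ jcs.acs_distal
        rel = inv_hom(world_p) @ world_d
        rz, ry, rx, gim = decompose_zyx(rel[:3, :3])
        out["rz"][f], out["ry"][f], out["rx"][f] = np.degrees([rz, ry, rx])
        out["tx"][f], out["ty"][f], out["tz"][f] = rel[:3, 3]
        gimbal[f] = gim
    return EulerKinematics(
        name=jcs.name, fps=proximal.fps, valid=valid, gimbal=gimbal,
        semantics=dict(jcs.semantics), **out,
    )


def zero_offset(kin: EulerKinematics, reference_frame: int) -> EulerKinematics:
    """Shift every channel so the reference frame reads zero.

    Matches the convention of standardizing Euler rotations to 0 deg at the
    start of each strike.  Idempotent for a fixed reference frame.
    """
    if not (0 <= reference_frame < kin.n_frames) or not kin.valid[reference_frame]:
        raise ConfigError(f"reference frame {reference_frame} invalid")
    shifted = {
        ch: kin.channel(ch) - kin.channel(ch)[reference_frame]
        for ch in EulerKinematics.CHANNELS
    }
    return replace(kin, zero_frame=reference_frame, **shifted)


def recompose(kin: EulerKinematics, frame: int) -> np.ndarray:
    """Rotation matrix rebuilt from the (rz, ry, rx) channels at one frame."""
    return compose_zyx(
        np.radians(kin.rz[frame]), np.radians(kin.ry[frame]), np.radians(kin.rx[frame])
    )


def virtual_point(pose: PoseSeries, local: np.ndarray) -> np.ndarray:
    """World trajectory of a bone-fixed point; NaN at invalid frames."""
    local = np.asarray(local, dtype=float)
    out = np.full((pose.n_frames, 3), np.nan)
    for f in np.nonzero(pose.valid)[0]:
        out[f] = apply_hom(pose.transforms[f], local)
    return out


@dataclass
class StrainSeries:
    """Percent length change of a landmark pair relative to L_i.

    Negative strain is shortening; strain at the reference frame is 0.
    """

    muscle: str
    initial_length: float  # L_i, cm
    length: np.ndarray  # per-frame landmark distance, cm
    strain: np.ndarray  # per-frame, % of L_i
    reference_frame: int


def muscle_strain(
    origin_traj: np.ndarray,
    insertion_traj: np.ndarray,
    reference_frame: int = 0,
    name: str = "muscle",
) -> StrainSeries:
    """Strain(t) = 100 * (L(t) - L_i) / L_i from origin/insertion trajectories."""
    o = np.asarray(origin_traj, dtype=float)
    i = np.asarray(insertion_traj, dtype=float)
    if o.shape != i.shape:
        raise ConfigError("origin and insertion trajectories must match in shape")
    length = np.linalg.norm(o - i, axis=1)
    if not np.isfinite(length[reference_frame]):
        raise ConfigError(f"reference frame {reference_frame} untracked")
    li = float(length[reference_frame])
    if li <= 0:
        raise DegenerateMuscleError("initial muscle length L_i must be > 0")
    strain = 100.0 * (length - li) / li
    return StrainSeries(
        muscle=name, initial_length=li, length=length, strain=strain,
        reference_frame=reference_frame,
    )


def tongue_distances(
    right: np.ndarray, left: np.ndarray, rostral: np.ndarray
) -> dict[str, np.ndarray]:
    """Pairwise distances (cm) among the three tongue markers per frame."""
    r = np.asarray(right, dtype=float)
    l = np.asarray(left, dtype=float)
    m = np.asarray(rostral, dtype=float)
    return {
        "right_left": np.linalg.norm(r - l, axis=1),
        "right_rostral": np.linalg.norm(r - m, axis=1),
        "left_rostral": np.linalg.norm(l - m, axis=1),
    }


@dataclass
class PreyKinematics:
    """Scalar prey motion series derived from the prey marker trajectory."""

    displacement: np.ndarray  # |p(t) - p(0)|, cm
    velocity: np.ndarray  # |dp/dt|, cm/s
    acceleration: np.ndarray  # |d2p/dt2|, cm/s^2
    fps: float


def prey_kinematics(prey_traj: np.ndarray, fps: float) -> PreyKinematics:
    """Displacement from start plus velocity/acceleration magnitudes.

    Velocity and acceleration are magnitudes of the first and second vector
    derivatives of position (second-order central differences, one-sided at
    the ends) — not derivatives of the scalar displacement, avoiding sign
    artifacts when the prey re-crosses its start point.
    """
    p = np.atleast_2d(np.asarray(prey_traj, dtype=float))
    if p.shape[0] < 3:
        raise ConfigError("need >=3 frames for prey kinematics")
    dt = 1.0 / fps
    v = np.gradient(p, dt, axis=0, edge_order=2)
    a = np.gradient(v, dt, axis=0, edge_order=2)
    return PreyKinematics(
        displacement=np.linalg.norm(p - p[0], axis=1),
        velocity=np.linalg.norm(v, axis=1),
        acceleration=np.linalg.norm(a, axis=1),
        fps=fps,
    )
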