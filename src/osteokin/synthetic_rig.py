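"""Forward-kinematics generator of strike-like marker datasets.

Builds an articulated skull rig (neurocranium riding on a body plane, a
hinged lower jaw, bilateral curved ceratohyals with coupled depression and
long-axis rotation, clavicles, and a cranial rib), drives it with smooth
raised-cosine motion channels, and emits noisy marker tables together with
exact ground truth for round-trip testing of the analysis pipeline.

World frame: right-handed, +x rostral, +y dorsal, +z toward the animal's
right; units cm and ms.  Every body's rest pose is the identity, so marker
"local" coordinates double as the reference (CT-pose) coordinates.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np

from ._geometry import apply_hom, compose_zyx, hom, orthonormal_frame
from .errors import ConfigError
from .jcs_kinematics import JointCoordinateSystem
from .rigid_body import MarkerTrajectorySet, PoseSeries, RigidBodyDefinition

# ---------------------------------------------------------------------------
# Motion profiles


@dataclass
class ProfileChannel:
    """One motion channel: rise to amplitude, then return (or hold).

    ``amplitude`` is degrees for rotation DOFs (rz/ry/rx) and cm for
    translation DOFs (tx/ty/tz).
    """

    amplitude: float
    onset_ms: float = 0.0
    time_to_peak_ms: float = 100.0
    return_ms: float = 100.0
    shape: str = "raised-cosine"

    def __post_init__(self) -> None:
        if self.time_to_peak_ms <= 0:
            raise ConfigError("time_to_peak_ms must be positive")
        if self.return_ms < 0:
            raise ConfigError("return_ms must be >= 0")
        if self.shape not in ("raised-cosine", "hold"):
            raise ConfigError(f"unknown profile shape {self.shape!r}")


def motion_profile(channel: ProfileChannel, t_ms: np.ndarray | float) -> np.ndarray:
    """Evaluate a channel at time(s) ``t_ms``.

    C1-smooth: zero value and slope at onset, amplitude at
    ``onset + time_to_peak``, cosine return toward zero over ``return_ms``
    (or a hold at amplitude for the "hold" shape); zero outside the active
    interval.
    """
    t = np.asarray(t_ms, dtype=float)
    a = channel.amplitude
    t0 = channel.onset_ms
    tp = channel.time_to_peak_ms
    tr = channel.return_ms
    out = np.zeros_like(t)
    rise = (t >= t0) & (t <= t0 + tp)
    out[rise] = a / 2.0 * (1.0 - np.cos(np.pi * (t[rise] - t0) / tp))
    if channel.shape == "hold":
        out[t > t0 + tp] = a
    elif tr > 0:
        ret = (t > t0 + tp) & (t <= t0 + tp + tr)
        out[ret] = a / 2.0 * (1.0 + np.cos(np.pi * (t[ret] - t0 - tp) / tr))
    return out if np.ndim(t_ms) else float(out)


# ---------------------------------------------------------------------------
# Rig definition


@dataclass
class RigBody:
    """One articulated body: hinge point/frame relative to its parent.

    ``acs`` columns are the joint x/y/z axes in the parent's rest frame;
    the x column is the long axis where one is meaningful.  Rotation
    channels rz/ry/rx act about these axes (composed z-then-y-then-x, so a
    depression-then-long-axis drive decomposes exactly).
    """

    name: str
    parent: str | None
    hinge: np.ndarray = field(default_factory=lambda: np.zeros(3))
    acs: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        self.hinge = np.asarray(self.hinge, dtype=float)
        self.acs = np.asarray(self.acs, dtype=float)
        if not np.allclose(self.acs.T @ self.acs, np.eye(3), atol=1e-9):
            raise ConfigError(f"body {self.name}: ACS axes must be orthonormal")


@dataclass
class TongueConfig:
    """Three tongue points tracking the ceratohyal tips with a stretch factor."""

    right_body: str = "cerato_r"
    left_body: str = "cerato_l"
    right_tip: np.ndarray = field(default_factory=lambda: np.zeros(3))
    left_tip: np.ndarray = field(default_factory=lambda: np.zeros(3))
    rostral_offset: np.ndarray = field(default_factory=lambda: np.array([0.9, -0.1, 0.35]))
    stretch_factor: float = 0.05
    driver_body: str = "cerato_r"
    driver_dof: str = "rx"


@dataclass
class PreyConfig:
    """Constant-acceleration-then-decay prey displacement law."""

    start: np.ndarray = field(default_factory=lambda: np.array([9.5, -0.1, 0.2]))
    direction: np.ndarray = field(default_factory=lambda: np.array([-1.0, 0.0, 0.0]))
    onset_ms: float = 340.0
    acceleration: float = 2000.0  # cm/s^2
    accel_duration_ms: float = 31.5
    decay_tau_ms: float = 62.0
    stop_speed: float = 1.0  # cm/s; below this the prey is parked

    def displacement(self, t_ms: np.ndarray) -> np.ndarray:
        """Scalar distance travelled along ``direction`` at each time."""
        t = (np.asarray(t_ms, dtype=float) - self.onset_ms) / 1000.0
        ta = self.accel_duration_ms / 1000.0
        tau = self.decay_tau_ms / 1000.0
        vmax = self.acceleration * ta
        d_acc = 0.5 * self.acceleration * ta**2
        t_stop = ta + tau * np.log(max(vmax / self.stop_speed, 1.0))
        out = np.zeros_like(t)
        ph1 = (t > 0) & (t <= ta)
        out[ph1] = 0.5 * self.acceleration * t[ph1] ** 2
        ph2 = (t > ta) & (t <= t_stop)
        out[ph2] = d_acc + vmax * tau * (1.0 - np.exp(-(t[ph2] - ta) / tau))
        out[t > t_stop] = d_acc + vmax * tau * (1.0 - np.exp(-(t_stop - ta) / tau))
        return out


@dataclass
class RigDefinition:
    """Articulated bodies, their markers, landmarks, and soft-point rules."""

    bodies: list[RigBody]
    markers: list[tuple[str, str, np.ndarray]]  # (marker, body, local cm)
    landmarks: dict[str, tuple[str, np.ndarray]] = field(default_factory=dict)
    tongue: TongueConfig | None = None
    prey: PreyConfig | None = None

    def __post_init__(self) -> None:
        names = [b.name for b in self.bodies]
        if len(set(names)) != len(names):
            raise ConfigError("body names must be unique")
        self.markers = [
            (m, b, np.asarray(p, dtype=float)) for m, b, p in self.markers
        ]
        for body in names:
            pts = np.array([p for _, b, p in self.markers if b == body])
            if len(pts) >= 3:
                centered = pts - pts.mean(axis=0)
                s = np.linalg.svd(centered, compute_uv=False)
                if s[1] / max(s[0], 1.0) < 1e-8:
                    raise ConfigError(f"body {body}: markers are collinear")
        by_name = {b.name: b for b in self.bodies}
        for b in self.bodies:
            if b.parent is not None and b.parent not in by_name:
                raise ConfigError(f"body {b.name}: unknown parent {b.parent!r}")

    def body(self, name: str) -> RigBody:
        for b in self.bodies:
            if b.name == name:
                return b
        raise KeyError(name)

    def body_order(self) -> list[str]:
        """Parents-before-children evaluation order."""
        order: list[str] = []
        remaining = {b.name: b for b in self.bodies}
        while remaining:
            progress = False
            for name, b in list(remaining.items()):
                if b.parent is None or b.parent in order:
                    order.append(name)
                    del remaining[name]
                    progress = True
            if not progress:
                raise ConfigError("cyclic parent relationships in rig")
        return order

    def markers_of(self, body: str) -> list[tuple[str, np.ndarray]]:
        return [(m, p) for m, b, p in self.markers if b == body]


@dataclass
class StrikeProfileConfig:
    """Per-body motion channels plus sampling and noise parameters."""

    channels: dict[str, dict[str, ProfileChannel]]
    fps: float = 500.0
    duration_ms: float = 1000.0
    noise_sigma: float = 0.029  # cm, matches typical tracking precision
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fps <= 0 or self.duration_ms <= 0:
            raise ConfigError("fps and duration must be positive")
        if self.noise_sigma < 0:
            raise ConfigError("noise_sigma must be >= 0")
        for body, dofs in self.channels.items():
            for dof, ch in dofs.items():
                if dof not in ("rz", "ry", "rx", "tx", "ty", "tz"):
                    raise ConfigError(f"{body}: unknown DOF {dof!r}")
                if ch.onset_ms + ch.time_to_peak_ms > self.duration_ms:
                    raise ConfigError(
                        f"{body}.{dof}: onset + time_to_peak exceeds duration"
                    )

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_ms / 1000.0 * self.fps)) + 1

    def time_ms(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.fps * 1000.0


@dataclass
class GroundTruth:
    """Exact poses, channel series, and event times emitted with a strike."""

    fps: float
    time_ms: np.ndarray
    poses: dict[str, np.ndarray]  # body -> (F, 4, 4)
    channels: dict[str, dict[str, np.ndarray]]  # body -> dof -> series
    events: dict[str, float]  # ms
    marker_names: list[str]
    markers_noiseless: np.ndarray  # (F, M, 3)
    stretch: np.ndarray | None = None  # tongue scale factor per frame
    volumes: np.ndarray | None = None

    def pose_series(self, body: str) -> PoseSeries:
        T = self.poses[body]
        F = T.shape[0]
        return PoseSeries(
            body=body, transforms=T, residual=np.zeros(F),
            valid=np.ones(F, dtype=bool), fps=self.fps,
        )


# ---------------------------------------------------------------------------
# Simulation


def _joint_transform(body: RigBody, values: dict[str, float]) -> np.ndarray:
    """Local transform of a body relative to its parent for channel values."""
    rz = np.radians(values.get("rz", 0.0))
    ry = np.radians(values.get("ry", 0.0))
    rx = np.radians(values.get("rx", 0.0))
    t = np.array([values.get("tx", 0.0), values.get("ty", 0.0), values.get("tz", 0.0)])
    RT = hom(compose_zyx(rz, ry, rx), t)
    A = hom(body.acs)
    Ainv = hom(body.acs.T)
    return hom(None, body.hinge) @ A @ RT @ Ainv @ hom(None, -body.hinge)


def true_poses(
    rig: RigDefinition, config: StrikeProfileConfig
) -> tuple[dict[str, np.ndarray], dict[str, dict[str, np.ndarray]]]:
    """Forward kinematics: world pose per body per frame, plus channel series."""
    t_ms = config.time_ms()
    F = len(t_ms)
    channels: dict[str, dict[str, np.ndarray]] = {}
    for body, dofs in config.channels.items():
        channels[body] = {
            dof: np.asarray(motion_profile(ch, t_ms)) for dof, ch in dofs.items()
        }
    poses: dict[str, np.ndarray] = {}
    for name in rig.body_order():
        body = rig.body(name)
        W = np.tile(np.eye(4), (F, 1, 1))
        vals = channels.get(name, {})
        for f in range(F):
            M = _joint_transform(body, {d: s[f] for d, s in vals.items()})
            if body.parent is not None:
                M = poses[body.parent][f] @ M
            W[f] = M
        poses[name] = W
    return poses, channels


def _soft_points(
    rig: RigDefinition,
    config: StrikeProfileConfig,
    poses: dict[str, np.ndarray],
    channels: dict[str, dict[str, np.ndarray]],
) -> tuple[list[str], np.ndarray, np.ndarray | None]:
    """Tongue and prey trajectories (noiseless)."""
    t_ms = config.time_ms()
    F = len(t_ms)
    names: list[str] = []
    trajs: list[np.ndarray] = []
    stretch = None
    if rig.tongue is not None:
        tc = rig.tongue
        pr = np.einsum(
            "fij,j->fi", poses[tc.right_body][:, :3, :3], tc.right_tip
        ) + poses[tc.right_body][:, :3, 3]
        pl = np.einsum(
            "fij,j->fi", poses[tc.left_body][:, :3, :3], tc.left_tip
        ) + poses[tc.left_body][:, :3, 3]
        pm = (pr + pl) / 2.0 + tc.rostral_offset
        drive = channels.get(tc.driver_body, {}).get(tc.driver_dof)
        if drive is not None and np.max(np.abs(drive)) > 0:
            stretch = 1.0 + tc.stretch_factor * np.abs(drive) / np.max(np.abs(drive))
        else:
            stretch = np.ones(F)
        pts = np.stack([pr, pl, pm], axis=1)  # (F, 3, 3)
        centroid = pts.mean(axis=1, keepdims=True)
        pts = centroid + (pts - centroid) * stretch[:, None, None]
        names += ["tongue_right", "tongue_left", "tongue_rostral"]
        trajs += [pts[:, 0], pts[:, 1], pts[:, 2]]
    if rig.prey is not None:
        pc = rig.prey
        d = pc.displacement(t_ms)
        direction = np.asarray(pc.direction, dtype=float)
        direction = direction / np.linalg.norm(direction)
        names.append("prey")
        trajs.append(pc.start + d[:, None] * direction)
    if not names:
        return [], np.empty((F, 0, 3)), stretch
    return names, np.stack(trajs, axis=1), stretch


def simulate_strike(
    rig: RigDefinition, config: StrikeProfileConfig
) -> tuple[MarkerTrajectorySet, GroundTruth]:
    """Generate one synthetic strike: noisy marker table + exact ground truth.

    Markers are the true poses applied to the local coordinates plus i.i.d.
    isotropic Gaussian noise of ``config.noise_sigma``; identical configs and
    seeds produce bit-identical output.
    """
    poses, channels = true_poses(rig, config)
    F = config.n_frames
    bone_names = [m for m, _, _ in rig.markers]
    bone_coords = np.empty((F, len(bone_names), 3))
    for j, (_, body, local) in enumerate(rig.markers):
        W = poses[body]
        bone_coords[:, j, :] = np.einsum("fij,j->fi", W[:, :3, :3], local) + W[:, :3, 3]
    soft_names, soft_coords, stretch = _soft_points(rig, config, poses, channels)
    names = bone_names + soft_names
    coords = np.concatenate([bone_coords, soft_coords], axis=1)

    noiseless = coords.copy()
    if config.noise_sigma > 0:
        rng = np.random.default_rng(config.seed)
        coords = coords + rng.normal(0.0, config.noise_sigma, coords.shape)

    events: dict[str, float] = {}
    jaw = config.channels.get("lower_jaw", {}).get("rz")
    if jaw is not None:
        events["onset_ms"] = jaw.onset_ms
        events["peak_gape_ms"] = jaw.onset_ms + jaw.time_to_peak_ms
        events["jaw_close_ms"] = jaw.onset_ms + jaw.time_to_peak_ms + jaw.return_ms
    for body, dofs in config.channels.items():
        for dof, ch in dofs.items():
            events[f"peak_{body}_{dof}_ms"] = ch.onset_ms + ch.time_to_peak_ms

    gt = GroundTruth(
        fps=config.fps, time_ms=config.time_ms(), poses=poses, channels=channels,
        events=events, marker_names=names, markers_noiseless=noiseless,
        stretch=stretch,
    )
    mset = MarkerTrajectorySet(fps=config.fps, markers=names, coords=coords)
    return mset, gt


def simulate_frozen(
    rig: RigDefinition,
    n_frames: int = 160,
    noise_sigma: float = 0.029,
    seed: int = 0,
    fps: float = 500.0,
) -> MarkerTrajectorySet:
    """Motionless (frozen-specimen) recording: static true pose, noise only.

    The ~160-frame default mirrors the usual precision-study protocol.
    """
    if n_frames < 2:
        raise ConfigError("n_frames must be >= 2")
    if rig.prey is not None:
        # a frozen specimen has no moving prey: push the law past the trial
        rig = replace(rig, prey=replace(rig.prey, onset_ms=float("inf")))
    config = StrikeProfileConfig(
        channels={}, fps=fps, duration_ms=(n_frames - 1) / fps * 1000.0,
        noise_sigma=noise_sigma, seed=seed,
    )
    mset, _ = simulate_strike(rig, config)
    return mset


# ---------------------------------------------------------------------------
# Default rig: marked-element roster of a lungfish-like skull


_MIRROR = np.diag([1.0, 1.0, -1.0])


def _cerato_geometry() -> dict[str, np.ndarray]:
    post_r = np.array([0.5, -0.5, 1.0])
    direction = np.array([4.5, -0.8, -0.7])
    A_r = orthonormal_frame(direction, np.array([0.0, 0.0, 1.0]))
    tip_r = post_r + 4.6 * A_r[:, 0]
    post_l = _MIRROR @ post_r
    x_l = _MIRROR @ A_r[:, 0]
    z_l = -(_MIRROR @ A_r[:, 2])
    A_l = orthonormal_frame(x_l, z_l)
    tip_l = _MIRROR @ tip_r
    return {"post_r": post_r, "A_r": A_r, "tip_r": tip_r,
            "post_l": post_l, "A_l": A_l, "tip_l": tip_l}


def default_rig() -> RigDefinition:
    """Standard rig: the full marked-element roster with plausible geometry.

    3 markers per jaw/ceratohyal/clavicle, 5 in the neurocranium, 3 in the
    cranial rib, 6 body-plane points, 3 tongue points, 1 prey point.
    """
    cg = _cerato_geometry()
    bodies = [
        RigBody("body_plane", None),
        RigBody("neurocranium", "body_plane", hinge=np.array([0.0, 0.5, 0.0])),
        RigBody("upper_jaw", "neurocranium"),
        RigBody("lower_jaw", "neurocranium", hinge=np.zeros(3)),
        RigBody("cerato_r", "neurocranium", hinge=cg["post_r"], acs=cg["A_r"]),
        RigBody("cerato_l", "neurocranium", hinge=cg["post_l"], acs=cg["A_l"]),
        RigBody("clav_r", "neurocranium", hinge=np.array([-1.5, -0.5, 0.8])),
        RigBody("clav_l", "neurocranium", hinge=np.array([-1.5, -0.5, -0.8])),
        RigBody("cranial_rib", "neurocranium", hinge=np.array([-2.0, 0.3, 0.0])),
    ]
    x_r, y_r, z_r = cg["A_r"].T
    x_l, y_l, z_l = cg["A_l"].T
    # generous off-axis spread (the bone is curved): keeps long-axis rotation
    # well conditioned at realistic tracking noise
    cr = [
        cg["post_r"] + 1.0 * x_r + 0.9 * y_r - 0.4 * z_r,
        cg["post_r"] + 2.6 * x_r - 0.9 * y_r + 0.7 * z_r,
        cg["post_r"] + 4.2 * x_r + 0.6 * y_r - 0.9 * z_r,
    ]
    cl = [
        cg["post_l"] + 1.0 * x_l + 0.9 * y_l - 0.4 * z_l,
        cg["post_l"] + 2.6 * x_l - 0.9 * y_l + 0.7 * z_l,
        cg["post_l"] + 4.2 * x_l + 0.6 * y_l - 0.9 * z_l,
    ]
    clav_r = [
        np.array([-1.2, -1.2, 0.9]),
        np.array([-0.8, -1.8, 0.6]),
        np.array([-1.6, -1.9, 1.1]),
    ]
    markers: list[tuple[str, str, np.ndarray]] = []
    for i, p in enumerate(
        [
            np.array([0.8, 1.2, 0.9]),
            np.array([2.2, 1.6, -0.9]),
            np.array([3.6, 1.2, 0.8]),
            np.array([4.6, 1.0, -0.6]),
            np.array([2.8, 2.0, 0.2]),
        ],
        1,
    ):
        markers.append((f"neuro_{i}", "neurocranium", p))
    for i, p in enumerate(
        [np.array([5.0, 0.5, 0.9]), np.array([6.3, 0.05, -0.9]),
         np.array([7.0, 0.55, 0.2])], 1,
    ):
        markers.append((f"ujaw_{i}", "upper_jaw", p))
    for i, p in enumerate(
        [np.array([4.6, -1.0, 0.9]), np.array([6.2, -0.2, -0.95]),
         np.array([7.1, -0.7, 0.35])], 1,
    ):
        markers.append((f"ljaw_{i}", "lower_jaw", p))
    for i, p in enumerate(cr, 1):
        markers.append((f"cerato_r_{i}", "cerato_r", p))
    for i, p in enumerate(cl, 1):
        markers.append((f"cerato_l_{i}", "cerato_l", p))
    for i, p in enumerate(clav_r, 1):
        markers.append((f"clav_r_{i}", "clav_r", p))
    for i, p in enumerate(clav_r, 1):
        markers.append((f"clav_l_{i}", "clav_l", _MIRROR @ p))
    for i, p in enumerate(
        [np.array([-2.5, 0.2, 0.3]), np.array([-3.2, -0.1, -0.2]),
         np.array([-2.9, -0.5, 0.45])], 1,
    ):
        markers.append((f"rib_{i}", "cranial_rib", p))
    for i, p in enumerate(
        [np.array([-6.0, -2.0, 0.8]), np.array([-4.0, -2.1, -0.8]),
         np.array([-8.0, -1.9, -0.6]), np.array([-9.0, -2.0, 0.5])], 1,
    ):
        markers.append((f"bp_v{i}", "body_plane", p))
    for i, p in enumerate(
        [np.array([-5.0, 2.2, 0.2]), np.array([-7.0, 2.3, -0.3])], 1,
    ):
        markers.append((f"bp_d{i}", "body_plane", p))

    landmarks = {
        "upper_tip": ("upper_jaw", np.array([7.5, 0.0, 0.0])),
        "lower_tip": ("lower_jaw", np.array([7.5, -0.2, 0.0])),
        "cerato_r_tip": ("cerato_r", cg["tip_r"]),
        "cerato_l_tip": ("cerato_l", cg["tip_l"]),
        "rc_origin": ("clav_r", np.array([-1.0, -1.5, 0.8])),
        "rc_insertion": ("cerato_r", cg["post_r"] + 3.5 * x_r),
        "cch_origin": ("cranial_rib", np.array([-3.0, -0.3, 0.2])),
        "cch_insertion": ("clav_r", np.array([-1.3, -1.6, 0.9])),
    }
    tongue = TongueConfig(
        right_tip=cg["tip_r"] + np.array([0.0, 0.0, 0.45]),
        left_tip=cg["tip_l"] - np.array([0.0, 0.0, 0.45]),
    )
    return RigDefinition(
        bodies=bodies, markers=markers, landmarks=landmarks,
        tongue=tongue, prey=PreyConfig(),
    )


def default_config(
    noise_sigma: float = 0.0, seed: int = 0, fps: float = 500.0
) -> StrikeProfileConfig:
    """Strike channels using the published mean amplitudes/timings as truth.

    Peak jaw depression -11.6 deg 273 ms after a 100 ms onset (so peak gape
    sits at 373 ms and the jaw closes at 565 ms, a 465 ms strike);
    ceratohyal depression -20.7 deg and internal long-axis rotation
    -13.3 deg peaking after peak gape; cranial elevation +3.8 deg; clavicle
    retraction -22.4 deg; cranial-rib retraction -7.7 deg.
    """
    ch = {
        "neurocranium": {"rz": ProfileChannel(3.8, 150.0, 270.0, 250.0)},
        "lower_jaw": {"rz": ProfileChannel(-11.6, 100.0, 273.0, 192.0)},
        "cerato_r": {
            "rz": ProfileChannel(-20.7, 187.0, 280.0, 280.0),
            "rx": ProfileChannel(-13.3, 244.0, 280.0, 280.0),
        },
        "cerato_l": {
            "rz": ProfileChannel(-20.7, 187.0, 280.0, 280.0),
            "rx": ProfileChannel(13.3, 244.0, 280.0, 280.0),
        },
        "clav_r": {"rz": ProfileChannel(-22.4, 213.0, 280.0, 280.0)},
        "clav_l": {"rz": ProfileChannel(-22.4, 213.0, 280.0, 280.0)},
        "cranial_rib": {"rz": ProfileChannel(-7.7, 253.0, 280.0, 200.0)},
    }
    return StrikeProfileConfig(
        channels=ch, fps=fps, duration_ms=1000.0,
        noise_sigma=noise_sigma, seed=seed,
    )


def default_body_definitions(rig: RigDefinition) -> dict[str, RigidBodyDefinition]:
    """Rigid-body definitions (reference = rest-pose marker coordinates)."""
    out: dict[str, RigidBodyDefinition] = {}
    for body in rig.body_order():
        mk = rig.markers_of(body)
        if len(mk) >= 3:
            out[body] = RigidBodyDefinition(
                name=body,
                marker_names=[m for m, _ in mk],
                reference=np.array([p for _, p in mk]),
            )
    return out


def default_jcs_set(rig: RigDefinition) -> dict[str, JointCoordinateSystem]:
    """One JCS per articulated body, ACS at the body's hinge frame.

    The lower jaw pairs with the upper jaw (which is rigidly fused to the
    neurocranium); every other body pairs with its kinematic parent.  Since
    all rest poses are the identity, the same ACS transform serves both the
    proximal and distal bone frames.
    """
    out: dict[str, JointCoordinateSystem] = {}
    semantics = {
        "lower_jaw": {"rz": "negative = depression"},
        "cerato_r": {"rz": "negative = depression",
                     "rx": "negative = internal long-axis rotation"},
        "cerato_l": {"rz": "negative = depression",
                     "rx": "positive = internal long-axis rotation (mirrored)"},
        "neurocranium": {"rz": "positive = cranial elevation"},
        "clav_r": {"rz": "negative = retraction"},
        "clav_l": {"rz": "negative = retraction"},
        "cranial_rib": {"rz": "negative = retraction (bucket-handle axis)"},
    }
    for body in rig.body_order():
        b = rig.body(body)
        if b.parent is None or body == "upper_jaw":
            continue
        acs = hom(None, b.hinge) @ hom(b.acs)
        proximal = "upper_jaw" if body == "lower_jaw" else b.parent
        out[body] = JointCoordinateSystem(
            name=body, proximal_body=proximal, distal_body=body,
            acs_proximal=acs, acs_distal=acs,
            semantics=semantics.get(body, {}),
        )
    return out


def default_endocast():
    """Locator constellation over the right anterior oral-cavity surfaces.

    >=40 locators spread over the palate (neurocranium), jaw floor
    (lower jaw), ceratohyal, clavicle (posterior wall), and midline sheet so
    that every freeze unit moves some locators.
    """
    from .endocast import EndocastDefinition

    cg = _cerato_geometry()
    x_r, y_r, z_r = cg["A_r"].T
    locs: list[tuple[str, np.ndarray]] = []
    for x in (2.5, 4.75, 7.0):  # palate roof
        for z in (0.0, 0.6, 1.2):
            locs.append(("neurocranium", np.array([x, 0.3, z])))
    for x in (4.5, 5.3, 6.1, 7.0):  # mouth floor, front
        for z in (0.0, 0.5, 1.0):
            locs.append(("lower_jaw", np.array([x, -0.4, z])))
    for s in (1.0, 2.5, 4.0):  # floor, middle (hyoid)
        for off in (-0.15, 0.25):
            locs.append(("cerato_r", cg["post_r"] + s * x_r + off * y_r))
    for y in (-1.4, -0.8, -0.2):  # posterior wall
        for z in (0.3, 0.9):
            locs.append(("clav_r", np.array([-1.2, y, z])))
    for x in (2.5, 4.75, 7.0):  # midline sheet
        for y in (-0.4, 0.0):
            locs.append(("neurocranium", np.array([x, y, 0.0])))
    locs.append(("neurocranium", np.array([1.8, 0.0, 0.6])))  # anterior wall
    locs.append(("neurocranium", np.array([1.8, -0.3, 0.2])))
    return EndocastDefinition(locators=locs, alpha=2.0, bilateral_factor=2.0)


# ---------------------------------------------------------------------------
# Config (de)serialization


def config_to_json(config: StrikeProfileConfig, path: str | Path) -> None:
    doc = asdict(config)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)


def config_from_json(path: str | Path) -> StrikeProfileConfig:
    with open(path) as fh:
        doc = json.load(fh)
    channels = {
        body: {dof: ProfileChannel(**ch) for dof, ch in dofs.items()}
        for body, dofs in doc.pop("channels").items()
    }
    return StrikeProfileConfig(channels=channels, **doc)


def write_ground_truth_poses(gt: GroundTruth, directory: str | Path) -> None:
    """Sidecar CSVs: 16-column row-major homogeneous transforms per body."""
    from .rigid_body import write_transforms_csv

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for body in gt.poses:
        write_transforms_csv(gt.pose_series(body), directory / f"{body}_truth.csv")
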