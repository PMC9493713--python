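"""Relative contribution to volume change (RCVC) by rolling bone freezing.

For each window [t, t+N] and each freeze unit i the unit's pose relative to
the neurocranium is held at its frame-t value while the neurocranium moves
as recorded; the endocast volume change with and without the freeze gives

    RCVC_i = (dV_full - dV_frozen_i) / sum_j |dV_full - dV_frozen_j|

so positive values mean the unit's own motion expands the cavity.  Windows
advance one frame at a time; the value is stamped at the window centre and
truncated windows at the trial ends are dropped.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from ._geometry import inv_hom
from .endocast import EndocastDefinition, alpha_shape_volume, locator_cloud
from .errors import ConfigError
from .rigid_body import PoseSeries


@dataclass(frozen=True)
class FreezeUnit:
    """A single bone or a mirrored bilateral pair frozen as one unit."""

    name: str
    bodies: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.bodies:
            raise ConfigError(f"freeze unit {self.name}: no bodies")


@dataclass
class FreezeWindowConfig:
    """Rolling-freeze parameters: window length and disjoint freeze units."""

    window_frames: int
    units: list[FreezeUnit]
    neurocranium: str = "neurocranium"

    def __post_init__(self) -> None:
        if self.window_frames < 2:
            raise ConfigError("window_frames must be >= 2")
        if not self.units:
            raise ConfigError("need at least one freeze unit")
        seen: set[str] = set()
        for u in self.units:
            overlap = seen.intersection(u.bodies)
            if overlap:
                raise ConfigError(f"freeze units overlap on {sorted(overlap)}")
            seen.update(u.bodies)
        if self.neurocranium in seen:
            raise ConfigError("the neurocranium cannot be a freeze unit")


@dataclass
class RCVCResult:
    """Per-unit, per-window volume contributions."""

    unit_names: list[str]
    window_center_time_ms: np.ndarray  # (W,)
    window_start_frame: np.ndarray  # (W,)
    dv_full: np.ndarray  # (W,), cm^3
    dv_frozen: np.ndarray  # (W, n), cm^3
    rcvc: np.ndarray  # (W, n), signed, sum of |.| = 1 when defined
    degenerate: np.ndarray  # (W,) True where the denominator vanished
    fps: float


def freeze_bone(
    poses: dict[str, PoseSeries],
    unit: FreezeUnit,
    neurocranium: str,
    window: tuple[int, int],
) -> dict[str, PoseSeries]:
    """Hold a unit's pose relative to the neurocranium over [t0, t1].

    Within the window the unit's world pose becomes
    ``neuro(s) @ neuro(t0)^-1 @ body(t0)``; all other bodies are untouched.
    Returns a new pose dict (inputs are not mutated).
    """
    t0, t1 = window
    neuro = poses[neurocranium]
    frames = range(t0, t1 + 1)
    needed = [neuro] + [poses[b] for b in unit.bodies]
    for p in needed:
        if t1 >= p.n_frames or not np.all(p.valid[t0 : t1 + 1]):
            raise ConfigError(
                f"freeze window [{t0}, {t1}] has invalid frames for {p.body}"
            )
    out = dict(poses)
    anchor = inv_hom(neuro.transforms[t0])
    for body in unit.bodies:
        p = poses[body]
        rel0 = anchor @ p.transforms[t0]
        transforms = p.transforms.copy()
        for s in frames:
            transforms[s] = neuro.transforms[s] @ rel0
        out[body] = replace(p, transforms=transforms)
    return out


def _window_volume(
    defn: EndocastDefinition, poses: dict[str, PoseSeries], frame: int
) -> float | None:
    cloud = locator_cloud(defn, poses, frame)
    if cloud is None:
        return None
    return defn.bilateral_factor * alpha_shape_volume(
        cloud, defn.alpha, defn.largest_component_only
    )


def _frozen_cloud(
    defn: EndocastDefinition,
    poses: dict[str, PoseSeries],
    unit: FreezeUnit,
    neurocranium: str,
    t0: int,
    t1: int,
) -> np.ndarray | None:
    """World locator cloud at t1 with the unit frozen since t0.

    Equivalent to ``locator_cloud`` on :func:`freeze_bone` output, but only
    composes the frozen pose at the window end (no pose-array copies).
    """
    neuro = poses[neurocranium]
    if not (neuro.valid[t0] and neuro.valid[t1]):
        return None
    anchor = neuro.transforms[t1] @ inv_hom(neuro.transforms[t0])
    frozen_T = {}
    for body in unit.bodies:
        p = poses[body]
        if not p.valid[t0]:
            return None
        frozen_T[body] = anchor @ p.transforms[t0]
    cloud = np.empty((len(defn.locators), 3))
    for i, (body, local) in enumerate(defn.locators):
        if body in frozen_T:
            T = frozen_T[body]
        else:
            p = poses[body]
            if not p.valid[t1]:
                return None
            T = p.transforms[t1]
        cloud[i] = T[:3, :3] @ local + T[:3, 3]
    return cloud


def rcvc_series(
    defn: EndocastDefinition,
    poses: dict[str, PoseSeries],
    config: FreezeWindowConfig,
) -> RCVCResult:
    """Rolling-window RCVC for every configured freeze unit.

    Windows containing invalid poses are skipped with a warning; windows
    where no unit affects the volume (zero denominator) report RCVC 0 for
    all units and are flagged degenerate.
    """
    frame_counts = {p.n_frames for p in poses.values()}
    fps_set = {p.fps for p in poses.values()}
    if len(frame_counts) != 1 or len(fps_set) != 1:
        raise ConfigError("pose series must agree in frame count and fps")
    F = frame_counts.pop()
    fps = fps_set.pop()
    N = config.window_frames
    if F <= N:
        raise ConfigError(f"trial length {F} must exceed window {N}")
    for u in config.units:
        for b in u.bodies:
            if b not in poses:
                raise ConfigError(f"freeze unit {u.name}: no poses for body {b}")
    if config.neurocranium not in poses:
        raise ConfigError(f"no poses for neurocranium {config.neurocranium!r}")

    n = len(config.units)
    starts, dv_full_l, dv_frozen_l = [], [], []
    for t0 in range(F - N):
        t1 = t0 + N
        v0 = _window_volume(defn, poses, t0)
        v1 = _window_volume(defn, poses, t1)
        if v0 is None or v1 is None:
            warnings.warn(f"window [{t0}, {t1}] skipped: invalid poses")
            continue
        row = np.empty(n)
        ok = True
        for i, unit in enumerate(config.units):
            cloud = _frozen_cloud(defn, poses, unit, config.neurocranium, t0, t1)
            if cloud is None:
                warnings.warn(f"window [{t0}, {t1}] skipped: invalid poses")
                ok = False
                break
            vf = defn.bilateral_factor * alpha_shape_volume(
                cloud, defn.alpha, defn.largest_component_only
            )
            row[i] = vf - v0
        if not ok:
            continue
        starts.append(t0)
        dv_full_l.append(v1 - v0)
        dv_frozen_l.append(row)
    if not starts:
        raise ConfigError("no usable windows")

    start = np.array(starts)
    dv_full = np.array(dv_full_l)
    dv_frozen = np.array(dv_frozen_l)
    diff = dv_full[:, None] - dv_frozen
    denom = np.sum(np.abs(diff), axis=1)
    degenerate = denom == 0
    rcvc = np.zeros_like(diff)
    nz = ~degenerate
    rcvc[nz] = diff[nz] / denom[nz, None]
    center_ms = (start + N / 2.0) / fps * 1000.0
    return RCVCResult(
        unit_names=[u.name for u in config.units],
        window_center_time_ms=center_ms,
        window_start_frame=start,
        dv_full=dv_full,
        dv_frozen=dv_frozen,
        rcvc=rcvc,
        degenerate=degenerate,
        fps=fps,
    )
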