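"""Rigid-body pose estimation from marker trajectories.

Turns frame-indexed 3D marker coordinates into per-frame rigid transforms
(bone-local -> world), with zero-phase low-pass filtering, polynomial
trajectory refinement, and marker/JCS precision reporting.

Units: centimetres and frames-per-second throughout.  Transforms are stored
internally in the column-vector convention (``world = T @ [local, 1]``);
the CSV dialect written by :func:`write_transforms_csv` uses the row-vector
("animation package") layout with the translation in the fourth row.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal

from ._geometry import apply_hom, hom, inv_hom, is_rotation
from .errors import ConfigError, DegenerateFitError, FormatError, UnusableBodyError

_COLLINEAR_TOL = 1e-8


# ---------------------------------------------------------------------------
# Domain types


@dataclass
class MarkerTrajectorySet:
    """Frame-indexed 3D coordinates of named markers.

    ``coords`` has shape (frames, markers, 3); untracked marker-frames are
    NaN.  All frames share the same marker roster.
    """

    fps: float
    markers: list[str]
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.fps <= 0:
            raise ConfigError("fps must be positive")
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ConfigError("coords must have shape (frames, markers, 3)")
        if self.coords.shape[1] != len(self.markers):
            raise ConfigError("marker roster does not match coords")
        finite = self.coords[~np.isnan(self.coords)]
        if finite.size and not np.all(np.isfinite(finite)):
            raise ConfigError("coordinates must be finite where present")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def index(self, name: str) -> int:
        try:
            return self.markers.index(name)
        except ValueError:
            raise KeyError(f"unknown marker {name!r}") from None

    def get(self, name: str) -> np.ndarray:
        """(frames, 3) trajectory of one marker."""
        return self.coords[:, self.index(name), :]

    def present(self, name: str) -> np.ndarray:
        """Boolean per-frame mask: marker tracked in that frame."""
        return np.all(np.isfinite(self.get(name)), axis=1)


@dataclass
class RigidBodyDefinition:
    """Marker-to-bone assignment with reference (CT-pose) local coordinates.

    ``virtual_points`` are extra correspondences (name, local 3-vector,
    weight) whose observed world trajectories must be present in the marker
    set under the same name (e.g. landmarks animated on another bone).
    """

    name: str
    marker_names: list[str]
    reference: np.ndarray  # (n_markers, 3) local coords, cm
    virtual_points: list[tuple[str, np.ndarray, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.reference = np.atleast_2d(np.asarray(self.reference, dtype=float))
        if self.reference.shape != (len(self.marker_names), 3):
            raise ConfigError(f"body {self.name}: reference must be (n_markers, 3)")
        pts = self.all_reference()
        if len(pts) < 3 or _is_collinear(pts):
            raise DegenerateFitError(
                f"body {self.name}: needs >=3 non-collinear reference points"
            )

    def all_names(self) -> list[str]:
        return self.marker_names + [n for n, _, _ in self.virtual_points]

    def all_reference(self) -> np.ndarray:
        vp = [np.asarray(p, dtype=float) for _, p, _ in self.virtual_points]
        return np.vstack([self.reference] + vp) if vp else self.reference

    def all_weights(self) -> np.ndarray:
        return np.array(
            [1.0] * len(self.marker_names) + [w for _, _, w in self.virtual_points]
        )


@dataclass
class PoseSeries:
    """Per-frame rigid transforms for one body (bone-local -> world)."""

    body: str
    transforms: np.ndarray  # (frames, 4, 4)
    residual: np.ndarray  # (frames,) fit RMSD, cm
    valid: np.ndarray  # (frames,) bool
    fps: float

    def __post_init__(self) -> None:
        self.transforms = np.asarray(self.transforms, dtype=float)
        self.residual = np.asarray(self.residual, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        for f in np.nonzero(self.valid)[0]:
            if not is_rotation(self.transforms[f, :3, :3]):
                raise ConfigError(
                    f"body {self.body}: frame {f} rotation not orthonormal"
                )
        if np.any(self.residual[self.valid] < 0):
            raise ConfigError("residuals must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.transforms.shape[0]


@dataclass
class PrecisionReport:
    """Tracking precision from intra-body pairwise marker distances."""

    pair_std: dict[str, dict[tuple[str, str], float]]  # body -> pair -> std (cm)
    body_mean: dict[str, float]  # mean of pair stds per body
    mean: float  # grand mean across bodies (cm)
    max: float  # worst pair (cm)
    jcs_dof_std: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"body": b, "pair": f"{m1}-{m2}", "distance_std_cm": s}
            for b, pairs in self.pair_std.items()
            for (m1, m2), s in pairs.items()
        ]
        return pd.DataFrame(rows)

    def __str__(self) -> str:  # human-readable summary
        lines = [f"marker precision: mean {self.mean:.4f} cm, max {self.max:.4f} cm"]
        for b, m in self.body_mean.items():
            lines.append(f"  {b}: {m:.4f} cm")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Points CSV dialect (one name_X,name_Y,name_Z triple per marker)


def read_points_csv(path: str | Path, fps: float = 500.0) -> MarkerTrajectorySet:
    """Read a marker-coordinate table (XMALab-export-style dialect).

    Header must consist of ``name_X,name_Y,name_Z`` column triples; blank
    fields or NaN tokens mark untracked marker-frames.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: ragged rows ({exc})") from exc
    cols = list(df.columns)
    if len(cols) % 3 != 0:
        raise FormatError(f"{path}: column count {len(cols)} is not a multiple of 3")
    markers: list[str] = []
    for i in range(0, len(cols), 3):
        triple = cols[i : i + 3]
        suffixes = [c.rsplit("_", 1)[-1] for c in triple]
        names = {c.rsplit("_", 1)[0] for c in triple}
        if suffixes != ["X", "Y", "Z"] or len(names) != 1:
            raise FormatError(
                f"{path}: columns {triple} do not form a name_X,name_Y,name_Z triple"
            )
        markers.append(triple[0].rsplit("_", 1)[0])
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric body: {exc}") from exc
    coords = values.reshape(len(df), len(markers), 3)
    return MarkerTrajectorySet(fps=fps, markers=markers, coords=coords)


def write_points_csv(mset: MarkerTrajectorySet, path: str | Path) -> None:
    """Write the points-CSV dialect (lossless round-trip with read)."""
    cols: dict[str, np.ndarray] = {}
    for j, name in enumerate(mset.markers):
        for k, ax in enumerate("XYZ"):
            cols[f"{name}_{ax}"] = mset.coords[:, j, k]
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.10g")


def write_transforms_csv(pose: PoseSeries, path: str | Path) -> None:
    """16-column row-major transform table in the row-vector dialect.

    The stored matrix M satisfies ``world_row = [local, 1] @ M`` (translation
    in the fourth row), matching common animation-package exports.  Invalid
    frames are written as NaN rows.
    """
    rows = np.full((pose.n_frames, 16), np.nan)
    for f in range(pose.n_frames):
        if pose.valid[f]:
            rows[f] = pose.transforms[f].T.reshape(16)
    cols = {f"{pose.body}_{i}{j}": rows[:, 4 * i + j] for i in range(4) for j in range(4)}
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.12g")


def read_transforms_csv(
    path: str | Path, fps: float, row_vector: bool = True
) -> PoseSeries:
    """Read a transform table written by :func:`write_transforms_csv`.

    Set ``row_vector=False`` for tables stored in the column-vector
    convention (no transpose applied).
    """
    df = pd.read_csv(path)
    if df.shape[1] != 16:
        raise FormatError(f"{path}: expected 16 columns, got {df.shape[1]}")
    body = df.columns[0].rsplit("_", 1)[0]
    raw = df.to_numpy(dtype=float).reshape(-1, 4, 4)
    valid = np.all(np.isfinite(raw), axis=(1, 2))
    transforms = np.where(valid[:, None, None], raw, np.eye(4))
    if row_vector:
        transforms = np.transpose(transforms, (0, 2, 1))
    residual = np.zeros(len(raw))
    return PoseSeries(body=body, transforms=transforms, residual=residual,
                      valid=valid, fps=fps)


# ---------------------------------------------------------------------------
# Rigid fitting


def _is_collinear(points: np.ndarray, tol: float = _COLLINEAR_TOL) -> bool:
    centered = points - points.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    scale = max(s[0], 1.0)
    return s[1] / scale < tol


def estimate_rigid_transform(
    reference: np.ndarray,
    observed: np.ndarray,
    weights: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Weighted least-squares proper rigid transform (Kabsch/Umeyama).

    Finds the rotation+translation minimizing the weighted sum of squared
    distances ``sum w_i |R p_i + t - q_i|^2``; reflections are never
    returned.  Returns the 4x4 transform and the weighted residual RMSD.
    """
    P = np.atleast_2d(np.asarray(reference, dtype=float))
    Q = np.atleast_2d(np.asarray(observed, dtype=float))
    if P.shape != Q.shape or P.shape[0] < 3:
        raise DegenerateFitError("need >=3 corresponded points")
    if weights is None:
        w = np.ones(len(P))
    else:
        w = np.asarray(weights, dtype=float)
        if np.any(w < 0) or w.sum() <= 0:
            raise ConfigError("weights must be non-negative with positive sum")
    if _is_collinear(P) or _is_collinear(Q):
        raise DegenerateFitError("points are collinear; rigid fit ill-posed")
    wn = w / w.sum()
    cp = wn @ P
    cq = wn @ Q
    H = (P - cp).T @ ((Q - cq) * wn[:, None])
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = cq - R @ cp
    T = hom(R, t)
    resid = float(np.sqrt(wn @ np.sum((apply_hom(T, P) - Q) ** 2, axis=1)))
    return T, resid


def animate_body(
    defn: RigidBodyDefinition, mset: MarkerTrajectorySet
) -> PoseSeries:
    """Per-frame rigid fit of a body to its visible markers.

    Frames with fewer than 3 visible (non-collinear) correspondences are
    flagged invalid — never interpolated.  Virtual-constraint points are
    included at their configured weights.
    """
    names = defn.all_names()
    missing = [n for n in names if n not in mset.markers]
    if missing:
        raise KeyError(f"body {defn.name}: markers {missing} absent from set")
    ref = defn.all_reference()
    wts = defn.all_weights()
    obs = np.stack([mset.get(n) for n in names], axis=1)  # (F, n, 3)
    F = mset.n_frames
    transforms = np.tile(np.eye(4), (F, 1, 1))
    residual = np.full(F, np.nan)
    valid = np.zeros(F, dtype=bool)
    for f in range(F):
        mask = np.all(np.isfinite(obs[f]), axis=1)
        if mask.sum() < 3 or _is_collinear(ref[mask]):
            continue
        T, r = estimate_rigid_transform(ref[mask], obs[f, mask], wts[mask])
        transforms[f] = T
        residual[f] = r
        valid[f] = True
    if not valid.any():
        raise UnusableBodyError(
            f"body {defn.name}: no frame has 3 visible non-collinear markers"
        )
    return PoseSeries(body=defn.name, transforms=transforms, residual=residual,
                      valid=valid, fps=mset.fps)


def fit_body_plane(
    mset: MarkerTrajectorySet,
    marker_names: Sequence[str],
    name: str = "body_plane",
    reference: np.ndarray | None = None,
) -> PoseSeries:
    """Rigid fit of the pseudo-rigid body plane to superficial body markers.

    No deformation correction is applied; the per-frame residual RMSD is the
    deformation indicator.  If ``reference`` is omitted, the configuration at
    the first fully tracked frame is used as the reference shape.
    """
    if len(marker_names) < 3:
        raise DegenerateFitError("body plane needs >=3 markers")
    if reference is None:
        obs = np.stack([mset.get(n) for n in marker_names], axis=1)
        ok = np.all(np.isfinite(obs), axis=(1, 2))
        if not ok.any():
            raise UnusableBodyError("no frame with all body-plane markers tracked")
        reference = obs[int(np.argmax(ok))]
    defn = RigidBodyDefinition(
        name=name, marker_names=list(marker_names), reference=reference
    )
    return animate_body(defn, mset)


# ---------------------------------------------------------------------------
# Filtering and smoothing


def lowpass_filter(
    series: np.ndarray, cutoff_hz: float, fps: float, order: int = 4
) -> np.ndarray:
    """Zero-phase Butterworth low-pass along axis 0.

    Forward-backward application (``filtfilt`` with reflective odd padding)
    doubles the effective order and cancels phase lag; the default 4th-order
    design is the common biomechanics choice.
    """
    if cutoff_hz >= fps / 2.0:
        raise ConfigError(f"cutoff {cutoff_hz} Hz >= Nyquist {fps / 2.0} Hz")
    if cutoff_hz <= 0:
        raise ConfigError("cutoff must be positive")
    x = np.asarray(series, dtype=float)
    shape = x.shape
    flat = x.reshape(shape[0], -1)
    b, a = signal.butter(order, cutoff_hz / (fps / 2.0), btype="low")
    padlen = 3 * max(len(a), len(b))
    if shape[0] <= padlen:
        raise ConfigError(f"series length {shape[0]} too short for padding {padlen}")
    out = signal.filtfilt(b, a, flat, axis=0, padlen=padlen)
    return out.reshape(shape)


def filter_markers(
    mset: MarkerTrajectorySet, cutoff_hz: float, order: int = 4
) -> MarkerTrajectorySet:
    """Low-pass every fully tracked marker trajectory; gappy markers pass through."""
    coords = mset.coords.copy()
    for j in range(len(mset.markers)):
        traj = coords[:, j, :]
        if np.all(np.isfinite(traj)):
            coords[:, j, :] = lowpass_filter(traj, cutoff_hz, mset.fps, order)
    return MarkerTrajectorySet(fps=mset.fps, markers=list(mset.markers), coords=coords)


def smooth_trajectory_poly(
    traj: np.ndarray, window: int, order: int
) -> np.ndarray:
    """Sliding-window least-squares polynomial smoother.

    Evaluates the windowed polynomial fit at the window centre; endpoints
    use shrunken one-sided windows.  ``window=1`` is the identity.
    """
    if window < 1 or window % 2 == 0:
        raise ConfigError("window must be odd and >=1")
    if order >= window:
        raise ConfigError("order must be < window")
    x = np.asarray(traj, dtype=float)
    F = x.shape[0]
    if window == 1:
        return x.copy()
    flat = x.reshape(F, -1)
    out = np.empty_like(flat)
    half = window // 2
    for i in range(F):
        lo, hi = max(0, i - half), min(F, i + half + 1)
        deg = min(order, hi - lo - 1)
        ts = np.arange(lo, hi, dtype=float) - i
        coeffs = np.polynomial.polynomial.polyfit(ts, flat[lo:hi], deg)
        out[i] = coeffs[0]
    return out.reshape(x.shape)


# ---------------------------------------------------------------------------
# Precision


def marker_precision(
    mset: MarkerTrajectorySet, bodies: Mapping[str, Iterable[str]]
) -> PrecisionReport:
    """Std over frames of every unfiltered intra-body pairwise marker distance.

    The grand ``mean`` is the mean of per-body means (matching the usual
    XROMM precision statistic); bodies with <2 markers are skipped with a
    warning.
    """
    pair_std: dict[str, dict[tuple[str, str], float]] = {}
    body_mean: dict[str, float] = {}
    for body, names in bodies.items():
        names = list(names)
        if len(names) < 2:
            warnings.warn(f"body {body}: fewer than 2 markers, skipped")
            continue
        stds: dict[tuple[str, str], float] = {}
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                a, b = mset.get(names[i]), mset.get(names[j])
                ok = np.all(np.isfinite(a), axis=1) & np.all(np.isfinite(b), axis=1)
                if ok.sum() < 2:
                    continue
                d = np.linalg.norm(a[ok] - b[ok], axis=1)
                stds[(names[i], names[j])] = float(np.std(d, ddof=1))
        if stds:
            pair_std[body] = stds
            body_mean[body] = float(np.mean(list(stds.values())))
    if not body_mean:
        raise ConfigError("no body with >=2 tracked markers")
    all_stds = [s for pairs in pair_std.values() for s in pairs.values()]
    return PrecisionReport(
        pair_std=pair_std,
        body_mean=body_mean,
        mean=float(np.mean(list(body_mean.values()))),
        max=float(np.max(all_stds)),
    )


def jcs_precision(jcs, proximal: PoseSeries, distal: PoseSeries) -> dict[str, float]:
    """Per-DOF standard deviations of a JCS on a motion-free recording.

    For a frozen specimen the joint should be still, so the six standard
    deviations (rz/ry/rx deg, tx/ty/tz cm) are the precision threshold of
    the whole pipeline.
    """
    from .jcs_kinematics import jcs_angles  # local import avoids a cycle

    kin = jcs_angles(jcs, proximal, distal)
    ok = kin.valid
    if ok.sum() < 2:
        raise ConfigError("need >=2 valid frames for a precision estimate")
    return {
        ch: float(np.std(getattr(kin, ch)[ok], ddof=1))
        for ch in ("rz", "ry", "rx", "tx", "ty", "tz")
    }
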