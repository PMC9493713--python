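"""Dynamic digital endocast: alpha-shape volume of bone-attached locators.

Locators ride on the oral surfaces of the right anterior half of the
cavity; per frame they are mapped to world coordinates, an alpha shape is
computed over the constellation, and its volume doubled (bilateral factor)
to report the whole-cavity volume.

Alpha convention: ``alpha`` is the circumradius threshold in cm — a
Delaunay tetrahedron is kept iff its circumsphere radius is <= alpha.
``alpha = inf`` therefore reproduces the convex hull.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay, QhullError

from ._geometry import apply_hom
from .errors import ConfigError
from .rigid_body import PoseSeries


@dataclass
class EndocastDefinition:
    """Bone-attached locator cloud plus alpha-shape parameters."""

    locators: list[tuple[str, np.ndarray]]  # (body, local 3-vector cm)
    alpha: float = 2.0  # circumradius threshold, cm
    bilateral_factor: float = 2.0  # doubled unilateral volume
    largest_component_only: bool = False

    def __post_init__(self) -> None:
        self.locators = [
            (body, np.asarray(p, dtype=float)) for body, p in self.locators
        ]
        if len(self.locators) < 4:
            raise ConfigError("endocast needs >=4 locators")
        if self.alpha <= 0:
            raise ConfigError("alpha must be positive")

    def bodies(self) -> list[str]:
        return sorted({body for body, _ in self.locators})


@dataclass
class VolumeSeries:
    """Per-frame endocast volume and change from the first valid frame."""

    volume: np.ndarray  # cm^3, NaN where invalid
    dv: np.ndarray  # volume - volume[first valid frame]
    valid: np.ndarray
    fps: float

    @property
    def time_ms(self) -> np.ndarray:
        return np.arange(len(self.volume)) / self.fps * 1000.0


def _tet_volumes(points: np.ndarray, tets: np.ndarray) -> np.ndarray:
    a, b, c, d = (points[tets[:, k]] for k in range(4))
    return np.abs(np.einsum("ij,ij->i", np.cross(b - a, c - a), d - a)) / 6.0


def _circumradii(points: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Circumsphere radius per tetrahedron; inf for degenerate ones."""
    a = points[tets[:, 0]]  # (T, 3)
    M = 2.0 * (points[tets[:, 1:]] - a[:, None, :])  # (T, 3, 3)
    rhs = np.sum(points[tets[:, 1:]] ** 2, axis=2) - np.sum(a**2, axis=1)[:, None]
    radii = np.full(len(tets), np.inf)
    det = np.abs(np.linalg.det(M))
    scale = np.max(np.abs(M), axis=(1, 2)) ** 3 + 1e-300
    ok = det / scale > 1e-12
    if ok.any():
        centre = np.linalg.solve(M[ok], rhs[ok][..., None])[..., 0]
        radii[ok] = np.linalg.norm(centre - a[ok], axis=1)
    return radii


def _kept_tets(points: np.ndarray, alpha: float) -> tuple[np.ndarray, np.ndarray]:
    """Delaunay tetrahedra surviving the alpha criterion, with the point array."""
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 3:
        raise ConfigError("points must be (n, 3)")
    if len(points) < 4:
        raise ConfigError("alpha shape needs >=4 points")
    try:
        tri = Delaunay(points)
    except QhullError:
        warnings.warn("degenerate (coplanar) locator cloud; volume 0")
        return np.empty((0, 4), dtype=int), points
    tets = tri.simplices
    keep = _circumradii(points, tets) <= alpha
    return tets[keep], points


def _component_labels(tets: np.ndarray) -> np.ndarray:
    """Label kept tetrahedra by face-connected component (union-find)."""
    parent = np.arange(len(tets))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    faces: dict[tuple[int, int, int], int] = {}
    for i, tet in enumerate(tets):
        for f in range(4):
            face = tuple(sorted(np.delete(tet, f)))
            if face in faces:
                ri, rj = find(i), find(faces[face])
                parent[ri] = rj
            else:
                faces[face] = i
    return np.array([find(i) for i in range(len(tets))])


def alpha_shape_volume(
    points: np.ndarray, alpha: float, largest_component_only: bool = False
) -> float:
    """Volume (cm^3) of the alpha complex over a 3D point cloud.

    Keeps Delaunay tetrahedra with circumradius <= alpha and sums their
    volumes.  A degenerate (coplanar) cloud yields 0 with a warning; by
    default all connected components count toward the volume.
    """
    if alpha <= 0:
        raise ConfigError("alpha must be positive")
    tets, pts = _kept_tets(points, alpha)
    if len(tets) == 0:
        return 0.0
    vols = _tet_volumes(pts, tets)
    if largest_component_only and len(tets) > 1:
        labels = _component_labels(tets)
        best = max(set(labels), key=lambda l: vols[labels == l].sum())
        return float(vols[labels == best].sum())
    return float(vols.sum())


def alpha_shape_boundary(points: np.ndarray, alpha: float) -> np.ndarray:
    """Boundary triangles (index triples) of the alpha complex."""
    tets, _ = _kept_tets(points, alpha)
    counts: dict[tuple[int, int, int], int] = {}
    for tet in tets:
        for f in range(4):
            face = tuple(sorted(np.delete(tet, f)))
            counts[face] = counts.get(face, 0) + 1
    return np.array([f for f, c in counts.items() if c == 1], dtype=int).reshape(-1, 3)


def write_boundary_obj(points: np.ndarray, faces: np.ndarray, path) -> None:
    """Dump a boundary mesh as Wavefront OBJ for visual checking."""
    with open(path, "w") as fh:
        for p in np.asarray(points, dtype=float):
            fh.write(f"v {p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")
        for f in faces:
            fh.write(f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}\n")


def locator_cloud(
    defn: EndocastDefinition, poses: dict[str, PoseSeries], frame: int
) -> np.ndarray | None:
    """World locator constellation at one frame; None if any pose is invalid."""
    cloud = np.empty((len(defn.locators), 3))
    for i, (body, local) in enumerate(defn.locators):
        pose = poses.get(body)
        if pose is None or not pose.valid[frame]:
            return None
        cloud[i] = apply_hom(pose.transforms[frame], local)
    return cloud


def endocast_volumes(
    defn: EndocastDefinition, poses: dict[str, PoseSeries]
) -> VolumeSeries:
    """Per-frame alpha-shape volume times the bilateral factor, plus delta-V.

    Frames where any locator's body lacks a valid pose are flagged invalid.
    """
    frame_counts = {p.n_frames for p in poses.values()}
    fps_set = {p.fps for p in poses.values()}
    if len(frame_counts) != 1 or len(fps_set) != 1:
        raise ConfigError("pose series must agree in frame count and fps")
    F = frame_counts.pop()
    volume = np.full(F, np.nan)
    valid = np.zeros(F, dtype=bool)
    for f in range(F):
        cloud = locator_cloud(defn, poses, f)
        if cloud is None:
            continue
        volume[f] = defn.bilateral_factor * alpha_shape_volume(
            cloud, defn.alpha, defn.largest_component_only
        )
        valid[f] = True
    if not valid.any():
        raise ConfigError("no frame with valid poses for every locator body")
    first = int(np.argmax(valid))
    dv = volume - volume[first]
    return VolumeSeries(volume=volume, dv=dv, valid=valid, fps=fps_set.pop())
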