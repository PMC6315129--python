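"""Dense surface correspondence and cohort average mesh.

Correspondence from a base mesh to a subject is computed in two steps:
a landmark-interpolating thin-plate-spline (TPS) warp of the base vertices,
followed by exact closest-point projection onto the subject's triangle set.
Projection uses a KD-tree over triangle centroids to prune candidates and a
conservative radius fallback, so the result equals an all-triangle scan.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .mesh_core import LandmarkSet, SurfaceMesh

__all__ = [
    "ThinPlateSpline",
    "Correspondence",
    "AverageMesh",
    "tps_warp",
    "project_to_surface",
    "dense_correspondence",
    "compute_average_mesh",
    "closest_point_triangles",
]


# ---------------------------------------------------------------------------
# Thin-plate spline (3D, kernel U(r) = r)
# ---------------------------------------------------------------------------

class ThinPlateSpline:
    """Landmark-interpolating 3D thin-plate-spline warp.

    Solves for the minimal-bending-energy deformation carrying each source
    landmark to its target. With regularization ``lam = 0`` the warp
    interpolates targets exactly and reproduces affine maps; ``lam > 0``
    trades interpolation accuracy for smoothness (useful for noisy landmarks).
    """

    def __init__(self, source: np.ndarray, target: np.ndarray, lam: float = 0.0):
        source = np.asarray(source, dtype=np.float64)
        target = np.asarray(target, dtype=np.float64)
        n = len(source)
        if n < 4:
            raise ValueError("3D TPS needs >= 4 landmarks")
        d = cKDTree(source).query_pairs(1e-9)
        if d:
            raise ValueError(f"coincident source landmarks (pairs {sorted(d)[:3]}): TPS system is singular")
        centered = source - source.mean(axis=0)
        if np.linalg.matrix_rank(centered, tol=1e-8 * max(1.0, np.abs(centered).max())) < 3:
            raise ValueError("source landmarks are coplanar; 3D TPS warp is underdetermined")
        K = np.linalg.norm(source[:, None] - source[None, :], axis=-1)  # U(r) = r
        K[np.diag_indices(n)] += lam
        P = np.hstack([np.ones((n, 1)), source])
        A = np.zeros((n + 4, n + 4))
        A[:n, :n] = K
        A[:n, n:] = P
        A[n:, :n] = P.T
        b = np.zeros((n + 4, 3))
        b[:n] = target
        try:
            coef = np.linalg.solve(A, b)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded above
            raise ValueError("singular TPS system (degenerate landmark configuration)") from exc
        self.source = source
        self.weights = coef[:n]
        self.affine = coef[n:]

    def __call__(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, dtype=np.float64))
        U = np.linalg.norm(points[:, None] - self.source[None, :], axis=-1)
        return U @ self.weights + self.affine[0] + points @ self.affine[1:]


def tps_warp(source_landmarks: LandmarkSet, target_landmarks: LandmarkSet,
             points: np.ndarray, lam: float = 0.0) -> np.ndarray:
    """Warp ``points`` by the TPS carrying source landmarks onto targets.

    Landmarks are matched by name; both sets must share the same names.
    """
    common = sorted(set(source_landmarks.points) & set(target_landmarks.points))
    if len(common) < 4:
        raise ValueError(f"TPS warp needs >= 4 shared landmarks, got {len(common)}")
    spline = ThinPlateSpline(source_landmarks.array(common), target_landmarks.array(common), lam)
    return spline(points)


# ---------------------------------------------------------------------------
# Exact point -> triangle-set projection
# ---------------------------------------------------------------------------

def _closest_on_triangles(points: np.ndarray, tri: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Closest point on triangle i from point i, vectorized (Ericson's method).

    Parameters are matched pairs: ``points`` (n, 3) and ``tri`` (n, 3, 3).
    Returns (closest points (n, 3), barycentric coordinates (n, 3)).
    """
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab, ac, ap = b - a, c - a, points - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = points - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = points - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    bary = np.zeros_like(points)
    done = np.zeros(len(points), dtype=bool)

    def settle(mask, u, v, w):
        m = mask & ~done
        bary[m, 0], bary[m, 1], bary[m, 2] = u[m] if np.ndim(u) else u, \
            v[m] if np.ndim(v) else v, w[m] if np.ndim(w) else w
        done[m] = True

    # vertex regions
    settle((d1 <= 0) & (d2 <= 0), 1.0, 0.0, 0.0)
    settle((d3 >= 0) & (d4 <= d3), 0.0, 1.0, 0.0)
    settle((d6 >= 0) & (d5 <= d6), 0.0, 0.0, 1.0)
    # edge AB
    vc = d1 * d4 - d3 * d2
    with np.errstate(divide="ignore", invalid="ignore"):
        t_ab = d1 / (d1 - d3)
    m = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    settle(m, 1.0 - np.nan_to_num(t_ab), np.nan_to_num(t_ab), 0.0)
    # edge AC
    vb = d5 * d2 - d1 * d6
    with np.errstate(divide="ignore", invalid="ignore"):
        t_ac = d2 / (d2 - d6)
    m = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    settle(m, 1.0 - np.nan_to_num(t_ac), 0.0, np.nan_to_num(t_ac))
    # edge BC
    va = d3 * d6 - d5 * d4
    with np.errstate(divide="ignore", invalid="ignore"):
        t_bc = (d4 - d3) / ((d4 - d3) + (d5 - d6))
    m = (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    settle(m, 0.0, 1.0 - np.nan_to_num(t_bc), np.nan_to_num(t_bc))
    # interior
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = va + vb + vc
        v = vb / denom
        w = vc / denom
    settle(np.ones(len(points), dtype=bool), 1.0 - np.nan_to_num(v) - np.nan_to_num(w),
           np.nan_to_num(v), np.nan_to_num(w))

    closest = bary[:, 0, None] * a + bary[:, 1, None] * b + bary[:, 2, None] * c
    return closest, bary


def closest_point_triangles(points: np.ndarray, points_tri: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Public matched-pair point/triangle projection (see :func:`_closest_on_triangles`)."""
    return _closest_on_triangles(np.asarray(points, float), np.asarray(points_tri, float))


def _project_exact(points: np.ndarray, mesh: SurfaceMesh, k: int = 32
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exact nearest point on the triangle set for every query point.

    KD-tree over triangle centroids proposes the ``k`` nearest candidate
    triangles; any triangle whose centroid lies within the current best
    distance plus the largest centroid-to-vertex radius could still win, so
    those points get a second, radius-based candidate pass. The result is
    identical to a brute-force all-triangle scan.
    """
    tri = mesh.vertices[mesh.faces]
    centroids = tri.mean(axis=1)
    radii = np.linalg.norm(tri - centroids[:, None, :], axis=-1).max(axis=1)
    r_max = float(radii.max())
    tree = cKDTree(centroids)
    k = min(k, mesh.n_faces)
    cdist, cand = tree.query(points, k=k)
    if k == 1:
        cdist, cand = cdist[:, None], cand[:, None]

    n = len(points)
    flat_pts = np.repeat(points, k, axis=0)
    close, bary = _closest_on_triangles(flat_pts, tri[cand.ravel()])
    dist = np.linalg.norm(close - flat_pts, axis=1).reshape(n, k)
    best = dist.argmin(axis=1)
    rows = np.arange(n)
    best_dist = dist[rows, best]
    best_face = cand[rows, best]
    best_close = close.reshape(n, k, 3)[rows, best]
    best_bary = bary.reshape(n, k, 3)[rows, best]

    # Points whose kth centroid distance does not dominate best + r_max may
    # have an unexplored winning triangle; re-check them exhaustively within
    # the safe radius.
    if k < mesh.n_faces:
        unsafe = np.flatnonzero(cdist[:, -1] < best_dist + r_max)
        for i in unsafe:
            extra = tree.query_ball_point(points[i], best_dist[i] + r_max + 1e-12)
            extra = np.asarray(extra, dtype=np.int64)
            if len(extra) == 0:
                continue
            cl, ba = _closest_on_triangles(np.repeat(points[None, i], len(extra), axis=0), tri[extra])
            dd = np.linalg.norm(cl - points[i], axis=1)
            j = dd.argmin()
            if dd[j] < best_dist[i]:
                best_dist[i] = dd[j]
                best_face[i] = extra[j]
                best_close[i] = cl[j]
                best_bary[i] = ba[j]
    return best_face, best_bary, best_close


# ---------------------------------------------------------------------------
# Correspondence containers and operations
# ---------------------------------------------------------------------------

@dataclass
class Correspondence:
    """Mapping of each base-mesh point onto a subject surface.

    ``positions[i]`` lies on subject face ``face_index[i]`` at barycentric
    coordinates ``barycentric[i]`` (non-negative, summing to 1).
    """

    face_index: np.ndarray
    barycentric: np.ndarray
    positions: np.ndarray

    def __post_init__(self) -> None:
        self.face_index = np.asarray(self.face_index, dtype=np.int64)
        self.barycentric = np.asarray(self.barycentric, dtype=np.float64)
        self.positions = np.asarray(self.positions, dtype=np.float64)
        if not (len(self.face_index) == len(self.barycentric) == len(self.positions)):
            raise ValueError("correspondence arrays must have equal length")
        if np.any(self.barycentric < -1e-9) or np.any(np.abs(self.barycentric.sum(axis=1) - 1) > 1e-9):
            raise ValueError("barycentric coordinates must be non-negative and sum to 1")

    @property
    def base_point_count(self) -> int:
        return len(self.face_index)

    def interpolate(self, mesh: SurfaceMesh, vertex_values: np.ndarray) -> np.ndarray:
        """Barycentric interpolation of a per-vertex attribute at the targets."""
        vals = np.asarray(vertex_values)
        corner = vals[mesh.faces[self.face_index]]  # (n, 3) or (n, 3, d)
        if corner.ndim == 2:
            return np.einsum("nk,nk->n", corner, self.barycentric)
        return np.einsum("nkd,nk->nd", corner, self.barycentric)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "base_index": np.arange(self.base_point_count),
            "face_index": self.face_index,
            "b0": self.barycentric[:, 0], "b1": self.barycentric[:, 1], "b2": self.barycentric[:, 2],
            "x": self.positions[:, 0], "y": self.positions[:, 1], "z": self.positions[:, 2],
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class AverageMesh:
    """Cohort average surface: per-point mean of corresponding positions."""

    mesh: SurfaceMesh
    provenance: list[str] = field(default_factory=list)


def project_to_surface(points: np.ndarray, mesh: SurfaceMesh) -> Correspondence:
    """Exact closest-point projection of ``points`` onto the triangle set."""
    if mesh.n_faces == 0:
        raise ValueError("cannot project onto an empty mesh")
    points = np.atleast_2d(np.asarray(points, dtype=np.float64))
    face, bary, close = _project_exact(points, mesh)
    return Correspondence(face, np.clip(bary, 0.0, 1.0), close)


def dense_correspondence(base_mesh: SurfaceMesh, base_landmarks: LandmarkSet,
                         subject_mesh: SurfaceMesh, subject_landmarks: LandmarkSet,
                         lam: float = 0.0, refine: int = 0) -> Correspondence:
    """Dense base -> subject correspondence: TPS warp then surface projection.

    ``refine`` extra passes Laplacian-smooth the mapped positions toward
    their one-ring average (factor 0.5) and re-project; off by default for
    determinism.
    """
    warped = tps_warp(base_landmarks, subject_landmarks, base_mesh.vertices, lam=lam)
    corr = project_to_surface(warped, subject_mesh)
    for _ in range(refine):
        edges = base_mesh.edges()
        acc = np.zeros_like(corr.positions)
        deg = np.zeros(base_mesh.n_vertices)
        for i, j in ((0, 1), (1, 0)):
            np.add.at(acc, edges[:, i], corr.positions[edges[:, j]])
            np.add.at(deg, edges[:, i], 1.0)
        smoothed = corr.positions.copy()
        ok = deg > 0
        smoothed[ok] = 0.5 * corr.positions[ok] + 0.5 * acc[ok] / deg[ok, None]
        corr = project_to_surface(smoothed, subject_mesh)
    return corr


def compute_average_mesh(base_mesh: SurfaceMesh, correspondences: list[Correspondence],
                         subject_ids: list[str] | None = None) -> AverageMesh:
    """Vertex-wise arithmetic mean of corresponding positions; base faces inherited."""
    if len(correspondences) < 2:
        raise ValueError("average mesh needs >= 2 correspondences")
    counts = {c.base_point_count for c in correspondences}
    if counts != {base_mesh.n_vertices}:
        raise ValueError(f"correspondence point counts {counts} do not match base mesh "
                         f"({base_mesh.n_vertices} vertices)")
    mean = np.mean([c.positions for c in correspondences], axis=0)
    ids = subject_ids if subject_ids is not None else [str(i) for i in range(len(correspondences))]
    return AverageMesh(SurfaceMesh(mean, base_mesh.faces.copy()), list(ids))
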