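"""Surface-mesh and landmark data model, I/O, rigid alignment, mirroring, crop.

Conventions
-----------
All coordinates are in millimetres. In the aligned frame the midsagittal
plane is ``x = 0``, ``+x`` points to the subject's anatomical left, ``+y``
is superior and ``+z`` anterior. Bilateral landmark names carry ``_l``/``_r``
suffixes in the default schema; the pairing table makes the convention
explicit and user-overridable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

__all__ = [
    "SurfaceMesh",
    "LandmarkSet",
    "AlignmentFrame",
    "CropResult",
    "read_mesh",
    "write_mesh",
    "read_landmarks",
    "write_landmarks",
    "default_landmark_schema",
    "landmark_rigid_align",
    "mirror_mesh",
    "crop_below_eyes",
    "vertex_normals",
]


# ---------------------------------------------------------------------------
# Data model
# ---------------------------------------------------------------------------

@dataclass
class SurfaceMesh:
    """A triangulated 2-manifold surface.

    Parameters
    ----------
    vertices : (n, 3) float array, mm
    faces : (m, 3) int array of vertex indices, consistently wound so that
        face normals point outward.
    """

    vertices: np.ndarray
    faces: np.ndarray
    _normals: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be an (n, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError(f"faces must be (m, 3) triangles, got shape {self.faces.shape}")
        if len(self.faces) and (self.faces.min() < 0 or self.faces.max() >= len(self.vertices)):
            raise ValueError("face indices out of range")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def normals(self) -> np.ndarray:
        """Per-vertex outward unit normals (area-weighted face-normal average)."""
        if self._normals is None:
            self._normals = vertex_normals(self)
        return self._normals

    def edges(self) -> np.ndarray:
        """Unique undirected edges as an (e, 2) sorted-index array."""
        e = np.concatenate([self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]])
        return np.unique(np.sort(e, axis=1), axis=0)

    def validate_manifold(self) -> None:
        """Check the 2-manifold property: every edge is shared by at most 2 faces."""
        e = np.concatenate([self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]])
        _, counts = np.unique(np.sort(e, axis=1), axis=0, return_counts=True)
        if counts.max(initial=0) > 2:
            raise ValueError("mesh is not 2-manifold: an edge is shared by more than 2 faces")

    def copy(self) -> "SurfaceMesh":
        return SurfaceMesh(self.vertices.copy(), self.faces.copy())

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "SurfaceMesh":
        """Apply a rigid motion ``x -> R x + t``."""
        return SurfaceMesh(self.vertices @ np.asarray(rotation).T + np.asarray(translation), self.faces.copy())


@dataclass
class LandmarkSet:
    """Named 3D landmarks with bilateral pairing and midline annotation.

    ``pairs`` lists ``(left_name, right_name)`` tuples; ``midline`` lists the
    unpaired on-axis landmarks. Names in the two groups must be disjoint and
    all present in ``points``.
    """

    points: dict[str, np.ndarray]
    pairs: list[tuple[str, str]] = field(default_factory=list)
    midline: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.points = {k: np.asarray(v, dtype=np.float64).reshape(3) for k, v in self.points.items()}
        paired = [n for pair in self.pairs for n in pair]
        if len(set(paired)) != len(paired):
            raise ValueError("duplicate names in pairing table")
        if set(paired) & set(self.midline):
            raise ValueError("pairing table and midline lists must be disjoint")
        missing = (set(paired) | set(self.midline)) - set(self.points)
        if missing:
            raise ValueError(f"landmarks referenced but absent from points: {sorted(missing)}")

    @property
    def names(self) -> list[str]:
        return list(self.points)

    def array(self, names: list[str] | None = None) -> np.ndarray:
        """Stack landmark coordinates in the given (default: sorted) name order."""
        names = sorted(self.points) if names is None else names
        return np.array([self.points[n] for n in names])

    def paired_names(self) -> list[str]:
        return [n for pair in self.pairs for n in pair]

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "LandmarkSet":
        R, t = np.asarray(rotation), np.asarray(translation)
        return LandmarkSet({k: R @ v + t for k, v in self.points.items()},
                           list(self.pairs), list(self.midline))

    def mirrored(self) -> "LandmarkSet":
        """Reflect across x = 0 and relabel left <-> right per the pairing table."""
        swap = {}
        for left, right in self.pairs:
            swap[left], swap[right] = right, left
        pts = {}
        for name, p in self.points.items():
            q = p.copy()
            q[0] = -q[0]
            pts[swap.get(name, name)] = q
        return LandmarkSet(pts, list(self.pairs), list(self.midline))


@dataclass
class AlignmentFrame:
    """A rigid motion ``x -> R x + t`` mapping a subject into the reference frame."""

    rotation: np.ndarray
    translation: np.ndarray
    residual: float = 0.0  # RMS landmark distance after alignment, mm

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=np.float64)
        if R.shape != (3, 3) or not np.allclose(R @ R.T, np.eye(3), atol=1e-9) \
                or not np.isclose(np.linalg.det(R), 1.0, atol=1e-9):
            raise ValueError("rotation must be orthonormal with determinant +1")
        self.rotation = R
        self.translation = np.asarray(self.translation, dtype=np.float64).reshape(3)

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.rotation.T + self.translation

    def inverse(self) -> "AlignmentFrame":
        return AlignmentFrame(self.rotation.T, -self.rotation.T @ self.translation, self.residual)

    def compose(self, other: "AlignmentFrame") -> "AlignmentFrame":
        """Frame applying ``other`` first, then ``self``."""
        return AlignmentFrame(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)


@dataclass
class CropResult:
    """A cropped mesh together with the old -> new vertex-index bookkeeping."""

    mesh: SurfaceMesh
    kept: np.ndarray        # old indices of retained vertices, ascending
    index_map: np.ndarray   # old -> new index, -1 where dropped


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _check_triangular(path: Path) -> None:
    """Reject OBJ/PLY files containing non-triangular faces before loading.

    trimesh silently triangulates n-gons; the pipeline's face-index
    bookkeeping requires the file's own faces to be triangles.
    """
    suffix = path.suffix.lower()
    text = path.read_text(errors="replace")
    if suffix == ".obj":
        for line in text.splitlines():
            if line.startswith("f ") and len(line.split()) - 1 != 3:
                raise ValueError(f"{path}: non-triangular face in OBJ ('{line.strip()}')")
    elif suffix == ".ply":
        lines = text.splitlines()
        if not lines or lines[0].strip() != "ply":
            raise ValueError(f"{path}: not an ASCII PLY file")
        n_vertex = n_face = 0
        i = 0
        current = None
        for i, line in enumerate(lines):
            tok = line.split()
            if tok[:2] == ["element", "vertex"]:
                current, n_vertex = "vertex", int(tok[2])
            elif tok[:2] == ["element", "face"]:
                current, n_face = "face", int(tok[2])
            elif tok[:1] == ["format"] and tok[1] != "ascii":
                raise ValueError(f"{path}: only ASCII PLY is supported")
            elif tok[:1] == ["end_header"]:
                break
        face_lines = lines[i + 1 + n_vertex: i + 1 + n_vertex + n_face]
        for line in face_lines:
            tok = line.split()
            if tok and int(tok[0]) != 3:
                raise ValueError(f"{path}: non-triangular face in PLY (count {tok[0]})")


def read_mesh(path: str | Path) -> SurfaceMesh:
    """Read a triangulated mesh from an ASCII OBJ or PLY file."""
    path = Path(path)
    if path.suffix.lower() not in (".obj", ".ply"):
        raise ValueError(f"unsupported mesh format: {path.suffix} (expected .obj or .ply)")
    if not path.is_file():
        raise FileNotFoundError(path)
    _check_triangular(path)
    loaded = trimesh.load(path, process=False, force="mesh")
    return SurfaceMesh(np.asarray(loaded.vertices), np.asarray(loaded.faces))


def write_mesh(mesh: SurfaceMesh, path: str | Path) -> None:
    """Write a mesh as ASCII OBJ or PLY; round-trips vertices to < 1e-6 mm."""
    path = Path(path)
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    if path.suffix.lower() == ".ply":
        path.write_bytes(tm.export(file_type="ply", encoding="ascii"))
    elif path.suffix.lower() == ".obj":
        path.write_text(tm.export(file_type="obj"))
    else:
        raise ValueError(f"unsupported mesh format: {path.suffix} (expected .obj or .ply)")


def default_landmark_schema() -> tuple[list[tuple[str, str]], list[str]]:
    """The shipped 18-landmark pairing table: (pairs, midline) name lists."""
    with resources.files("faceasym.data").joinpath("landmarks18.json").open() as fh:
        schema = json.load(fh)
    return [tuple(p) for p in schema["pairs"]], list(schema["midline"])


def read_landmarks(path: str | Path,
                   pairs: list[tuple[str, str]] | None = None,
                   midline: list[str] | None = None) -> LandmarkSet:
    """Read landmarks from a CSV with columns name, x, y, z.

    Pairing defaults to the shipped 18-landmark schema restricted to the
    names present in the file.
    """
    df = pd.read_csv(path)
    required = {"name", "x", "y", "z"}
    if not required <= set(df.columns):
        raise ValueError(f"landmark CSV must have columns {sorted(required)}")
    points = {str(r["name"]): np.array([r.x, r.y, r.z]) for _, r in df.iterrows()}
    if pairs is None and midline is None:
        all_pairs, all_mid = default_landmark_schema()
        pairs = [p for p in all_pairs if p[0] in points and p[1] in points]
        midline = [n for n in all_mid if n in points]
    return LandmarkSet(points, pairs or [], midline or [])


def write_landmarks(landmarks: LandmarkSet, path: str | Path) -> None:
    rows = [{"name": n, "x": p[0], "y": p[1], "z": p[2]} for n, p in landmarks.points.items()]
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Rigid alignment (Kabsch / orthogonal Procrustes, no scaling)
# ---------------------------------------------------------------------------

def landmark_rigid_align(landmarks: LandmarkSet, reference: LandmarkSet) -> AlignmentFrame:
    """Least-squares rigid fit of ``landmarks`` onto ``reference``.

    Finds the rotation + translation minimizing the sum of squared distances
    between matched landmarks (no scaling: asymmetry magnitudes are physical
    millimetres and must be preserved). Landmarks are matched by name.
    """
    names = sorted(set(landmarks.points) & set(reference.points))
    if len(names) < 3:
        raise ValueError(f"rigid alignment needs >= 3 shared landmarks, got {len(names)}")
    X = landmarks.array(names)
    Y = reference.array(names)
    xc, yc = X.mean(axis=0), Y.mean(axis=0)
    X0, Y0 = X - xc, Y - yc
    if np.linalg.matrix_rank(X0, tol=1e-8 * max(1.0, np.abs(X0).max())) < 2:
        raise ValueError("landmark configuration is collinear; rotation is underdetermined")
    H = X0.T @ Y0
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = yc - R @ xc
    resid = float(np.sqrt(np.mean(np.sum((X @ R.T + t - Y) ** 2, axis=1))))
    return AlignmentFrame(R, t, resid)


# ---------------------------------------------------------------------------
# Mirroring and cropping
# ---------------------------------------------------------------------------

def mirror_mesh(mesh: SurfaceMesh, landmarks: LandmarkSet) -> tuple[SurfaceMesh, LandmarkSet]:
    """Reflect an aligned mesh across the midsagittal plane x = 0.

    Face winding is reversed so normals stay outward; landmark names are
    relabelled left <-> right per the pairing table. The operation is an
    exact involution: mirroring twice returns bit-identical data.
    """
    v = mesh.vertices.copy()
    v[:, 0] = -v[:, 0]
    return SurfaceMesh(v, mesh.faces[:, ::-1].copy()), landmarks.mirrored()


def crop_below_eyes(mesh: SurfaceMesh, landmarks: LandmarkSet,
                    eye_landmarks: tuple[str, str] = ("endocanthion_l", "endocanthion_r"),
                    min_vertices: int = 100) -> CropResult:
    """Restrict the mesh to the region below the eyes.

    Keeps vertices with ``y <= mean(y)`` of the two endocanthion landmarks;
    faces touching any removed vertex are dropped. Limits the scored region
    to the face area where the signal is reliable.
    """
    for name in eye_landmarks:
        if name not in landmarks.points:
            raise ValueError(f"crop requires landmark '{name}'")
    y_cut = float(np.mean([landmarks.points[n][1] for n in eye_landmarks]))
    keep_mask = mesh.vertices[:, 1] <= y_cut
    kept = np.flatnonzero(keep_mask)
    if len(kept) < min_vertices:
        raise ValueError(
            f"below-eyes crop leaves only {len(kept)} vertices (< {min_vertices}); "
            "degenerate face region")
    index_map = np.full(mesh.n_vertices, -1, dtype=np.int64)
    index_map[kept] = np.arange(len(kept))
    face_ok = keep_mask[mesh.faces].all(axis=1)
    new_faces = index_map[mesh.faces[face_ok]]
    return CropResult(SurfaceMesh(mesh.vertices[kept], new_faces), kept, index_map)


# ---------------------------------------------------------------------------
# Normals
# ---------------------------------------------------------------------------

def vertex_normals(mesh: SurfaceMesh) -> np.ndarray:
    """Area-weighted per-vertex unit normals.

    Each vertex normal is the normalized sum of the (un-normalized) cross
    products of its incident faces; the cross-product magnitude is twice the
    face area, so larger faces weigh more. Raises if a vertex has no
    incident face (its normal is undefined).
    """
    tri = mesh.vertices[mesh.faces]
    fn = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])  # 2 * area * n̂
    acc = np.zeros_like(mesh.vertices)
    for k in range(3):
        np.add.at(acc, mesh.faces[:, k], fn)
    norms = np.linalg.norm(acc, axis=1)
    if np.any(norms == 0.0):
        bad = np.flatnonzero(norms == 0.0)
        raise ValueError(f"vertex normal undefined (isolated vertex or degenerate star): indices {bad[:5]}")
    return acc / norms[:, None]
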