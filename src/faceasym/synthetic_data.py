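"""Synthetic face-like meshes and simulated cohorts with a planted genetic effect.

The template is a smooth, exactly mirror-symmetric height-field surface
(dome plus nasal ridge, lip and chin bumps) with the 18-landmark schema of
the package. Controlled asymmetries are injected as cosine-tapered
displacement fields on one side of the face; a cohort simulator couples the
injected amplitude to a planted causal SNP so that parameter-recovery of
the whole phenotyping + association pipeline can be tested against ground
truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import dijkstra

from .association import GenotypeMatrix, write_genotype_tsv
from .mesh_core import (LandmarkSet, SurfaceMesh, default_landmark_schema,
                        write_landmarks, write_mesh)

__all__ = [
    "AsymmetrySpec",
    "CohortConfig",
    "Cohort",
    "make_template",
    "inject_asymmetry",
    "simulate_cohort",
    "write_cohort",
]

# Regions echoing where normal-population asymmetry concentrates on real
# faces: nasal tip, nasal bridge, upper lip and chin.
DEFAULT_REGIONS = ("pronasale", "nasion", "labiale_superius", "pogonion")


@dataclass
class AsymmetrySpec:
    """One localized asymmetry: a smooth displacement on one side of the face.

    ``center`` names a landmark (bilateral names may omit the side suffix;
    the spec's ``side`` selects it); ``radius`` is the geodesic extent in mm;
    ``amplitude`` is mm for displacements and degrees for rotations.
    """

    center: str
    radius: float = 15.0
    kind: str = "normal_bump"  # normal_bump | tangential_shear | regional_rotation
    amplitude: float = 1.0
    side: str = "left"

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.radius <= 0:
            raise ValueError("region radius must be > 0")
        if self.kind not in ("normal_bump", "tangential_shear", "regional_rotation"):
            raise ValueError(f"unknown asymmetry kind '{self.kind}'")
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")


@dataclass
class CohortConfig:
    """Study conditions for a simulated cohort.

    Per subject the injected amplitude is ``max(0, N(amplitude_mean,
    amplitude_sd) + effect * g_causal)`` with the region and side drawn
    uniformly, so the cohort-average asymmetry map stays small the way it
    does in a normal population where asymmetry location varies.
    """

    n_subjects: int = 50
    seed: int = 0
    resolution: int = 40
    amplitude_mean: float = 1.5      # mm
    amplitude_sd: float = 0.75       # mm
    region_radius: float = 12.0      # mm
    regions: tuple[str, ...] = DEFAULT_REGIONS
    noise_sd: float = 0.02           # mm, iid vertex noise (residual scan roughness)
    rigid_jitter: bool = True        # random pose, removed by alignment
    n_snps: int = 0
    causal_index: int = 0
    effect: float = 0.0              # mm of amplitude per minor-allele copy
    causal_maf: float = 0.3
    maf_range: tuple[float, float] = (0.05, 0.5)
    age_range: tuple[float, float] = (3.0, 40.0)
    sex_ratio: float = 0.5
    make_meshes: bool = True

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_snps < 0:
            raise ValueError("counts must be positive")
        if self.seed is None:
            raise ValueError("a seed is mandatory for reproducibility")
        if self.n_snps and not (0 <= self.causal_index < self.n_snps):
            raise ValueError("causal_index out of range")


@dataclass
class Cohort:
    subject_ids: list[str]
    meshes: list[SurfaceMesh] | None
    landmarks: list[LandmarkSet] | None
    genotypes: GenotypeMatrix | None
    covariates: pd.DataFrame
    truth: pd.DataFrame
    template_mesh: SurfaceMesh | None = None
    template_landmarks: LandmarkSet | None = None
    config: CohortConfig | None = None


# ---------------------------------------------------------------------------
# Template surface
# ---------------------------------------------------------------------------

def _face_height(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Analytic face-like height field z(x, y); even in x by construction."""
    x2 = x * x
    dome = 35.0 * np.exp(-((x2 / 55.0 ** 2) + (y / 75.0) ** 2) ** 1.5)
    nose = 16.0 * np.exp(-x2 / 9.0 ** 2) * np.exp(-((y - 14.0) / 20.0) ** 2)
    tip = 6.0 * np.exp(-(x2 + (y - 4.0) ** 2) / 45.0)
    lips = 4.0 * np.exp(-((y + 25.0) / 6.0) ** 2) * np.exp(-x2 / 22.0 ** 2)
    chin = 5.0 * np.exp(-x2 / 300.0 - (y + 58.0) ** 2 / 180.0)
    return dome + nose + tip + lips + chin


# landmark template positions (x, y); z from the analytic height field.
_MIDLINE_XY = {
    "nasion": (0.0, 30.0),
    "pronasale": (0.0, 5.0),
    "subnasale": (0.0, -12.0),
    "labiale_superius": (0.0, -20.0),
    "labiale_inferius": (0.0, -30.0),
    "pogonion": (0.0, -58.0),
}
_PAIR_XY = {  # x is the left-side (+x) coordinate; the right twin is at -x
    "endocanthion": (16.0, 32.0),
    "exocanthion": (42.0, 33.0),
    "alare": (11.0, -6.0),
    "cheilion": (24.0, -25.0),
    "crista_philtri": (5.0, -21.0),
    "gonion": (52.0, -45.0),
}


def make_template(resolution: int = 40) -> tuple[SurfaceMesh, LandmarkSet]:
    """Exactly mirror-symmetric face-like surface with the 18-landmark set.

    The grid has ``2*(resolution//2)+1`` columns in x and ``2*resolution``
    rows in y (at least ``2*resolution**2`` vertices); the x < 0 half is a
    bitwise mirror of the x > 0 half, so template symmetry is exact to
    machine precision.
    """
    if resolution < 20:
        raise ValueError("resolution must be >= 20 for a usable face surface")
    nxh = resolution // 2
    ny = 2 * resolution
    xs_half = np.linspace(0.0, 60.0, nxh + 1)
    xs = np.concatenate([-xs_half[:0:-1], xs_half])  # exact negation mirror
    ys = np.linspace(-85.0, 85.0, ny)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    Zh = _face_height(X[nxh:], Y[nxh:])               # x >= 0 half
    Z = np.concatenate([Zh[:0:-1], Zh])               # mirrored bit-exactly
    nx = len(xs)
    vertices = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    # Triangulate the x >= 0 half and mirror its faces so the triangulation
    # itself is mirror-symmetric (quad diagonals included); otherwise the
    # piecewise-linear surface of the mirrored mesh differs within quads and
    # a perfectly symmetric face would show spurious orientation asymmetry.
    idx = np.arange(nx * ny).reshape(nx, ny)
    half = idx[nxh:]
    q00, q10 = half[:-1, :-1].ravel(), half[1:, :-1].ravel()
    q01, q11 = half[:-1, 1:].ravel(), half[1:, 1:].ravel()
    # wound so normals point toward +z (anterior / outward)
    right = np.concatenate([np.column_stack([q00, q10, q11]),
                            np.column_stack([q00, q11, q01])])
    col, row = right // ny, right % ny
    left = ((2 * nxh - col) * ny + row)[:, ::-1]  # reflected ids, reversed winding
    mesh = SurfaceMesh(vertices, np.concatenate([right, left]))

    pairs, midline = default_landmark_schema()
    points: dict[str, np.ndarray] = {}
    for name, (x0, y0) in _MIDLINE_XY.items():
        points[name] = np.array([x0, y0, float(_face_height(np.array(x0), np.array(y0)))])
    for base, (x0, y0) in _PAIR_XY.items():
        z0 = float(_face_height(np.array(x0), np.array(y0)))
        points[f"{base}_l"] = np.array([x0, y0, z0])
        points[f"{base}_r"] = np.array([-x0, y0, z0])
    return mesh, LandmarkSet(points, pairs, midline)


# ---------------------------------------------------------------------------
# Asymmetry injection
# ---------------------------------------------------------------------------

def _edge_length_graph(mesh: SurfaceMesh) -> sp.csr_matrix:
    e = mesh.edges()
    w = np.linalg.norm(mesh.vertices[e[:, 0]] - mesh.vertices[e[:, 1]], axis=1)
    n = mesh.n_vertices
    g = sp.coo_matrix((w, (e[:, 0], e[:, 1])), shape=(n, n))
    return (g + g.T).tocsr()


def _region_center(landmarks: LandmarkSet, spec: AsymmetrySpec) -> np.ndarray:
    sided = f"{spec.center}_{spec.side[0]}"
    if sided in landmarks.points:
        return landmarks.points[sided]
    if spec.center in landmarks.points:
        # a one-sided asymmetry "at" a midline landmark peaks lateral to it,
        # not on the mirror plane itself: offset the centre by half a radius
        center = landmarks.points[spec.center].copy()
        center[0] += (0.5 if spec.side == "left" else -0.5) * spec.radius
        return center
    raise ValueError(f"asymmetry region center '{spec.center}' not in landmark set")


def _displacement(mesh: SurfaceMesh, landmarks: LandmarkSet, spec: AsymmetrySpec,
                  graph: sp.csr_matrix) -> np.ndarray:
    center = _region_center(landmarks, spec)
    seed_vertex = int(np.linalg.norm(mesh.vertices - center, axis=1).argmin())
    dist = dijkstra(graph, directed=False, indices=seed_vertex, limit=spec.radius)
    inside = np.isfinite(dist)
    if not inside.any():
        raise ValueError(f"asymmetry region around '{spec.center}' does not touch the mesh")
    w = np.zeros(mesh.n_vertices)
    w[inside] = 0.5 * (1.0 + np.cos(np.pi * dist[inside] / spec.radius))

    # confine the displacement to one side; smooth ramp near the midline so a
    # midline-centred region does not produce a crease at x = 0
    sign = 1.0 if spec.side == "left" else -1.0
    ramp_width = max(spec.radius / 4.0, 1e-9)
    s = np.clip(sign * mesh.vertices[:, 0] / ramp_width, 0.0, 1.0)
    w = w * (s * s * (3.0 - 2.0 * s))

    disp = np.zeros_like(mesh.vertices)
    act = w > 0
    if spec.kind == "normal_bump":
        disp[act] = spec.amplitude * w[act, None] * mesh.normals[act]
    elif spec.kind == "tangential_shear":
        n = mesh.normals[act]
        t = np.array([0.0, 1.0, 0.0]) - n * n[:, 1:2]
        t /= np.maximum(np.linalg.norm(t, axis=1, keepdims=True), 1e-12)
        disp[act] = spec.amplitude * w[act, None] * t
    else:  # regional_rotation about the outward normal at the region centre
        axis = mesh.normals[seed_vertex]
        theta = np.radians(spec.amplitude) * w[act]
        p = mesh.vertices[act] - center
        cos_t, sin_t = np.cos(theta)[:, None], np.sin(theta)[:, None]
        cross = np.cross(np.broadcast_to(axis, p.shape), p)
        dot = (p @ axis)[:, None]
        rotated = p * cos_t + cross * sin_t + axis * dot * (1.0 - cos_t)
        disp[act] = rotated - p
    return disp


def inject_asymmetry(mesh: SurfaceMesh, landmarks: LandmarkSet,
                     specs: list[AsymmetrySpec], noise_sd: float = 0.0,
                     rng: np.random.Generator | None = None
                     ) -> tuple[SurfaceMesh, LandmarkSet]:
    """Apply smooth one-sided displacements plus iid vertex noise.

    Landmarks ride the surface: each landmark moves with its nearest vertex.
    With all amplitudes 0 and ``noise_sd`` 0 the inputs are returned
    bit-exactly (copies).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if noise_sd > 0 and rng is None:
        raise ValueError("vertex noise requires an explicit rng")
    if noise_sd == 0.0 and all(s.amplitude == 0.0 for s in specs):
        return mesh.copy(), LandmarkSet(dict(landmarks.points), list(landmarks.pairs),
                                        list(landmarks.midline))
    graph = _edge_length_graph(mesh)
    disp = np.zeros_like(mesh.vertices)
    for spec_ in specs:
        if spec_.amplitude > 0:
            disp += _displacement(mesh, landmarks, spec_, graph)
    if noise_sd > 0:
        disp = disp + rng.normal(0.0, noise_sd, size=disp.shape)
    nearest = {name: int(np.linalg.norm(mesh.vertices - p, axis=1).argmin())
               for name, p in landmarks.points.items()}
    new_points = {name: landmarks.points[name] + disp[vi] for name, vi in nearest.items()}
    return (SurfaceMesh(mesh.vertices + disp, mesh.faces.copy()),
            LandmarkSet(new_points, list(landmarks.pairs), list(landmarks.midline)))


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

def _simulate_genotypes(rng: np.random.Generator, n_subjects: int, config: CohortConfig,
                        subject_ids: list[str]) -> GenotypeMatrix:
    maf = rng.uniform(*config.maf_range, size=config.n_snps)
    maf[config.causal_index] = config.causal_maf
    codes = rng.binomial(2, maf, size=(n_subjects, config.n_snps)).astype(float)
    snp_ids = [f"snp{i:05d}" for i in range(config.n_snps)]
    chrom = (np.arange(config.n_snps) % 22) + 1
    pos = 1000 * (np.arange(config.n_snps) + 1)
    info = pd.DataFrame({"chrom": chrom, "pos": pos}, index=snp_ids)
    return GenotypeMatrix(pd.DataFrame(codes, index=subject_ids, columns=snp_ids), info)


def _random_rigid(rng: np.random.Generator, max_angle_deg: float = 5.0,
                  max_shift: float = 5.0) -> tuple[np.ndarray, np.ndarray]:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.radians(rng.uniform(0.0, max_angle_deg))
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    R = np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)
    t = rng.uniform(-max_shift, max_shift, size=3)
    return R, t


def simulate_cohort(config: CohortConfig,
                    template: tuple[SurfaceMesh, LandmarkSet] | None = None) -> Cohort:
    """Draw a cohort of faces, genotypes and covariates with known ground truth.

    All randomness flows from ``config.seed`` through one generator. The
    returned ``truth`` table holds the injected amplitude per subject, the
    quantity the asymmetry scores should recover.
    """
    rng = np.random.default_rng(config.seed)
    tmesh, tlm = make_template(config.resolution) if template is None else template
    ids = [f"s{i:04d}" for i in range(config.n_subjects)]

    genotypes = _simulate_genotypes(rng, config.n_subjects, config, ids) if config.n_snps else None
    g_causal = (genotypes.codes.iloc[:, config.causal_index].to_numpy()
                if genotypes is not None else np.zeros(config.n_subjects))
    amplitude = rng.normal(config.amplitude_mean, config.amplitude_sd, config.n_subjects)
    amplitude = np.maximum(0.0, amplitude + config.effect * g_causal)
    region = rng.choice(config.regions, size=config.n_subjects)
    side = rng.choice(["left", "right"], size=config.n_subjects)
    age = rng.uniform(*config.age_range, size=config.n_subjects)
    sex = (rng.random(config.n_subjects) < config.sex_ratio).astype(int)

    meshes: list[SurfaceMesh] | None = None
    lm_list: list[LandmarkSet] | None = None
    if config.make_meshes:
        meshes, lm_list = [], []
        for i in range(config.n_subjects):
            spec_ = AsymmetrySpec(center=str(region[i]), radius=config.region_radius,
                                  kind="normal_bump", amplitude=float(amplitude[i]),
                                  side=str(side[i]))
            m, lm = inject_asymmetry(tmesh, tlm, [spec_], config.noise_sd, rng)
            if config.rigid_jitter:
                R, t = _random_rigid(rng)
                m, lm = m.transformed(R, t), lm.transformed(R, t)
            meshes.append(m)
            lm_list.append(lm)

    covariates = pd.DataFrame({"age": age, "sex": sex}, index=ids)
    truth = pd.DataFrame({"amplitude": amplitude, "region": region, "side": side,
                          "causal_genotype": g_causal}, index=ids)
    return Cohort(ids, meshes, lm_list, genotypes, covariates, truth,
                  tmesh, tlm, config)


def write_cohort(cohort: Cohort, out_dir: str | Path) -> None:
    """Write a cohort directory: meshes/, landmarks/, TSV tables and config."""
    out = Path(out_dir)
    (out / "meshes").mkdir(parents=True, exist_ok=True)
    (out / "landmarks").mkdir(exist_ok=True)
    if cohort.meshes is not None:
        for sid, mesh, lm in zip(cohort.subject_ids, cohort.meshes, cohort.landmarks):
            write_mesh(mesh, out / "meshes" / f"{sid}.ply")
            write_landmarks(lm, out / "landmarks" / f"{sid}.csv")
    if cohort.template_mesh is not None:
        write_mesh(cohort.template_mesh, out / "template.ply")
        write_landmarks(cohort.template_landmarks, out / "template_landmarks.csv")
    if cohort.genotypes is not None:
        write_genotype_tsv(cohort.genotypes, out / "genotypes.tsv")
    cohort.covariates.rename_axis("subject_id").to_csv(out / "covariates.tsv", sep="\t")
    cohort.truth.rename_axis("subject_id").to_csv(out / "truth.tsv", sep="\t")
    if cohort.config is not None:
        (out / "config.json").write_text(json.dumps(asdict(cohort.config), indent=2))
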