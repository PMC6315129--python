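"""Local asymmetry features and the population model of normal asymmetry.

For every point of the average mesh, the subject's original and mirrored
surfaces are sampled through dense correspondences. The difference of the
two sampled positions is the *asymmetry flow vector*; from it and the
sampled surface normals three per-point features are derived:

- ``surface_orientation_angle`` — angle (degrees) between the normals at
  corresponding points of the original and mirrored surface; measures
  asymmetry of local orientation, independent of its magnitude.
- ``deformation_angle`` — angle (degrees) between the flow vector and the
  original surface normal; the direction of the mirror transformation.
- ``deformation_magnitude`` — Euclidean length of the flow vector (mm).

A cohort of per-subject feature maps is summarized point-wise by its mean
and standard deviation — the model of *normal* asymmetry that individual
subjects are scored against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .correspondence import AverageMesh, Correspondence
from .mesh_core import SurfaceMesh

__all__ = [
    "FEATURE_NAMES",
    "FeatureHeatMap",
    "NormalAsymmetryModel",
    "sample_normals",
    "asymmetry_flow",
    "surface_orientation_angle",
    "deformation_angle",
    "deformation_magnitude",
    "compute_feature_maps",
    "build_normal_model",
]

FEATURE_NAMES = ("surface_orientation_angle", "deformation_angle", "deformation_magnitude")

#: flows shorter than this (mm) are treated as "no asymmetry": the
#: deformation angle is defined as 0 rather than left undefined.
EPS_FLOW = 1e-6

#: floor for the model standard deviation, so standardized errors stay finite
#: even at points where the cohort is perfectly concordant.
EPS_SD = 1e-6


@dataclass
class FeatureHeatMap:
    """One scalar per average-mesh point for one feature of one subject."""

    feature_name: str
    values: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        if self.feature_name not in FEATURE_NAMES:
            raise ValueError(f"unknown feature '{self.feature_name}'; expected one of {FEATURE_NAMES}")
        self.values = np.asarray(self.values, dtype=np.float64).reshape(-1)
        if np.any(self.values < -1e-9):
            raise ValueError(f"{self.feature_name} values must be non-negative")
        if self.feature_name.endswith("angle") and np.any(self.values > 180 + 1e-9):
            raise ValueError("angle features must lie in [0, 180] degrees")

    def restricted(self, indices: np.ndarray) -> "FeatureHeatMap":
        return FeatureHeatMap(self.feature_name, self.values[indices], self.subject_id)


@dataclass
class NormalAsymmetryModel:
    """Per-point mean/SD of each feature over a reference cohort."""

    average_mesh: AverageMesh
    mean: dict[str, np.ndarray]
    sd: dict[str, np.ndarray]
    n_subjects: int
    bin_edges: dict[str, np.ndarray] = field(default_factory=dict)

    def save(self, path) -> None:
        """Serialize as a single .npz archive (mesh + stats + binning)."""
        arrays = {
            "vertices": self.average_mesh.mesh.vertices,
            "faces": self.average_mesh.mesh.faces,
            "n_subjects": np.array(self.n_subjects),
            "provenance": np.array(self.average_mesh.provenance, dtype=str),
        }
        for name in self.mean:
            arrays[f"mean_{name}"] = self.mean[name]
            arrays[f"sd_{name}"] = self.sd[name]
        for name, edges in self.bin_edges.items():
            arrays[f"edges_{name}"] = edges
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "NormalAsymmetryModel":
        with np.load(path, allow_pickle=False) as z:
            mesh = SurfaceMesh(z["vertices"], z["faces"])
            mean = {k[5:]: z[k] for k in z.files if k.startswith("mean_")}
            sd = {k[3:]: z[k] for k in z.files if k.startswith("sd_")}
            edges = {k[6:]: z[k] for k in z.files if k.startswith("edges_")}
            prov = [str(s) for s in z["provenance"]]
            n = int(z["n_subjects"])
        return cls(AverageMesh(mesh, prov), mean, sd, n, edges)


# ---------------------------------------------------------------------------
# Per-subject features
# ---------------------------------------------------------------------------

def sample_normals(mesh: SurfaceMesh, corr: Correspondence) -> np.ndarray:
    """Unit surface normals at correspondence targets.

    Vertex normals are barycentric-interpolated inside the target triangle
    and renormalized; interpolation avoids the quantization noise of flat
    per-facet normals.
    """
    n = corr.interpolate(mesh, mesh.normals)
    norms = np.linalg.norm(n, axis=1)
    if np.any(norms < 1e-12):
        raise ValueError("interpolated normal has zero length (opposing vertex normals)")
    return n / norms[:, None]


def asymmetry_flow(corr_original: Correspondence, corr_mirror: Correspondence) -> np.ndarray:
    """Flow vectors v_j = p_mirror(j) - p_original(j), one per base point (mm)."""
    if corr_original.base_point_count != corr_mirror.base_point_count:
        raise ValueError("original and mirror correspondences map different point counts")
    return corr_mirror.positions - corr_original.positions


def _angle_deg(cosines: np.ndarray) -> np.ndarray:
    return np.degrees(np.arccos(np.clip(cosines, -1.0, 1.0)))


def surface_orientation_angle(normals_original: np.ndarray, normals_mirror: np.ndarray,
                              subject_id: str = "") -> FeatureHeatMap:
    """Angle between unit normals at corresponding original/mirror points."""
    a = np.asarray(normals_original, float)
    b = np.asarray(normals_mirror, float)
    for arr in (a, b):
        if np.any(np.abs(np.linalg.norm(arr, axis=1) - 1.0) > 1e-6):
            raise ValueError("normals must be unit length")
    return FeatureHeatMap("surface_orientation_angle",
                          _angle_deg(np.einsum("ij,ij->i", a, b)), subject_id)


def deformation_angle(flow: np.ndarray, normals_original: np.ndarray,
                      subject_id: str = "", eps_flow: float = EPS_FLOW) -> FeatureHeatMap:
    """Angle between the flow vector and the original surface normal.

    Where the flow is shorter than ``eps_flow`` the point is symmetric and
    the angle is defined as 0 (no asymmetry), not NaN.
    """
    v = np.asarray(flow, float)
    n = np.asarray(normals_original, float)
    mag = np.linalg.norm(v, axis=1)
    ang = np.zeros(len(v))
    moving = mag >= eps_flow
    cosv = np.einsum("ij,ij->i", v[moving], n[moving]) / mag[moving]
    ang[moving] = _angle_deg(cosv)
    return FeatureHeatMap("deformation_angle", ang, subject_id)


def deformation_magnitude(flow: np.ndarray, subject_id: str = "") -> FeatureHeatMap:
    """Length of the asymmetry flow vector at each point (mm)."""
    return FeatureHeatMap("deformation_magnitude",
                          np.linalg.norm(np.asarray(flow, float), axis=1), subject_id)


def compute_feature_maps(corr_original: Correspondence, corr_mirror: Correspondence,
                         mesh_original: SurfaceMesh, mesh_mirror: SurfaceMesh,
                         subject_id: str = "") -> dict[str, FeatureHeatMap]:
    """All three feature maps of one subject, evaluated at average-mesh points."""
    flow = asymmetry_flow(corr_original, corr_mirror)
    n_orig = sample_normals(mesh_original, corr_original)
    n_mirr = sample_normals(mesh_mirror, corr_mirror)
    return {
        "surface_orientation_angle": surface_orientation_angle(n_orig, n_mirr, subject_id),
        "deformation_angle": deformation_angle(flow, n_orig, subject_id),
        "deformation_magnitude": deformation_magnitude(flow, subject_id),
    }


# ---------------------------------------------------------------------------
# Normal-asymmetry model
# ---------------------------------------------------------------------------

def build_normal_model(heat_maps: list[FeatureHeatMap], average_mesh: AverageMesh,
                       eps_sd: float = EPS_SD, n_bins: int = 25) -> NormalAsymmetryModel:
    """Point-wise mean and sample SD (ddof=1) of each feature over the cohort.

    The SD is floored at ``eps_sd`` so downstream standardization never
    divides by zero. Histogram bin edges are fixed per feature: [0, 180]
    degrees for the two angles, [0, cohort max] for the magnitude.
    """
    by_feature: dict[str, list[FeatureHeatMap]] = {}
    for hm in heat_maps:
        by_feature.setdefault(hm.feature_name, []).append(hm)
    mean, sd, edges = {}, {}, {}
    n_subjects = None
    for name, maps in by_feature.items():
        if len(maps) < 2:
            raise ValueError(f"feature '{name}': sample SD needs >= 2 subjects, got {len(maps)}")
        counts = {len(m.values) for m in maps}
        if len(counts) != 1:
            raise ValueError(f"feature '{name}': heat maps have mismatched point counts {counts}")
        stacked = np.stack([m.values for m in maps])
        mean[name] = stacked.mean(axis=0)
        sd[name] = np.maximum(stacked.std(axis=0, ddof=1), eps_sd)
        if name.endswith("angle"):
            edges[name] = np.linspace(0.0, 180.0, n_bins + 1)
        else:
            edges[name] = np.linspace(0.0, max(float(stacked.max()), eps_sd), n_bins + 1)
        n_subjects = len(maps)
    return NormalAsymmetryModel(average_mesh, mean, sd, int(n_subjects or 0), edges)
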