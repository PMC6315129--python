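"""End-to-end asymmetry phenotyping: alignment through scores.

Runs the full chain for a cohort of meshes with landmarks:

1. rigid landmark alignment of every subject into the reference frame;
2. dense correspondence from a base mesh to each subject and construction
   of the cohort average mesh (optionally iterated, re-mapping from the
   current average);
3. below-eyes crop of the average mesh — the scored region;
4. per subject: mirror across the midsagittal plane, map the average mesh
   onto the original and mirrored surfaces, derive the three local
   asymmetry feature maps;
5. cohort model of normal asymmetry (per-point mean/SD);
6. spatiogram score per subject and feature, plus the two baselines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .asymmetry_features import (FEATURE_NAMES, FeatureHeatMap, NormalAsymmetryModel,
                                 build_normal_model, compute_feature_maps)
from .baseline_scores import landmark_procrustes_score, mean_magnitude_score
from .correspondence import (AverageMesh, compute_average_mesh, dense_correspondence)
from .mesh_core import (CropResult, LandmarkSet, SurfaceMesh, crop_below_eyes,
                        landmark_rigid_align, mirror_mesh)
from .spatiogram_score import DEFAULT_BINS, score_subject, vertex_adjacency

__all__ = ["CohortScores", "score_cohort"]


@dataclass
class CohortScores:
    """Pipeline output: per-subject scores, the model, and the scored region."""

    scores: pd.DataFrame                 # index subject_id; feature + baseline columns
    model: NormalAsymmetryModel
    heat_maps: dict[str, list[FeatureHeatMap]]
    average_mesh: AverageMesh
    crop: CropResult


def _mean_landmarks(landmark_sets: list[LandmarkSet]) -> LandmarkSet:
    names = sorted(landmark_sets[0].points)
    pts = {n: np.mean([lm.points[n] for lm in landmark_sets], axis=0) for n in names}
    return LandmarkSet(pts, list(landmark_sets[0].pairs), list(landmark_sets[0].midline))


def score_cohort(meshes: list[SurfaceMesh], landmarks: list[LandmarkSet],
                 subject_ids: list[str] | None = None,
                 reference_landmarks: LandmarkSet | None = None,
                 base_mesh: SurfaceMesh | None = None,
                 base_landmarks: LandmarkSet | None = None,
                 n_bins: int = DEFAULT_BINS, tau: int | None = None,
                 average_iterations: int = 1,
                 features: tuple[str, ...] = FEATURE_NAMES,
                 variant: str = "bhattacharyya",
                 tps_lambda: float = 0.0) -> CohortScores:
    """Score every subject of a cohort against its own model of normal asymmetry.

    ``reference_landmarks`` fixes the aligned frame (midsagittal plane x=0);
    defaults to the base landmarks. ``base_mesh`` seeds the correspondence
    (default: first subject). ``average_iterations`` >= 1 re-maps subjects
    from the current average mesh before averaging again.

    ``tau=None`` scales the coherence threshold with the scored region:
    a component is coherent from 0.1% of the scored points (at least 2), the
    same image fraction the canonical tau of 20 represents on a ~20,000-point
    facial scan.
    """
    if len(meshes) < 2 or len(meshes) != len(landmarks):
        raise ValueError("need >= 2 subjects with one landmark set each")
    ids = subject_ids or [f"s{i:04d}" for i in range(len(meshes))]
    if base_mesh is None:
        base_mesh, base_landmarks = meshes[0], landmarks[0]
    if base_landmarks is None:
        raise ValueError("base_landmarks must accompany base_mesh")
    if reference_landmarks is None:
        reference_landmarks = base_landmarks

    aligned_meshes, aligned_lms = [], []
    for mesh, lm in zip(meshes, landmarks):
        frame = landmark_rigid_align(lm, reference_landmarks)
        aligned_meshes.append(mesh.transformed(frame.rotation, frame.translation))
        aligned_lms.append(lm.transformed(frame.rotation, frame.translation))
    base_frame = landmark_rigid_align(base_landmarks, reference_landmarks)
    current_mesh = base_mesh.transformed(base_frame.rotation, base_frame.translation)
    current_lms = base_landmarks.transformed(base_frame.rotation, base_frame.translation)

    average = None
    for _ in range(max(1, average_iterations)):
        corrs = [dense_correspondence(current_mesh, current_lms, m, lm, lam=tps_lambda)
                 for m, lm in zip(aligned_meshes, aligned_lms)]
        average = compute_average_mesh(current_mesh, corrs, ids)
        current_mesh = average.mesh
        current_lms = _mean_landmarks(aligned_lms)

    crop = crop_below_eyes(average.mesh, current_lms)
    cropped_average = AverageMesh(crop.mesh, average.provenance)
    adjacency = vertex_adjacency(crop.mesh)
    if tau is None:
        tau = max(2, round(1e-3 * crop.mesh.n_vertices))

    heat_maps: dict[str, list[FeatureHeatMap]] = {f: [] for f in features}
    baseline_rows = []
    for sid, mesh, lm in zip(ids, aligned_meshes, aligned_lms):
        mirror_m, mirror_lm = mirror_mesh(mesh, lm)
        corr_o = dense_correspondence(crop.mesh, current_lms, mesh, lm, lam=tps_lambda)
        corr_m = dense_correspondence(crop.mesh, current_lms, mirror_m, mirror_lm, lam=tps_lambda)
        maps = compute_feature_maps(corr_o, corr_m, mesh, mirror_m, sid)
        for f in features:
            heat_maps[f].append(maps[f])
        baseline_rows.append({
            "subject_id": sid,
            "mean_magnitude": mean_magnitude_score(maps["deformation_magnitude"]).value,
            "landmark_procrustes": landmark_procrustes_score(lm, subject_id=sid).value,
        })

    model = build_normal_model([hm for maps in heat_maps.values() for hm in maps],
                               cropped_average, n_bins=n_bins)
    rows = []
    for i, sid in enumerate(ids):
        row = {"subject_id": sid}
        for f in features:
            row[f] = score_subject(heat_maps[f][i], model, tau=tau,
                                   adjacency=adjacency, variant=variant).score
        rows.append(row)
    scores = pd.DataFrame(rows).set_index("subject_id")
    baselines = pd.DataFrame(baseline_rows).set_index("subject_id")
    return CohortScores(scores.join(baselines), model, heat_maps, cropped_average, crop)
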