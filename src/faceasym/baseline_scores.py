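"""Comparison phenotypes: mean-deformation-magnitude and landmark Procrustes.

Both baselines are classical asymmetry summaries: the first averages the
dense mirror-displacement magnitude over the scored region; the second
rigidly aligns a landmark configuration with its mirrored, relabelled copy
and averages the residual paired-landmark distances. Both are zero for an
exactly symmetric face and invariant to rigid motion of the input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .asymmetry_features import FeatureHeatMap
from .mesh_core import LandmarkSet, landmark_rigid_align

__all__ = ["BaselineScore", "mean_magnitude_score", "landmark_procrustes_score"]

METHODS = ("mean_magnitude", "landmark_procrustes")


@dataclass
class BaselineScore:
    subject_id: str
    method: str
    value: float  # mm, >= 0

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown baseline method '{self.method}'")
        if self.value < 0:
            raise ValueError("baseline score must be non-negative")


def mean_magnitude_score(magnitude_map: FeatureHeatMap) -> BaselineScore:
    """Arithmetic mean of the per-point deformation magnitude (mm)."""
    if magnitude_map.feature_name != "deformation_magnitude":
        raise ValueError("mean_magnitude_score expects a deformation_magnitude map")
    if len(magnitude_map.values) == 0:
        raise ValueError("empty magnitude map")
    return BaselineScore(magnitude_map.subject_id, "mean_magnitude",
                         float(magnitude_map.values.mean()))


def landmark_procrustes_score(landmarks: LandmarkSet,
                              pairs: list[tuple[str, str]] | None = None,
                              subject_id: str = "") -> BaselineScore:
    """Sparse landmark asymmetry: mirror, rigidly re-align, average distances.

    The landmark set (restricted to the bilaterally paired subset) is
    reflected and relabelled left <-> right, rigidly aligned back onto the
    original configuration by least squares (no scaling), and the mean
    distance between each original landmark and its aligned mirrored
    counterpart is the score. Because the reflection plane is arbitrary up
    to a rigid motion, the score does not depend on the input frame.
    """
    pairs = list(landmarks.pairs) if pairs is None else list(pairs)
    names = [n for pair in pairs for n in pair]
    if len(pairs) < 2 or len(names) < 3:
        raise ValueError("landmark Procrustes score needs >= 2 bilateral pairs")
    missing = [n for n in names if n not in landmarks.points]
    if missing:
        raise ValueError(f"unpaired/missing landmarks referenced: {missing}")
    subset = LandmarkSet({n: landmarks.points[n] for n in names}, pairs, [])
    mirrored = subset.mirrored()
    frame = landmark_rigid_align(mirrored, subset)
    aligned = frame.apply(mirrored.array(names))
    dists = np.linalg.norm(aligned - subset.array(names), axis=1)
    return BaselineScore(subject_id, "landmark_procrustes", float(dists.mean()))
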