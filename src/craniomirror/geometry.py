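"""Landmark geometry: pairwise distances, symmetric averaging, size
normalization, triangulated angles, and centroid-based mandible metrics.

The feature-construction convention is the one standard in landmark-based
morphometrics of bilateral structures: compute all pairwise Euclidean
distances, average each distance with its left/right mirror image, and
divide by the per-subject geometric mean of the distance block to remove
overall size. The resulting normalized distances (dimensionless) plus any
triangulated angles (degrees) form the per-subject feature vector used by
every downstream statistical stage.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .schemes import LandmarkScheme

__all__ = [
    "LandmarkConfiguration",
    "FeatureVector",
    "compute_pairwise_distances",
    "average_symmetric",
    "count_symmetric_features",
    "geometric_mean_normalize",
    "compute_angle",
    "mandible_metrics",
    "feature_vector",
    "feature_table",
    "symmetric_feature_names",
]


@dataclass
class LandmarkConfiguration:
    """Raw 3D landmark coordinates (mm) for one subject.

    ``coords`` maps landmark label -> length-3 array; labels absent from
    ``coords`` must be listed in ``missing``.
    """

    subject_id: str
    coords: dict[str, np.ndarray]
    missing: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        clean = {}
        for lab, p in self.coords.items():
            arr = np.asarray(p, dtype=float)
            if arr.shape != (3,):
                raise ValueError(f"landmark {lab!r}: expected a 3D point, got shape {arr.shape}")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"landmark {lab!r} has non-finite coordinates")
            clean[lab] = arr
        self.coords = clean
        self.missing = frozenset(self.missing)

    def validate_against(self, scheme: LandmarkScheme) -> None:
        scheme.validate_labels(self.coords)
        unaccounted = set(scheme.labels) - set(self.coords) - self.missing
        if unaccounted:
            raise ValueError(
                f"subject {self.subject_id!r}: landmarks neither placed nor "
                f"declared missing: {sorted(unaccounted)}"
            )


@dataclass
class FeatureVector:
    """Per-subject features: normalized distances (dimensionless, geometric
    mean 1 over the distance block) plus angles in degrees."""

    subject_id: str
    features: dict[str, float]


def compute_pairwise_distances(
    config: LandmarkConfiguration, scheme: LandmarkScheme
) -> dict[tuple[str, str], float]:
    """All pairwise Euclidean distances between the non-missing landmarks.

    Keys are (label_a, label_b) ordered by position in the scheme. Invariant
    under any rigid motion of the configuration.
    """
    config.validate_against(scheme)
    present = [lab for lab in scheme.labels if lab in config.coords]
    if len(present) < 2:
        raise ValueError(
            f"subject {config.subject_id!r}: need at least 2 placed landmarks, "
            f"got {len(present)}"
        )
    out: dict[tuple[str, str], float] = {}
    for a, b in itertools.combinations(present, 2):
        out[(a, b)] = float(np.linalg.norm(config.coords[a] - config.coords[b]))
    return out


def _canonical_pair(pair: tuple[str, str], scheme: LandmarkScheme) -> tuple[str, str]:
    """Representative of the mirror-equivalence class of an unordered pair.

    The mirror image of {a, b} is {mirror(a), mirror(b)}; of the (at most
    two) members of the class, the one that sorts first by scheme index is
    the canonical name. With the default numeric schemes the left-form label
    has the lower index, so left-form names the merged feature.
    """
    idx = {lab: i for i, lab in enumerate(scheme.labels)}
    a, b = sorted(pair, key=idx.__getitem__)
    ma, mb = sorted((scheme.mirror_label(a), scheme.mirror_label(b)), key=idx.__getitem__)
    return min((a, b), (ma, mb), key=lambda t: (idx[t[0]], idx[t[1]]))


def feature_name(pair: tuple[str, str], scheme: LandmarkScheme) -> str:
    a, b = _canonical_pair(pair, scheme)
    return f"{a}-{b}"


def average_symmetric(
    raw: dict[tuple[str, str], float], scheme: LandmarkScheme
) -> dict[str, float]:
    """Merge mirror-equivalent distances by arithmetic mean.

    Distance a-b and its bilateral mirror mirror(a)-mirror(b) measure the
    same anatomy on opposite sides; they are replaced by their mean under
    the canonical name. Distances that are their own mirror image (midline-
    midline, or within one bilateral pair) pass through unchanged. When one
    member of a mirror pair is unavailable (missing landmark) the available
    member represents the feature alone.
    """
    for a, b in raw:
        for lab in (a, b):
            if lab not in scheme.roles:
                raise ValueError(f"distance references unknown landmark {lab!r}")
    groups: dict[str, list[float]] = {}
    for pair, d in raw.items():
        groups.setdefault(feature_name(pair, scheme), []).append(d)
    return {name: float(np.mean(vals)) for name, vals in groups.items()}


def symmetric_feature_names(scheme: LandmarkScheme) -> list[str]:
    """Canonical names of all symmetric distance features of a scheme."""
    names: dict[str, None] = {}
    for pair in itertools.combinations(scheme.labels, 2):
        names.setdefault(feature_name(pair, scheme), None)
    return list(names)


def count_symmetric_features(m: int, p: int) -> int:
    """Number of unique distance features for m midline landmarks and p
    bilateral pairs, after symmetric averaging.

    Closed form C(m,2) + m*p + p*(p-1) + p: midline-midline pairs are
    unmerged; each midline-left distance merges with its midline-right
    mirror; distances between two different bilateral pairs merge two-to-one
    (same-side with same-side, cross with cross); each within-pair
    left-right distance is its own mirror.
    """
    if m < 0 or p < 0:
        raise ValueError("m and p must be non-negative")
    if m + 2 * p < 2:
        raise ValueError("need at least 2 landmarks")
    return m * (m - 1) // 2 + m * p + p * (p - 1) + p


def geometric_mean_normalize(features: dict[str, float]) -> dict[str, float]:
    """Divide each distance by the geometric mean of all (finite) distances.

    Removes overall size: the output is invariant to uniform scaling of the
    input configuration and has geometric mean exactly 1 over the finite
    entries. Missing (NaN) features propagate as NaN and are excluded from
    the geometric mean.
    """
    finite = {k: v for k, v in features.items() if not math.isnan(v)}
    for name, v in finite.items():
        if v <= 0:
            raise ValueError(f"feature {name!r} is non-positive ({v}); distances must be > 0")
    if not finite:
        raise ValueError("no finite features to normalize")
    log_gm = float(np.mean([math.log(v) for v in finite.values()]))
    gm = math.exp(log_gm)
    return {k: (v / gm if not math.isnan(v) else v) for k, v in features.items()}


def compute_angle(a, vertex, c) -> float:
    """Interior angle at ``vertex`` in degrees, range (0, 180].

    Invariant under rigid motion and uniform scaling. Works for 2D or 3D
    points.
    """
    a = np.asarray(a, dtype=float)
    vertex = np.asarray(vertex, dtype=float)
    c = np.asarray(c, dtype=float)
    u = a - vertex
    w = c - vertex
    nu = np.linalg.norm(u)
    nw = np.linalg.norm(w)
    if nu == 0 or nw == 0:
        raise ValueError("angle undefined: a point coincides with the vertex")
    cosang = np.clip(np.dot(u, w) / (nu * nw), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def mandible_metrics(
    incisor_landmarks, left_ramus_landmarks, right_ramus_landmarks
) -> tuple[float, float]:
    """Mandibular length (ML) and width (MW) from landmark-group centroids.

    Each group's centroid is the coordinate mean of its landmarks. MW is
    the distance between the left- and right-ramus centroids. ML is the
    mean of the two incisor-to-ramus centroid distances — the symmetric
    average of the left and right lengths.
    """
    cents = []
    for name, group in (
        ("incisor", incisor_landmarks),
        ("left_ramus", left_ramus_landmarks),
        ("right_ramus", right_ramus_landmarks),
    ):
        arr = np.asarray(group, dtype=float)
        if arr.size == 0:
            raise ValueError(f"empty landmark group {name!r}")
        arr = np.atleast_2d(arr)
        cents.append(arr.mean(axis=0))
    inc, left, right = cents
    mw = float(np.linalg.norm(left - right))
    ml = float((np.linalg.norm(inc - left) + np.linalg.norm(inc - right)) / 2.0)
    return ml, mw


def feature_vector(
    config: LandmarkConfiguration,
    scheme: LandmarkScheme,
    normalize: bool = True,
) -> FeatureVector:
    """Full feature vector for one subject: symmetric (normalized) distances
    plus the scheme's angle features.

    Features touching a missing landmark come out as NaN; downstream models
    drop missingness per feature rather than imputing.
    """
    raw = compute_pairwise_distances(config, scheme)
    merged = average_symmetric(raw, scheme)
    all_names = symmetric_feature_names(scheme)
    dists = {name: merged.get(name, float("nan")) for name in all_names}
    if normalize:
        dists = geometric_mean_normalize(dists)
    feats = dict(dists)
    for ang_name, (a, v, c) in scheme.angles.items():
        if any(lab in config.missing for lab in (a, v, c)):
            feats[ang_name] = float("nan")
        else:
            feats[ang_name] = compute_angle(
                config.coords[a], config.coords[v], config.coords[c]
            )
    return FeatureVector(subject_id=config.subject_id, features=feats)


def feature_table(
    configs, scheme: LandmarkScheme, normalize: bool = True
) -> pd.DataFrame:
    """Feature vectors for many subjects as a DataFrame (rows = subjects,
    columns = canonical feature names; distance columns first, then angles)."""
    rows = {}
    for cfg in configs:
        fv = feature_vector(cfg, scheme, normalize=normalize)
        rows[fv.subject_id] = fv.features
    cols = symmetric_feature_names(scheme) + list(scheme.angles)
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "subject_id"
    return df.reindex(columns=cols)
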