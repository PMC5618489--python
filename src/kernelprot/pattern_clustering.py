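"""Temporal profile classification and hierarchical clustering.

Profiles are log2 ratio trajectories over the stage axis.  Each is assigned
one of four developmental expression patterns by its sequence of
consecutive-difference signs (differences smaller than a tolerance count as
flat):

* P1_up      — monotone non-decreasing with at least one rise
* P2_up_down — a strict rise followed later by a strict fall, no fall before
               the rise and no rise after the fall (single interior peak)
* P3_down_up — the mirror image (single interior trough)
* P4_down    — monotone non-increasing with at least one fall
* unclassified — flat or multi-modal trajectories

Hierarchical clustering of the profiles (uncentered Pearson distance,
average linkage by default, mirroring Cluster 3.0 conventions) is kept for
ordering and export; pattern membership itself is the rule above, because
the four patterns are trend categories, not dendrogram branches.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

PATTERNS = ("P1_up", "P2_up_down", "P3_down_up", "P4_down", "unclassified")

#: default flatness tolerance on consecutive log2 differences
DEFAULT_TOLERANCE = 0.1


@dataclass(frozen=True)
class TemporalProfile:
    """Ordered log2-ratio values over the stage axis for one protein/tissue."""

    protein_id: str
    tissue: str
    stages: tuple[int, ...]
    log2_values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.stages) != len(self.log2_values):
            raise ValueError("one value per stage required")
        if any(not math.isfinite(v) for v in self.log2_values):
            raise ValueError("profile values must be finite")


@dataclass(frozen=True)
class PatternAssignment:
    protein_id: str
    tissue: str
    pattern: str


def _sign_sequence(values: Sequence[float], tolerance: float) -> list[int]:
    signs = []
    for a, b in zip(values, values[1:]):
        d = b - a
        signs.append(0 if abs(d) <= tolerance else (1 if d > 0 else -1))
    return signs


def classify_sign_sequence(signs: Sequence[int]) -> str:
    """Trend category for a sequence of consecutive-difference signs.

    This is the rule core shared by :func:`classify_pattern` and the
    exhaustive enumeration used in testing.
    """
    has_up = any(s > 0 for s in signs)
    has_down = any(s < 0 for s in signs)
    if not has_up and not has_down:
        return "unclassified"
    if has_up and not has_down:
        return "P1_up"
    if has_down and not has_up:
        return "P4_down"
    first_up = min(i for i, s in enumerate(signs) if s > 0)
    last_up = max(i for i, s in enumerate(signs) if s > 0)
    first_down = min(i for i, s in enumerate(signs) if s < 0)
    last_down = max(i for i, s in enumerate(signs) if s < 0)
    if last_up < first_down:
        return "P2_up_down"
    if last_down < first_up:
        return "P3_down_up"
    return "unclassified"


def classify_pattern(
    profile: TemporalProfile, tolerance: float = DEFAULT_TOLERANCE
) -> PatternAssignment:
    """Assign a temporal profile to one of the four patterns (or unclassified)."""
    if len(profile.log2_values) < 3:
        raise ValueError("need at least three stages to classify a trend")
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    pattern = classify_sign_sequence(_sign_sequence(profile.log2_values, tolerance))
    return PatternAssignment(profile.protein_id, profile.tissue, pattern)


def summarize_patterns(
    assignments: Iterable[PatternAssignment],
) -> dict[str, dict[str, int]]:
    """Per-tissue pattern counts; every pattern key present, zeros included."""
    out: dict[str, dict[str, int]] = {}
    for a in assignments:
        tissue_counts = out.setdefault(a.tissue, {p: 0 for p in PATTERNS})
        tissue_counts[a.pattern] += 1
    return out


# ---------------------------------------------------------------------------
# hierarchical clustering
# ---------------------------------------------------------------------------


def uncentered_correlation_distance(matrix: np.ndarray) -> np.ndarray:
    """Pairwise 1 - uncentered Pearson correlation (Cluster 3.0's default).

    The uncentered correlation is the cosine of the angle between the raw
    vectors (no mean subtraction).  Rows with zero norm have no defined
    angle; callers must exclude them first.
    """
    norms = np.linalg.norm(matrix, axis=1)
    if np.any(norms == 0):
        raise ValueError("zero-norm profile has undefined uncentered correlation")
    unit = matrix / norms[:, None]
    sim = np.clip(unit @ unit.T, -1.0, 1.0)
    return 1.0 - sim


@dataclass
class ClusterResult:
    linkage_matrix: np.ndarray
    flat_labels: np.ndarray
    kept_ids: list[str]
    excluded: dict[str, str]  # protein id -> reason


def hier_cluster(
    profiles: Sequence[TemporalProfile],
    k: int = 4,
    distance: str = "uncentered-correlation",
    linkage: str = "average",
) -> ClusterResult:
    """Agglomerative clustering of temporal profiles with a flat cut at k.

    Profiles that are undefined under the chosen distance (zero-norm or
    constant under correlation metrics) are excluded and reported with a
    reason, never dropped silently.
    """
    if linkage not in ("average", "complete"):
        raise ValueError(f"unsupported linkage {linkage!r}")
    kept, excluded = [], {}
    for p in profiles:
        v = np.asarray(p.log2_values, dtype=float)
        if distance == "uncentered-correlation" and np.linalg.norm(v) == 0:
            excluded[p.protein_id] = "zero-norm profile: undefined correlation"
        elif distance == "pearson-correlation" and np.ptp(v) == 0:
            excluded[p.protein_id] = "constant profile: undefined correlation"
        else:
            kept.append(p)
    if len(kept) < 2:
        raise ValueError("need at least two usable profiles")
    matrix = np.array([p.log2_values for p in kept], dtype=float)
    if distance == "uncentered-correlation":
        dist = squareform(uncentered_correlation_distance(matrix), checks=False)
    elif distance == "pearson-correlation":
        centered = matrix - matrix.mean(axis=1, keepdims=True)
        dist = squareform(uncentered_correlation_distance(centered), checks=False)
    elif distance == "euclidean":
        from scipy.spatial.distance import pdist

        dist = pdist(matrix)
    else:
        raise ValueError(f"unsupported distance {distance!r}")
    Z = hierarchy.linkage(dist, method=linkage)
    labels = hierarchy.fcluster(Z, t=min(k, len(kept)), criterion="maxclust")
    return ClusterResult(
        linkage_matrix=Z,
        flat_labels=labels,
        kept_ids=[p.protein_id for p in kept],
        excluded=excluded,
    )


def pattern_counts_vector(assignments: Iterable[PatternAssignment]) -> Counter:
    """Flat multiset of pattern labels, tissue-agnostic (convenience)."""
    return Counter(a.pattern for a in assignments)
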