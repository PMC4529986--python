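"""Complete-linkage clustering of template patches and medoid representatives.

The template library is far too large to use directly as a feature basis, so
a random subsample (10,000 3-aa patches by default; 2-aa patches are never
subsampled) is grouped by complete-linkage hierarchical clustering under the
d_SS metric, the dendrogram is cut at a fixed cluster count (40 for 3-aa,
20 for 2-aa), and each cluster is represented by its medoid — the member
with the smallest sum of squared d_SS to the other members.  The ordered
medoids Y_1..Y_L (3-aa first, then 2-aa; L = 60 by default) define the
structural feature space.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .superposition import (Patch, dss_to_references, patch_from_dict,
                            patch_to_dict)

__all__ = [
    "PatchDistanceMatrix",
    "ClusterSet",
    "RepresentativeSet",
    "subsample_templates",
    "pairwise_distances",
    "cluster_complete_linkage",
    "select_centroid",
    "build_representative_set",
]


@dataclass
class PatchDistanceMatrix:
    """Symmetric matrix of d_SS values (A) with a zero diagonal."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("distance matrix must be square")

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class ClusterSet:
    """A flat partition of patches into ``n_clusters`` labels."""

    labels: np.ndarray
    n_clusters: int
    linkage: str = "complete"

    def members(self, label: int) -> np.ndarray:
        return np.flatnonzero(self.labels == label)


def subsample_templates(patches: list[Patch], n_max: int = 10000,
                        seed: int = 0) -> list[Patch]:
    """Uniform sample without replacement of min(n_max, n) patches.

    Deterministic for a fixed seed; selection order follows the original
    patch order so repeated runs are stable.
    """
    if len(patches) <= n_max:
        return list(patches)
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(patches), size=n_max, replace=False))
    return [patches[i] for i in idx]


def pairwise_distances(patches: list[Patch]) -> PatchDistanceMatrix:
    """All-pairs d_SS matrix; each pair computed once (d_SS is symmetric)."""
    n = len(patches)
    sizes = {p.m for p in patches}
    if len(sizes) > 1:
        raise ValueError(f"mixed patch sizes in distance matrix: {sorted(sizes)}")
    vals = np.zeros((n, n))
    for i in range(n - 1):
        row = dss_to_references(patches[i], patches[i + 1:])
        vals[i, i + 1:] = row
        vals[i + 1:, i] = row
    return PatchDistanceMatrix(values=vals)


def cluster_complete_linkage(dist: PatchDistanceMatrix, n_clusters: int,
                             method: str = "complete") -> ClusterSet:
    """Agglomerative clustering on a precomputed d_SS matrix, cut by count.

    Complete linkage (merge cost = maximum inter-member distance) is the
    default; single and average linkage are available for comparison but
    produce ladder-shaped dendrograms on template patches and are not used
    in the standard pipeline.
    """
    n = dist.n
    if n_clusters > n:
        raise ValueError(f"n_clusters={n_clusters} exceeds {n} patches")
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    if n == 1:
        return ClusterSet(labels=np.zeros(1, dtype=int), n_clusters=1,
                          linkage=method)
    condensed = squareform(dist.values, checks=False)
    z = linkage(condensed, method=method)
    labels = fcluster(z, t=n_clusters, criterion="maxclust") - 1
    return ClusterSet(labels=labels, n_clusters=int(labels.max()) + 1,
                      linkage=method)


def select_centroid(member_indices, dist: PatchDistanceMatrix) -> int:
    """Medoid of a cluster: argmin of the sum of squared d_SS to the others.

    Ties break to the lowest patch index.  Returns the index into the
    distance matrix (the caller maps back to the patch).
    """
    members = np.asarray(list(member_indices), dtype=int)
    if members.size == 0:
        raise ValueError("empty cluster has no centroid")
    sub = dist.values[np.ix_(members, members)]
    cost = np.sum(sub ** 2, axis=1)
    return int(members[int(np.argmin(cost))])


@dataclass
class RepresentativeSet:
    """The ordered medoid patches Y_1..Y_L defining the feature space.

    3-aa representatives come first (Y_1..Y_n3), then 2-aa (Y_{n3+1}..Y_L).
    """

    reps_3aa: list[Patch]
    reps_2aa: list[Patch]

    @property
    def L(self) -> int:
        return len(self.reps_3aa) + len(self.reps_2aa)

    @property
    def n3(self) -> int:
        return len(self.reps_3aa)

    def ordered(self) -> list[Patch]:
        return list(self.reps_3aa) + list(self.reps_2aa)

    def to_dict(self) -> dict:
        return {"reps_3aa": [patch_to_dict(p) for p in self.reps_3aa],
                "reps_2aa": [patch_to_dict(p) for p in self.reps_2aa]}

    @classmethod
    def from_dict(cls, d: dict) -> "RepresentativeSet":
        return cls(reps_3aa=[patch_from_dict(p) for p in d["reps_3aa"]],
                   reps_2aa=[patch_from_dict(p) for p in d["reps_2aa"]])

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "RepresentativeSet":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _cluster_medoids(patches: list[Patch], n_clusters: int,
                     method: str) -> list[Patch]:
    dist = pairwise_distances(patches)
    clusters = cluster_complete_linkage(dist, n_clusters, method=method)
    reps = []
    for label in range(clusters.n_clusters):
        medoid = select_centroid(clusters.members(label), dist)
        reps.append(patches[medoid])
    return reps


def build_representative_set(templates_3aa: list[Patch],
                             templates_2aa: list[Patch],
                             n3: int = 40, n2: int = 20,
                             n_max: int = 10000, seed: int = 0,
                             method: str = "complete") -> RepresentativeSet:
    """Subsample, cluster and pick medoids for both patch size classes.

    Raises
    ------
    ValueError
        If a size class has fewer templates than requested clusters.
    """
    if len(templates_3aa) < n3:
        raise ValueError(
            f"need >= {n3} 3-aa templates, got {len(templates_3aa)}")
    if len(templates_2aa) < n2:
        raise ValueError(
            f"need >= {n2} 2-aa templates, got {len(templates_2aa)}")
    sub3 = subsample_templates(templates_3aa, n_max=n_max, seed=seed)
    reps3 = _cluster_medoids(sub3, n3, method)
    reps2 = _cluster_medoids(list(templates_2aa), n2, method)
    return RepresentativeSet(reps_3aa=reps3, reps_2aa=reps2)
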