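"""Non-hierarchical grouping of regions by their ecoregion profiles.

Regions are clustered with standard Lloyd k-means on their raw 0/1
ecoregion rows under squared Euclidean distance.  The best of many
seeded initialisations (by within-cluster sum of squares) is kept and
labels are renumbered canonically so that cluster 1 contains the first
region in unit order, cluster 2 the next unassigned region, and so on —
making the partition deterministic and comparable across runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .matrix import MatrixError, PresenceAbsenceMatrix

__all__ = ["ClusterAssignment", "kmeans_binary"]


@dataclass
class ClusterAssignment:
    """Partition of units into k non-empty clusters (labels 1..k)."""

    unit_ids: list[str]
    labels: list[int]
    k: int
    inertia: float

    def __post_init__(self):
        if len(self.labels) != len(self.unit_ids):
            raise MatrixError("labels do not match unit ids")
        present = set(self.labels)
        if present != set(range(1, self.k + 1)):
            raise MatrixError(
                f"every cluster 1..{self.k} must be non-empty; got labels {sorted(present)}"
            )

    def groups(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {g: [] for g in range(1, self.k + 1)}
        for u, l in zip(self.unit_ids, self.labels):
            out[l].append(u)
        return out

    def label_of(self, unit_id: str) -> int:
        return self.labels[self.unit_ids.index(unit_id)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"unit_id": self.unit_ids, "cluster": self.labels})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_groups(cls, groups: dict[int, list[str]], unit_order: list[str] | None = None):
        """Build an assignment from {cluster: [unit, ...]} (e.g. a published
        grouping), keeping ``unit_order`` if given."""
        mapping = {u: g for g, members in groups.items() for u in members}
        units = unit_order or [u for members in groups.values() for u in members]
        labels = [mapping[u] for u in units]
        return cls(units, labels, k=len(groups), inertia=float("nan"))


def _canonical_relabel(unit_ids, raw_labels, k):
    mapping: dict[int, int] = {}
    nxt = 1
    for l in raw_labels:
        if l not in mapping:
            mapping[l] = nxt
            nxt += 1
    assert nxt == k + 1
    return [mapping[l] for l in raw_labels]


def kmeans_binary(
    m: PresenceAbsenceMatrix, k: int, seed: int = 0, restarts: int = 100
) -> ClusterAssignment:
    """Lloyd k-means on the 0/1 rows of ``m`` (rows = the things clustered).

    The matrix is interpreted as regions x ecoregions: each row is one
    region's binary ecoregion profile.  Runs ``restarts`` seeded
    initialisations and keeps the lowest-inertia solution; deterministic
    given ``seed``.
    """
    X = m.values.astype(float)
    n = X.shape[0]
    if k > n:
        raise MatrixError(f"k={k} exceeds the number of rows ({n})")
    if k < 1:
        raise MatrixError("k must be at least 1")
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed, algorithm="lloyd")
    km.fit(X)
    labels = _canonical_relabel(m.taxon_ids, [int(l) + 1 for l in km.labels_], k)
    return ClusterAssignment(
        unit_ids=list(m.taxon_ids), labels=labels, k=k, inertia=float(km.inertia_)
    )
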