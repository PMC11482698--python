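"""Pairwise faunal dissimilarity between units and UPGMA dendrograms.

Two classic binary indices are supported.  For a pair of units with
``a`` shared presences, ``b`` presences only in the first and ``c`` only
in the second:

* Jaccard dissimilarity  ``1 - a / (a + b + c)``
* Sørensen (Dice) dissimilarity  ``1 - 2a / (2a + b + c)``

Hierarchical clustering uses UPGMA proper (unweighted pair-group method
with arithmetic mean): the distance between two clusters is the mean of
all cross-pair leaf distances, and the merge height of every internal
node defines an ultrametric cophenetic distance between its leaves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import pdist, squareform

from .matrix import MatrixError, PresenceAbsenceMatrix

__all__ = [
    "DistanceMatrix",
    "Dendrogram",
    "jaccard_dissimilarity",
    "sorensen_dissimilarity",
    "upgma",
    "cophenetic_height",
    "to_newick",
    "FaunalSimilarity",
]


@dataclass
class DistanceMatrix:
    """Symmetric matrix of pairwise dissimilarities in [0, 1]."""

    unit_ids: list[str]
    values: np.ndarray
    metric: str = ""

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        n = len(self.unit_ids)
        if v.shape != (n, n):
            raise MatrixError("distance matrix shape does not match unit ids")
        if not np.allclose(v, v.T):
            raise MatrixError("distance matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise MatrixError("distance matrix diagonal must be zero")
        if np.nanmin(v) < 0 or np.nanmax(v) > 1:
            raise MatrixError("dissimilarities must lie in [0, 1]")
        self.values = v

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)

    def __getitem__(self, pair):
        u, v = pair
        return self.values[self.unit_ids.index(u), self.unit_ids.index(v)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.unit_ids, columns=self.unit_ids)

    def to_csv(self, path) -> None:
        self.to_frame().rename_axis("unit").to_csv(path)


def _binary_dissimilarity(m: PresenceAbsenceMatrix, metric: str, zero_union: str):
    X = m.values.T.astype(bool)  # units x taxa
    occ = X.sum(axis=1)
    if zero_union not in ("error", "zero"):
        raise ValueError("zero_union must be 'error' or 'zero'")
    empty = [u for u, n in zip(m.unit_ids, occ) if n == 0]
    if empty:
        # only all-absent pairs have an empty union
        if zero_union == "error" and len(empty) > 1:
            raise MatrixError(
                f"units with no presences give undefined dissimilarity: {empty}"
            )
        if zero_union == "zero" and len(empty) > 1:
            warnings.warn(
                f"dissimilarity of all-absent unit pairs set to 0: {empty}",
                stacklevel=3,
            )
    with np.errstate(invalid="ignore"):
        d = squareform(pdist(X, metric=metric))
    d = np.nan_to_num(d, nan=0.0)  # only reached under zero_union='zero'
    return DistanceMatrix(list(m.unit_ids), d, metric=metric)


def jaccard_dissimilarity(
    m: PresenceAbsenceMatrix, zero_union: str = "error"
) -> DistanceMatrix:
    """Jaccard dissimilarity ``1 - a/(a+b+c)`` between all unit pairs."""
    dm = _binary_dissimilarity(m, "jaccard", zero_union)
    dm.metric = "jaccard"
    return dm


def sorensen_dissimilarity(
    m: PresenceAbsenceMatrix, zero_union: str = "error"
) -> DistanceMatrix:
    """Sørensen dissimilarity ``1 - 2a/(2a+b+c)`` between all unit pairs."""
    dm = _binary_dissimilarity(m, "dice", zero_union)
    dm.metric = "sorensen"
    return dm


class Dendrogram:
    """UPGMA merge tree with per-node cophenetic heights.

    Wraps a scipy linkage matrix together with the leaf labels.  Heights
    are non-decreasing root-wards (ultrametricity) and there are exactly
    ``n - 1`` internal nodes for ``n`` leaves.
    """

    def __init__(self, linkage_matrix: np.ndarray, leaves: list[str]):
        self.linkage = np.asarray(linkage_matrix, dtype=float)
        self.leaves = list(leaves)
        n = len(self.leaves)
        if self.linkage.shape != (n - 1, 4):
            raise MatrixError("linkage matrix does not match leaf count")
        self._coph = squareform(cophenet(self.linkage))
        self._index = {u: i for i, u in enumerate(self.leaves)}

    # -- queries ---------------------------------------------------------
    def cophenetic_matrix(self) -> DistanceMatrix:
        return DistanceMatrix(list(self.leaves), self._coph.copy(), metric="cophenetic")

    def cophenetic_height(self, u: str, v: str) -> float:
        for x in (u, v):
            if x not in self._index:
                raise MatrixError(f"unknown leaf {x!r}")
        if u == v:
            return 0.0
        return float(self._coph[self._index[u], self._index[v]])

    def join_height(self, u: str) -> float:
        """Height of the node at which leaf ``u`` first merges with any
        other leaf (the minimum cophenetic height from ``u``)."""
        if u not in self._index:
            raise MatrixError(f"unknown leaf {u!r}")
        i = self._index[u]
        others = np.delete(self._coph[i], i)
        return float(others.min())

    def root_height(self) -> float:
        return float(self.linkage[-1, 2])

    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2].copy()

    def clades(self) -> list[tuple[float, frozenset]]:
        """All internal nodes as (height, leaf set), in merge order."""
        n = len(self.leaves)
        members = {i: frozenset([self.leaves[i]]) for i in range(n)}
        out = []
        for s, (a, b, h, _) in enumerate(self.linkage):
            mem = members[int(a)] | members[int(b)]
            members[n + s] = mem
            out.append((float(h), mem))
        return out

    # -- exports ---------------------------------------------------------
    def to_newick(self) -> str:
        return to_newick(self)

    def plot(self, ax=None, **kwargs):
        """Render with scipy's dendrogram plotting (requires matplotlib)."""
        from scipy.cluster.hierarchy import dendrogram as _dendro

        if ax is None:
            import matplotlib.pyplot as plt

            _, ax = plt.subplots(figsize=(6, 0.3 * len(self.leaves) + 1))
        _dendro(
            self.linkage,
            labels=self.leaves,
            orientation=kwargs.pop("orientation", "left"),
            ax=ax,
            **kwargs,
        )
        ax.set_xlabel("dissimilarity")
        return ax


def upgma(d: DistanceMatrix) -> Dendrogram:
    """Build the UPGMA (average-linkage) dendrogram of a distance matrix.

    At equal merge distances the pair appearing first in the current
    cluster-index order is merged, which makes the tree deterministic for
    a given leaf order.
    """
    if len(d.unit_ids) < 2:
        raise MatrixError("need at least two units to cluster")
    if np.isnan(d.values).any():
        raise MatrixError("distance matrix contains NaN")
    Z = linkage(d.condensed(), method="average")
    return Dendrogram(Z, list(d.unit_ids))


def cophenetic_height(t: Dendrogram, u: str, v: str) -> float:
    """Height of the lowest common ancestor of leaves ``u`` and ``v``."""
    return t.cophenetic_height(u, v)


def to_newick(t: Dendrogram) -> str:
    """Serialise an ultrametric dendrogram to Newick.

    Branch lengths follow the half-height convention: every leaf sits at
    depth ``root_height / 2`` below the root, so the tree path length
    between two leaves equals their cophenetic height.
    """
    n = len(t.leaves)
    height = {i: 0.0 for i in range(n)}
    label = {i: t.leaves[i] for i in range(n)}
    for s, (a, b, h, _) in enumerate(t.linkage):
        a, b = int(a), int(b)
        node = n + s
        height[node] = h / 2.0
        la = f"{label[a]}:{height[node] - height[a]:.10g}"
        lb = f"{label[b]}:{height[node] - height[b]:.10g}"
        label[node] = f"({la},{lb})"
    return label[2 * n - 2] + ";"


class FaunalSimilarity:
    """Descriptive similarity analysis of a presence/absence matrix.

    A light model-style facade: construct with the data and options,
    ``fit()`` computes the distance matrix and UPGMA dendrogram.

    Parameters
    ----------
    matrix
        Taxon x unit :class:`~faunalregions.matrix.PresenceAbsenceMatrix`.
    metric
        ``"jaccard"`` or ``"sorensen"``.
    level
        ``"species"`` uses rows as given, ``"genus"`` first aggregates
        rows to genera by logical OR.
    """

    _METRICS = {"jaccard": jaccard_dissimilarity, "sorensen": sorensen_dissimilarity}

    def __init__(self, matrix: PresenceAbsenceMatrix, metric: str = "jaccard",
                 level: str = "species", zero_union: str = "error"):
        if metric not in self._METRICS:
            raise ValueError(f"metric must be one of {sorted(self._METRICS)}")
        if level not in ("species", "genus"):
            raise ValueError("level must be 'species' or 'genus'")
        self.matrix = matrix
        self.metric = metric
        self.level = level
        self.zero_union = zero_union

    def fit(self) -> "SimilarityResults":
        m = self.matrix.aggregate_to_genus() if self.level == "genus" else self.matrix
        dist = self._METRICS[self.metric](m, zero_union=self.zero_union)
        tree = upgma(dist)
        return SimilarityResults(self, m, dist, tree)


@dataclass
class SimilarityResults:
    model: FaunalSimilarity
    matrix_used: PresenceAbsenceMatrix
    distance: DistanceMatrix
    dendrogram: Dendrogram

    def summary(self) -> str:
        t = self.dendrogram
        lines = [
            f"Faunal similarity ({self.model.metric}, {self.model.level} level)",
            f"  {self.matrix_used.shape[0]} taxa x {self.matrix_used.shape[1]} units",
            f"  root height: {t.root_height():.4f}",
            "  merge heights (root-most first):",
        ]
        for h, mem in sorted(t.clades(), reverse=True)[:5]:
            lines.append(f"    {h:.4f}  {'+'.join(sorted(mem))}")
        return "\n".join(lines)
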