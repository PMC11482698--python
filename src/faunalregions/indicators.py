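"""Simplified indicator species analysis (ISA) with the phi coefficient.

Given a partition of regions into k clusters, every taxon is scored
against every *cluster combination* (a union of clusters — any non-empty
proper subset of {1..k}) with the phi coefficient of association, which
for two 0/1 vectors equals their Pearson correlation:

    phi = (N*n_pg - n_p*n_g) / sqrt(n_p*n_g*(N-n_p)*(N-n_g))

where N is the number of regions, n_p the taxon's presences, n_g the
size of the combination, and n_pg the presences inside it.  The best
combination is the phi-maximizer (ties go to the smaller, then
lexicographically earlier, combination).  Significance comes from a
Monte Carlo permutation test: region labels are permuted wholesale and
the statistic — the maximum phi over all combinations — is re-selected
for every permutation, which controls the selection over the 2^k - 2
candidates.  The p-value uses the add-one estimator
p = (1 + #{perm >= observed}) / (1 + n_perm), so p is never 0 and never
below 1/(n_perm + 1).  No multiple-testing correction is applied across
taxa; raw p < alpha defines significance, and "characteristic" taxa
additionally require phi above a threshold (default 0.7).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clustering import ClusterAssignment
from .matrix import MatrixError, PresenceAbsenceMatrix

__all__ = [
    "UndefinedAssociationError",
    "ClusterCombination",
    "IndicatorResult",
    "IndicatorTable",
    "ISASettings",
    "phi",
    "enumerate_combinations",
    "best_association",
    "permutation_pvalue",
    "run_isa",
    "IndicatorSpeciesAnalysis",
    "ISAResults",
]


class UndefinedAssociationError(ValueError):
    """phi is undefined (constant presence or constant group)."""


@dataclass(frozen=True)
class ClusterCombination:
    """A union of clusters used as a single target group."""

    member_clusters: tuple[int, ...]
    site_mask: tuple[bool, ...]

    def __post_init__(self):
        if not self.member_clusters:
            raise MatrixError("combination must contain at least one cluster")
        if not any(self.site_mask) or all(self.site_mask):
            raise MatrixError("combination mask must be non-constant")

    def __str__(self) -> str:
        return "+".join(str(c) for c in self.member_clusters)

    def mask_array(self) -> np.ndarray:
        return np.asarray(self.site_mask, dtype=bool)


def _phi_values(presence: np.ndarray, masks: np.ndarray) -> np.ndarray:
    """phi of one presence vector against a stack of group masks.

    ``presence``: float (N,), ``masks``: float (m, N).  Assumes presence
    and every mask are non-constant.
    """
    N = presence.shape[0]
    n_p = presence.sum()
    n_g = masks.sum(axis=1)
    n_pg = masks @ presence
    num = N * n_pg - n_p * n_g
    den = np.sqrt(n_p * n_g * (N - n_p) * (N - n_g))
    return num / den


def phi(presence, group) -> float:
    """phi coefficient of association between two binary vectors.

    Equals the Pearson correlation of the 0/1 vectors.  Raises
    :class:`UndefinedAssociationError` if either vector is constant.
    """
    p = np.asarray(presence, dtype=float).ravel()
    g = np.asarray(group, dtype=float).ravel()
    if p.shape != g.shape or p.size < 2:
        raise MatrixError("presence and group must have equal length >= 2")
    if p.sum() in (0, p.size):
        raise UndefinedAssociationError("presence vector is constant")
    if g.sum() in (0, g.size):
        raise UndefinedAssociationError("group vector is constant")
    return float(_phi_values(p, g[None, :])[0])


def enumerate_combinations(k: int, assignment: ClusterAssignment | None = None):
    """All non-empty proper subsets of {1..k}, by size then lexicographic.

    Returns 2^k - 2 :class:`ClusterCombination` objects.  Site masks are
    filled from ``assignment`` when given, otherwise left as the trivial
    per-cluster indicator over clusters themselves.
    """
    if k < 2:
        raise MatrixError("need k >= 2 clusters to form proper combinations")
    labels = np.asarray(assignment.labels) if assignment is not None else np.arange(1, k + 1)
    out = []
    for size in range(1, k):
        for members in itertools.combinations(range(1, k + 1), size):
            mask = np.isin(labels, members)
            out.append(ClusterCombination(members, tuple(bool(x) for x in mask)))
    return out


def _mask_matrix(combos) -> np.ndarray:
    return np.array([c.mask_array() for c in combos], dtype=float)


def best_association(presence, assignment: ClusterAssignment):
    """The combination maximizing phi for a presence vector.

    Ties are broken toward the smaller combination, then lexicographic
    order (the enumeration order), by taking the first maximizer.
    """
    p = np.asarray(presence, dtype=float).ravel()
    if p.sum() in (0, p.size):
        raise UndefinedAssociationError("presence vector is constant")
    combos = enumerate_combinations(assignment.k, assignment)
    vals = _phi_values(p, _mask_matrix(combos))
    best = int(np.argmax(vals))
    return combos[best], float(vals[best])


def _perm_stats(p, masks, n_perm, rng):
    """Max-phi statistic for n_perm label permutations of ``p``."""
    perms = np.stack([rng.permutation(p) for _ in range(n_perm)])
    N = p.shape[0]
    n_p = p.sum()
    n_g = masks.sum(axis=1)
    npg = masks @ perms.T  # (m, n_perm)
    num = N * npg - n_p * n_g[:, None]
    den = np.sqrt(n_p * n_g * (N - n_p) * (N - n_g))[:, None]
    return (num / den).max(axis=0)


def permutation_pvalue(presence, assignment: ClusterAssignment,
                       n_perm: int = 999, seed: int = 0) -> float:
    """Monte Carlo p-value for the best association of one taxon.

    The null permutes the region labels uniformly; the statistic is the
    maximum phi over all combinations, re-selected per permutation.
    Deterministic given ``seed``.
    """
    if n_perm < 1:
        raise MatrixError("n_perm must be at least 1")
    p = np.asarray(presence, dtype=float).ravel()
    if p.sum() in (0, p.size):
        raise UndefinedAssociationError("presence vector is constant")
    masks = _mask_matrix(enumerate_combinations(assignment.k, assignment))
    observed = _phi_values(p, masks).max()
    rng = np.random.default_rng(seed)
    stats = _perm_stats(p, masks, n_perm, rng)
    return float((1 + int((stats >= observed).sum())) / (1 + n_perm))


@dataclass(frozen=True)
class ISASettings:
    alpha: float = 0.05
    phi_threshold: float = 0.7
    n_perm: int = 999
    seed: int = 0


@dataclass(frozen=True)
class IndicatorResult:
    taxon_id: str
    best_combination: ClusterCombination
    phi: float
    p_value: float
    significant: bool
    characteristic: bool

    def __post_init__(self):
        if self.characteristic and not self.significant:
            raise MatrixError("characteristic implies significant")


@dataclass
class IndicatorTable:
    """Per-taxon indicator results plus a report of skipped taxa."""

    results: list[IndicatorResult]
    skipped: dict[str, str]
    settings: ISASettings

    @property
    def significant_count(self) -> int:
        return sum(r.significant for r in self.results)

    @property
    def characteristic_count(self) -> int:
        return sum(r.characteristic for r in self.results)

    def result(self, taxon_id: str) -> IndicatorResult:
        for r in self.results:
            if r.taxon_id == taxon_id:
                return r
        raise MatrixError(f"no result for taxon {taxon_id!r}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "taxon_id": r.taxon_id,
                    "combination": str(r.best_combination),
                    "phi": r.phi,
                    "p_value": r.p_value,
                    "significant": r.significant,
                    "characteristic": r.characteristic,
                }
                for r in self.results
            ]
        )

    def to_csv(self, path) -> None:
        s = self.settings
        header = (
            f"# indicator species analysis: alpha={s.alpha} "
            f"phi_threshold={s.phi_threshold} n_perm={s.n_perm} seed={s.seed}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            self.to_frame().to_csv(fh, index=False)

    def skipped_report(self) -> dict[str, str]:
        return dict(self.skipped)


def run_isa(
    m: PresenceAbsenceMatrix,
    assignment: ClusterAssignment,
    alpha: float = 0.05,
    phi_threshold: float = 0.7,
    n_perm: int = 999,
    seed: int = 0,
) -> IndicatorTable:
    """Run simplified ISA over every taxon of a taxa x regions matrix.

    The matrix columns must match the assignment's unit ids (any order).
    Taxa with constant presence over the regions are skipped and listed
    in the report rather than assigned p = 1.  A single seeded generator
    drives all permutations in taxon order, so the whole table is
    deterministic given ``seed``.
    """
    if set(m.unit_ids) != set(assignment.unit_ids):
        raise MatrixError("matrix units do not match the cluster assignment")
    if n_perm < 1:
        raise MatrixError("n_perm must be at least 1")
    # align columns to the assignment's unit order
    cols = [m.unit_ids.index(u) for u in assignment.unit_ids]
    X = m.values[:, cols].astype(float)
    combos = enumerate_combinations(assignment.k, assignment)
    masks = _mask_matrix(combos)
    rng = np.random.default_rng(seed)

    results: list[IndicatorResult] = []
    skipped: dict[str, str] = {}
    for tid, p in zip(m.taxon_ids, X):
        s = p.sum()
        if s == 0:
            skipped[tid] = "absent from every region"
            continue
        if s == p.size:
            skipped[tid] = "present in every region"
            continue
        vals = _phi_values(p, masks)
        best = int(np.argmax(vals))
        observed = float(vals[best])
        stats = _perm_stats(p, masks, n_perm, rng)
        pval = float((1 + int((stats >= observed).sum())) / (1 + n_perm))
        sig = pval < alpha
        results.append(
            IndicatorResult(
                taxon_id=tid,
                best_combination=combos[best],
                phi=observed,
                p_value=pval,
                significant=sig,
                characteristic=sig and observed > phi_threshold,
            )
        )
    return IndicatorTable(
        results, skipped, ISASettings(alpha, phi_threshold, n_perm, seed)
    )


class IndicatorSpeciesAnalysis:
    """Model-style front end: configure, then ``fit()`` for results.

    Parameters
    ----------
    matrix
        Taxa x regions presence/absence matrix (regions only — subset
        surrounding areas away first).
    assignment
        :class:`~faunalregions.clustering.ClusterAssignment` of the
        matrix's units, the ISA grouping factor.
    """

    def __init__(self, matrix: PresenceAbsenceMatrix, assignment: ClusterAssignment,
                 alpha: float = 0.05, phi_threshold: float = 0.7,
                 n_perm: int = 999, seed: int = 0):
        self.matrix = matrix
        self.assignment = assignment
        self.settings = ISASettings(alpha, phi_threshold, n_perm, seed)

    def fit(self) -> "ISAResults":
        s = self.settings
        table = run_isa(
            self.matrix, self.assignment,
            alpha=s.alpha, phi_threshold=s.phi_threshold,
            n_perm=s.n_perm, seed=s.seed,
        )
        return ISAResults(self, table)


@dataclass
class ISAResults:
    model: IndicatorSpeciesAnalysis
    table: IndicatorTable

    @property
    def significant_count(self) -> int:
        return self.table.significant_count

    @property
    def characteristic_count(self) -> int:
        return self.table.characteristic_count

    def summary(self) -> str:
        s = self.table.settings
        lines = [
            "Simplified indicator species analysis",
            f"  {len(self.table.results)} taxa analysed, "
            f"{len(self.table.skipped)} skipped (constant presence)",
            f"  settings: alpha={s.alpha}, phi_threshold={s.phi_threshold}, "
            f"n_perm={s.n_perm}, seed={s.seed}",
            f"  significant (p < {s.alpha}): {self.significant_count}",
            f"  characteristic (significant and phi > {s.phi_threshold}): "
            f"{self.characteristic_count}",
        ]
        sig = sorted(
            (r for r in self.table.results if r.significant),
            key=lambda r: (len(r.best_combination.member_clusters),
                           r.best_combination.member_clusters, -r.phi),
        )
        for r in sig:
            lines.append(
                f"    {r.taxon_id[:42]:42s} {str(r.best_combination):10s} "
                f"phi={r.phi:.3f} p={r.p_value:.3f}"
                + ("  *" if r.characteristic else "")
            )
        return "\n".join(lines)
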