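"""Synthetic presence/absence matrices with known planted structure.

Every pipeline stage can be exercised without real data: the generators
plant region clusters, indicator taxa of tunable fidelity, and endemics
of known range size, and return the ground truth alongside the matrix.
Occurrence follows a Bernoulli model — a taxon is present with
probability ``p_in`` inside its target cluster combination and ``p_out``
outside — matching strictly binary occurrence data (no abundances).
Identical seeds give bit-identical matrices.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .matrix import MatrixError, PresenceAbsenceMatrix, TaxonRecord, Unit

__all__ = ["SyntheticTruth", "generate_clustered_fauna", "generate_endemism_testbed"]

DEFAULT_CLUSTER_SIZES = (3, 4, 3, 2, 1)


@dataclass
class SyntheticTruth:
    """Ground truth behind a generated matrix."""

    planted_partition: dict[str, int] = field(default_factory=dict)
    planted_indicators: dict[str, tuple[int, ...]] = field(default_factory=dict)
    planted_ranges: dict[str, int] = field(default_factory=dict)
    generator_config: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "planted_partition": self.planted_partition,
            "planted_indicators": {t: list(c) for t, c in self.planted_indicators.items()},
            "planted_ranges": self.planted_ranges,
            "generator_config": self.generator_config,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _cluster_sizes(n_regions: int, k: int, cluster_sizes) -> list[int]:
    if cluster_sizes is None:
        if (n_regions, k) == (sum(DEFAULT_CLUSTER_SIZES), len(DEFAULT_CLUSTER_SIZES)):
            return list(DEFAULT_CLUSTER_SIZES)
        base, extra = divmod(n_regions, k)
        return [base + (1 if i < extra else 0) for i in range(k)]
    cluster_sizes = [int(s) for s in cluster_sizes]
    if len(cluster_sizes) != k or sum(cluster_sizes) != n_regions or min(cluster_sizes) < 1:
        raise MatrixError(
            f"cluster_sizes must be {k} positive integers summing to {n_regions}"
        )
    return cluster_sizes


def generate_clustered_fauna(
    n_taxa: int = 60,
    n_regions: int = 13,
    k: int = 5,
    p_in: float = 0.95,
    p_out: float = 0.05,
    cluster_sizes=None,
    max_combination_size: int = 1,
    seed: int = 0,
) -> tuple[PresenceAbsenceMatrix, SyntheticTruth]:
    """Matrix with planted region clusters and planted indicator taxa.

    Regions are split into ``k`` contiguous clusters (sizes
    ``cluster_sizes``, default profile (3,4,3,2,1) when it fits,
    otherwise near-equal).  Each taxon targets a random cluster
    combination of size 1..``max_combination_size`` and is present
    Bernoulli(``p_in``) inside it and Bernoulli(``p_out``) outside.
    The expected phi is derivable from (p_in, p_out, group sizes).
    """
    if k < 2:
        raise MatrixError("need k >= 2 clusters")
    if n_regions < k:
        raise MatrixError("need at least as many regions as clusters")
    if n_taxa < 1:
        raise MatrixError("need at least one taxon")
    if not (0 <= p_out <= 1 and 0 <= p_in <= 1):
        raise MatrixError("p_in and p_out must lie in [0, 1]")
    if p_in <= p_out:
        raise MatrixError("p_in must exceed p_out (planted signal)")
    if not (1 <= max_combination_size <= k - 1):
        raise MatrixError("max_combination_size must lie in 1..k-1")

    sizes = _cluster_sizes(n_regions, k, cluster_sizes)
    rng = np.random.default_rng(seed)
    region_ids = [f"R{i + 1:02d}" for i in range(n_regions)]
    labels = np.repeat(np.arange(1, k + 1), sizes)
    partition = {r: int(l) for r, l in zip(region_ids, labels)}

    taxon_ids = [f"Genus{i + 1:03d} species" for i in range(n_taxa)]
    indicators: dict[str, tuple[int, ...]] = {}
    vals = np.zeros((n_taxa, n_regions), dtype=np.int8)
    for i, tid in enumerate(taxon_ids):
        size = int(rng.integers(1, max_combination_size + 1))
        combo = tuple(sorted(rng.choice(np.arange(1, k + 1), size=size, replace=False).tolist()))
        indicators[tid] = combo
        inside = np.isin(labels, combo)
        p = np.where(inside, p_in, p_out)
        vals[i] = rng.random(n_regions) < p
    truth = SyntheticTruth(
        planted_partition=partition,
        planted_indicators=indicators,
        generator_config={
            "n_taxa": n_taxa, "n_regions": n_regions, "k": k,
            "p_in": p_in, "p_out": p_out, "cluster_sizes": sizes,
            "max_combination_size": max_combination_size, "seed": seed,
        },
    )
    m = PresenceAbsenceMatrix(
        vals,
        [TaxonRecord(t) for t in taxon_ids],
        [Unit(r, kind="iran_region") for r in region_ids],
    )
    return m, truth


def generate_endemism_testbed(
    n_taxa: int = 50,
    n_ecoregions: int = 16,
    range_distribution=None,
    seed: int = 0,
    region_ecoregions: PresenceAbsenceMatrix | None = None,
):
    """Taxa with known ecoregion range sizes, plus induced region matrix.

    ``range_distribution`` is either an int (every taxon gets that fixed
    range), a sequence of per-taxon ranges (length ``n_taxa``), or a
    probability vector over range sizes 1..n_ecoregions (default:
    uniform over 1..4).  Each taxon then occupies that many ecoregions,
    drawn uniformly without replacement.  Region occupancy is induced by
    a region -> ecoregion map (default: one region per ecoregion): a
    taxon occupies a region iff its ecoregions intersect the region's.

    Returns ``(occupancy, regions_matrix, truth)``.
    """
    if n_taxa < 1 or n_ecoregions < 1:
        raise MatrixError("need at least one taxon and one ecoregion")
    rng = np.random.default_rng(seed)
    eco_ids = [f"E{i + 1:02d}" for i in range(n_ecoregions)]
    taxon_ids = [f"Genus{i + 1:03d} species" for i in range(n_taxa)]

    if range_distribution is None:
        hi = min(4, n_ecoregions)
        ranges = rng.integers(1, hi + 1, size=n_taxa)
    elif np.isscalar(range_distribution):
        ranges = np.full(n_taxa, int(range_distribution))
    else:
        arr = np.asarray(range_distribution, dtype=float)
        if arr.size == n_taxa and np.all(arr == np.round(arr)) and arr.min() >= 1:
            ranges = arr.astype(int)
        else:
            if arr.size != n_ecoregions or arr.min() < 0 or not np.isclose(arr.sum(), 1):
                raise MatrixError(
                    "range_distribution must be an int, per-taxon ranges, or a "
                    f"probability vector of length {n_ecoregions}"
                )
            ranges = rng.choice(np.arange(1, n_ecoregions + 1), size=n_taxa, p=arr)
    if ranges.min() < 1 or ranges.max() > n_ecoregions:
        raise MatrixError(
            f"ranges must lie in 1..{n_ecoregions}; got {int(ranges.min())}..{int(ranges.max())}"
        )

    occ = np.zeros((n_taxa, n_ecoregions), dtype=np.int8)
    for i, r in enumerate(ranges):
        occ[i, rng.choice(n_ecoregions, size=int(r), replace=False)] = 1

    occupancy = PresenceAbsenceMatrix(
        occ, [TaxonRecord(t) for t in taxon_ids],
        [Unit(e, kind="ecoregion") for e in eco_ids],
    )
    if region_ecoregions is None:
        region_ecoregions = PresenceAbsenceMatrix(
            np.eye(n_ecoregions, dtype=np.int8),
            [TaxonRecord(f"Reg{i + 1:02d}") for i in range(n_ecoregions)],
            [Unit(e, kind="ecoregion") for e in eco_ids],
        )
    if region_ecoregions.unit_ids != eco_ids:
        raise MatrixError("region_ecoregions columns must match the ecoregion ids")
    R = region_ecoregions.values.astype(int)  # regions x ecoregions
    reg_vals = (occ.astype(int) @ R.T > 0).astype(np.int8)
    regions_matrix = PresenceAbsenceMatrix(
        reg_vals, [TaxonRecord(t) for t in taxon_ids],
        [Unit(r, kind="iran_region") for r in region_ecoregions.taxon_ids],
    )
    truth = SyntheticTruth(
        planted_ranges={t: int(r) for t, r in zip(taxon_ids, ranges)},
        generator_config={
            "n_taxa": n_taxa, "n_ecoregions": n_ecoregions, "seed": seed,
        },
    )
    return occupancy, regions_matrix, truth
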