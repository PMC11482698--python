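"""Species richness, range sizes, and (corrected) weighted endemism.

The range of a taxon is the number of ecoregions it occupies,
irrespective of regions.  Weighted endemism (WE) of a region sums the
reciprocal ranges of the taxa present there; corrected weighted
endemism (CWE) divides WE by the region's richness, making it the mean
inverse range of the region's fauna — a proportion-like measure of how
narrow-ranged the fauna is, invariant to duplicating every taxon.

The species x ecoregion occupancy table is an explicit input.  When no
measured table exists, :func:`derive_occupancy` builds an approximate
one by crossing a taxon x region matrix with a region x ecoregion map
(a taxon is scored for every ecoregion of every region it occupies).
This union overestimates true ranges and is clearly labelled an
approximation; rankings derived from it are exploratory.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import MatrixError, PresenceAbsenceMatrix

__all__ = [
    "RangeSizeTable",
    "EndemismTable",
    "richness",
    "range_sizes",
    "weighted_endemism",
    "corrected_weighted_endemism",
    "derive_occupancy",
    "EndemismAnalysis",
]


@dataclass
class RangeSizeTable:
    """taxon_id -> number of ecoregions occupied (>= 1)."""

    ranges: dict[str, int]

    def __post_init__(self):
        bad = [t for t, r in self.ranges.items() if not (isinstance(r, (int, np.integer)) and r >= 1)]
        if bad:
            raise MatrixError(f"range must be a positive integer; offending taxa: {bad}")
        self.ranges = {t: int(r) for t, r in self.ranges.items()}

    def __getitem__(self, taxon_id: str) -> int:
        try:
            return self.ranges[taxon_id]
        except KeyError:
            raise MatrixError(f"no range for taxon {taxon_id!r}") from None

    def weight(self, taxon_id: str) -> float:
        return 1.0 / self[taxon_id]

    def max_range(self) -> int:
        return max(self.ranges.values())


def richness(m: PresenceAbsenceMatrix) -> pd.DataFrame:
    """Per-unit taxon counts and percentages of the matrix total.

    Percentages are exact (unrounded); round only at presentation.
    """
    counts = m.values.sum(axis=0)
    total = m.shape[0]
    return pd.DataFrame(
        {
            "richness": counts.astype(int),
            "richness_pct": counts / total * 100.0,
        },
        index=pd.Index(m.unit_ids, name="unit_id"),
    )


def range_sizes(occupancy: PresenceAbsenceMatrix) -> RangeSizeTable:
    """Row sums of a taxa x ecoregions occupancy matrix."""
    sums = occupancy.values.sum(axis=1)
    zero = [t for t, s in zip(occupancy.taxon_ids, sums) if s == 0]
    if zero:
        raise MatrixError(f"taxa occupying no ecoregion: {zero}")
    return RangeSizeTable(dict(zip(occupancy.taxon_ids, (int(s) for s in sums))))


def weighted_endemism(m: PresenceAbsenceMatrix, ranges: RangeSizeTable) -> pd.Series:
    """WE per unit: sum of 1/range over the taxa present in that unit."""
    missing = [t for t in m.taxon_ids if t not in ranges.ranges]
    if missing:
        raise MatrixError(f"taxa without a range size: {missing}")
    w = np.array([ranges.weight(t) for t in m.taxon_ids])
    we = w @ m.values.astype(float)
    return pd.Series(we, index=pd.Index(m.unit_ids, name="unit_id"), name="we")


def corrected_weighted_endemism(we: pd.Series, rich: pd.Series) -> pd.Series:
    """CWE per unit: WE / richness; NaN (flagged, not raised) at richness 0."""
    we = pd.Series(we)
    rich = pd.Series(rich).reindex(we.index)
    with np.errstate(divide="ignore", invalid="ignore"):
        cwe = we / rich.replace(0, np.nan)
    cwe.name = "cwe"
    return cwe


def derive_occupancy(
    m: PresenceAbsenceMatrix, region_ecoregions: PresenceAbsenceMatrix
) -> PresenceAbsenceMatrix:
    """Approximate taxa x ecoregion occupancy from region memberships.

    A taxon is scored for an ecoregion iff it occupies any region mapped
    to that ecoregion (union over its regions).  This is an upper bound
    on the true occupancy; use a measured table when one exists.
    """
    missing = [u for u in m.unit_ids if u not in region_ecoregions.taxon_ids]
    if missing:
        raise MatrixError(f"regions absent from the ecoregion map: {missing}")
    rows = [region_ecoregions.taxon_ids.index(u) for u in m.unit_ids]
    R = region_ecoregions.values[rows]  # regions x ecoregions, in m's unit order
    occ = (m.values.astype(int) @ R.astype(int) > 0).astype(np.int8)
    return PresenceAbsenceMatrix(occ, list(m.taxa), list(region_ecoregions.units))


class EndemismAnalysis:
    """Richness/WE/CWE/endemic summary of a taxa x regions matrix.

    ``occupancy`` supplies taxon ranges (taxa x ecoregions); when None,
    ranges are derived from ``region_ecoregions`` via
    :func:`derive_occupancy` (an approximation).
    """

    def __init__(self, matrix: PresenceAbsenceMatrix,
                 occupancy: PresenceAbsenceMatrix | None = None,
                 region_ecoregions: PresenceAbsenceMatrix | None = None):
        if occupancy is None and region_ecoregions is None:
            raise MatrixError("need an occupancy table or a region-ecoregion map")
        self.matrix = matrix
        self.occupancy = occupancy
        self.region_ecoregions = region_ecoregions

    def fit(self) -> "EndemismTable":
        m = self.matrix
        occ = self.occupancy
        approx = occ is None
        if approx:
            occ = derive_occupancy(m, self.region_ecoregions)
        ranges = range_sizes(occ)
        rich = richness(m)
        we = weighted_endemism(m, ranges)
        cwe = corrected_weighted_endemism(we, rich["richness"])
        endemics = [t.taxon_id for t in m.taxa if t.endemic_flag]
        if endemics:
            sub = m.subset_taxa(endemics)
            e_counts = pd.Series(sub.values.sum(axis=0).astype(int),
                                 index=rich.index, name="endemic_count")
        else:
            e_counts = pd.Series(0, index=rich.index, name="endemic_count")
        frame = rich.copy()
        frame["we"] = we
        frame["cwe"] = cwe
        frame["endemic_count"] = e_counts
        with np.errstate(divide="ignore", invalid="ignore"):
            frame["endemic_pct"] = np.where(
                frame["richness"] > 0,
                frame["endemic_count"] / frame["richness"] * 100.0,
                np.nan,
            )
        return EndemismTable(frame, ranges, approximate_ranges=approx)


@dataclass
class EndemismTable:
    """Per-region endemism summary (one row per unit)."""

    frame: pd.DataFrame
    ranges: RangeSizeTable
    approximate_ranges: bool = False

    def to_csv(self, path) -> None:
        out = self.frame.round({"richness_pct": 2, "endemic_pct": 2})
        out.to_csv(path)

    def summary(self) -> str:
        note = " (ranges approximated from region memberships)" if self.approximate_ranges else ""
        top = self.frame.sort_values("cwe", ascending=False).head(3)
        lines = [f"Endemism analysis over {len(self.frame)} units{note}",
                 "  top CWE:"]
        for uid, row in top.iterrows():
            lines.append(
                f"    {uid:4s} richness={int(row.richness):3d} "
                f"we={row.we:.3f} cwe={row.cwe:.3f}"
            )
        return "\n".join(lines)
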