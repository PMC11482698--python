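"""Packaged example data: the Iranian snake checklist and its metadata.

The checklist is a binary taxon x unit table compiled from the
published faunistic literature: 94 taxon rows (species, subspecies and
named clades) scored over 6 surrounding zoogeographic areas (Sa, O, W,
Tu, Ar, Ir) and 13 Iranian physiographic regions (Ce, Ca, A, M, R, Z,
WZ, Kh, T, K, S, B, I).  Two open-nomenclature ("cf.") rows are marked
provisional and excluded from the 92-taxon counted checklist that all
headline analyses use.

The region x ecoregion table is a *synthetic* stand-in (constructed
from regional ecological descriptions, not a measured dataset); the
filename says so.  It maps the 13 regions onto 16 terrestrial
ecoregions and supports the k-means grouping and approximate endemism
weighting.
"""

from __future__ import annotations

import json
from importlib import resources

from .matrix import PresenceAbsenceMatrix, read_matrix

__all__ = [
    "load_unit_metadata",
    "load_snake_checklist",
    "load_region_ecoregions",
    "IRAN_REGIONS",
    "SURROUNDING_AREAS",
    "PUBLISHED_CLUSTERS",
]

IRAN_REGIONS = ["Ce", "Ca", "A", "M", "R", "Z", "WZ", "Kh", "T", "K", "S", "B", "I"]
SURROUNDING_AREAS = ["Sa", "O", "W", "Tu", "Ar", "Ir"]

# Five-cluster grouping of the 13 regions by ecoregion profile (the
# best-inertia k-means solution on the packaged region x ecoregion table).
PUBLISHED_CLUSTERS = {
    1: ["Ce", "S", "B"],
    2: ["Ca", "A", "M", "R"],
    3: ["Z", "WZ", "Kh"],
    4: ["T", "K"],
    5: ["I"],
}


def _data(name: str):
    return resources.files("faunalregions").joinpath("data", name)


def load_unit_metadata() -> dict:
    """The sidecar metadata: unit kinds/names/areas and taxon flags."""
    with _data("unit_metadata.json").open() as fh:
        return json.load(fh)


def load_snake_checklist(counted_only: bool = True) -> PresenceAbsenceMatrix:
    """The packaged snake checklist (92 counted taxa x 19 units).

    ``counted_only=False`` keeps the two provisional "cf." rows as well
    (94 rows); they are excluded by default because every headline
    statistic uses the 92-taxon counted checklist.
    """
    meta = load_unit_metadata()
    with _data("iran_snakes_checklist.csv").open() as fh:
        m = read_matrix(fh, unit_metadata=meta["units"], taxon_metadata=meta["taxa"])
    if counted_only:
        keep = [t.taxon_id for t in m.taxa if not t.provisional]
        m = m.subset_taxa(keep)
    return m


def load_region_ecoregions() -> PresenceAbsenceMatrix:
    """Synthetic 13-region x 16-ecoregion membership table.

    Rows are the Iranian regions (so row-wise operations cluster
    regions); columns are ecoregions.
    """
    path = _data("region_ecoregions_synthetic.csv")
    with path.open() as fh:
        header = fh.readline().strip().split(",")[1:]
    umeta = {c: {"kind": "ecoregion"} for c in header}
    with path.open() as fh:
        return read_matrix(fh, unit_metadata=umeta)
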