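"""Binary presence/absence matrices of taxa by spatial units.

The single substrate of every analysis in this package is a taxon x unit
table of 0/1 occurrence records.  Rows are taxa (species, subspecies or
named clades), columns are spatial units (physiographic regions,
surrounding zoogeographic areas, or ecoregions).  Cells are strictly
binary: there is no missing-value state, because the source checklists
record only presence or absence.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TaxonRecord",
    "Unit",
    "PresenceAbsenceMatrix",
    "MatrixError",
    "read_matrix",
    "write_matrix",
    "aggregate_to_genus",
    "subset_units",
]


class MatrixError(ValueError):
    """Raised for malformed presence/absence data."""


@dataclass(frozen=True)
class TaxonRecord:
    """One row of the checklist.

    ``genus`` is always the first whitespace-delimited token of ``name``;
    parenthesised authorities or clade labels never contribute.
    ``endemic_flag`` is curated metadata (endemism cannot be derived from
    the matrix itself because surrounding-area columns overlap the focal
    country).  ``provisional`` marks open-nomenclature records ("cf."
    identifications) that are excluded from counted totals.
    """

    taxon_id: str
    name: str = ""
    rank_note: str = ""
    endemic_flag: bool | None = None
    provisional: bool = False

    def __post_init__(self):
        if not self.name:
            object.__setattr__(self, "name", self.taxon_id)
        if not self.genus:
            raise MatrixError(f"taxon {self.taxon_id!r} has an empty name")

    @property
    def genus(self) -> str:
        toks = self.name.split()
        return toks[0] if toks else ""


@dataclass(frozen=True)
class Unit:
    """A spatial unit (column) of the matrix."""

    unit_id: str
    kind: str = "iran_region"  # iran_region | surrounding_area | ecoregion
    display_name: str = ""
    area_fraction: float | None = None

    _KINDS = ("iran_region", "surrounding_area", "ecoregion")

    def __post_init__(self):
        if self.kind not in self._KINDS:
            raise MatrixError(f"unknown unit kind {self.kind!r}")
        if self.area_fraction is not None and not (0 < self.area_fraction <= 1):
            raise MatrixError(
                f"area_fraction of unit {self.unit_id!r} must lie in (0, 1]"
            )


class PresenceAbsenceMatrix:
    """Validated binary taxon x unit occurrence matrix.

    Parameters
    ----------
    values
        Array-like of shape (n_taxa, n_units) holding 0/1 cells.
    taxa
        Taxon labels (strings) or :class:`TaxonRecord` objects, one per row.
    units
        Unit codes (strings) or :class:`Unit` objects, one per column.
    """

    def __init__(self, values, taxa: Sequence, units: Sequence):
        vals = np.asarray(values)
        if vals.ndim != 2:
            raise MatrixError("matrix values must be two-dimensional")
        if vals.size == 0:
            raise MatrixError("empty presence/absence matrix")
        self.taxa = [t if isinstance(t, TaxonRecord) else TaxonRecord(str(t)) for t in taxa]
        self.units = [u if isinstance(u, Unit) else Unit(str(u)) for u in units]
        if vals.shape != (len(self.taxa), len(self.units)):
            raise MatrixError(
                f"shape {vals.shape} does not match {len(self.taxa)} taxa x "
                f"{len(self.units)} units"
            )
        bad = ~np.isin(vals, (0, 1))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise MatrixError(
                f"non-binary cell at taxon {self.taxa[i].taxon_id!r}, "
                f"unit {self.units[j].unit_id!r}: {vals[i, j]!r}"
            )
        ids = [t.taxon_id for t in self.taxa]
        if len(set(ids)) != len(ids):
            dup = sorted({x for x in ids if ids.count(x) > 1})
            raise MatrixError(f"duplicate taxon label(s): {dup}")
        uids = [u.unit_id for u in self.units]
        if len(set(uids)) != len(uids):
            dup = sorted({x for x in uids if uids.count(x) > 1})
            raise MatrixError(f"duplicate unit code(s): {dup}")
        self.values = vals.astype(np.int8)

    # -- basic accessors -------------------------------------------------
    @property
    def taxon_ids(self) -> list[str]:
        return [t.taxon_id for t in self.taxa]

    @property
    def unit_ids(self) -> list[str]:
        return [u.unit_id for u in self.units]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def taxon(self, taxon_id: str) -> TaxonRecord:
        try:
            return self.taxa[self.taxon_ids.index(taxon_id)]
        except ValueError:
            raise MatrixError(f"unknown taxon {taxon_id!r}") from None

    def unit(self, unit_id: str) -> Unit:
        try:
            return self.units[self.unit_ids.index(unit_id)]
        except ValueError:
            raise MatrixError(f"unknown unit {unit_id!r}") from None

    def row(self, taxon_id: str) -> np.ndarray:
        return self.values[self.taxon_ids.index(taxon_id)]

    def column(self, unit_id: str) -> np.ndarray:
        return self.values[:, self.unit_ids.index(unit_id)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values.copy(), index=self.taxon_ids, columns=self.unit_ids
        )

    def __repr__(self):
        return (
            f"<PresenceAbsenceMatrix {self.shape[0]} taxa x {self.shape[1]} "
            f"units, {int(self.values.sum())} presences>"
        )

    # -- derived matrices ------------------------------------------------
    def aggregate_to_genus(self) -> "PresenceAbsenceMatrix":
        return aggregate_to_genus(self)

    def subset_units(self, keep: Iterable[str], drop_empty_taxa: bool = False):
        return subset_units(self, keep, drop_empty_taxa=drop_empty_taxa)

    def subset_taxa(self, keep: Iterable[str]) -> "PresenceAbsenceMatrix":
        keep = list(keep)
        idx = {t: i for i, t in enumerate(self.taxon_ids)}
        unknown = [t for t in keep if t not in idx]
        if unknown:
            raise MatrixError(f"unknown taxon id(s): {unknown}")
        rows = [idx[t] for t in keep]
        return PresenceAbsenceMatrix(
            self.values[rows], [self.taxa[i] for i in rows], list(self.units)
        )


def read_matrix(
    source,
    presence_chars: tuple = ("1",),
    absence_chars: tuple = ("0", ""),
    star_dialect: bool = False,
    unit_metadata: dict | None = None,
    taxon_metadata: dict | None = None,
) -> PresenceAbsenceMatrix:
    """Read a presence/absence matrix from CSV text.

    The expected layout is a header ``taxon,<unit codes...>`` followed by
    one row per taxon.  With ``star_dialect=True``, cells ``*`` and blank
    are read as 1 and 0, matching the convention of printed checklists.

    ``unit_metadata``/``taxon_metadata`` optionally attach unit kinds,
    display names and area fractions, and taxon endemic/provisional flags
    (the sidecar-JSON structure produced by :func:`write_matrix`).
    """
    if isinstance(source, (str, bytes)):
        import os

        if isinstance(source, str) and (os.path.exists(source) or "\n" not in source):
            fh = open(source, newline="")
        else:
            fh = io.StringIO(source if isinstance(source, str) else source.decode())
    else:
        fh = source
    df = pd.read_csv(fh, dtype=str, keep_default_na=False)
    if df.shape[1] < 2 or df.shape[0] < 1:
        raise MatrixError("empty matrix: need at least one taxon and one unit")
    taxon_col = df.columns[0]
    unit_codes = [str(c) for c in df.columns[1:]]
    names = [str(x) for x in df[taxon_col]]

    if star_dialect:
        pres, absent = ("*",), ("", " ")
    else:
        pres, absent = presence_chars, absence_chars
    vals = np.zeros((len(names), len(unit_codes)), dtype=np.int8)
    for j, c in enumerate(unit_codes):
        col = df[c].astype(str).str.strip()
        is_p = col.isin(pres)
        is_a = col.isin([a.strip() for a in absent])
        bad = ~(is_p | is_a)
        if bad.any():
            i = int(np.argmax(bad.values))
            raise MatrixError(
                f"non-binary cell at taxon {names[i]!r}, unit {c!r}: {col.iloc[i]!r}"
            )
        vals[:, j] = is_p.values

    tmeta = taxon_metadata or {}
    provisional = set(tmeta.get("provisional", []))
    endemic = set(tmeta.get("endemic", []))
    taxa = [
        TaxonRecord(
            n,
            endemic_flag=(n in endemic) if endemic else None,
            provisional=n in provisional,
        )
        for n in names
    ]
    umeta = unit_metadata or {}
    units = [
        Unit(
            c,
            kind=umeta.get(c, {}).get("kind", "iran_region"),
            display_name=umeta.get(c, {}).get("display_name", ""),
            area_fraction=umeta.get(c, {}).get("area_fraction"),
        )
        for c in unit_codes
    ]
    return PresenceAbsenceMatrix(vals, taxa, units)


def write_matrix(m: PresenceAbsenceMatrix, path, sidecar_json: bool = False) -> None:
    """Write the matrix as CSV; optionally a metadata sidecar JSON."""
    m.to_frame().rename_axis("taxon").reset_index().to_csv(path, index=False)
    if sidecar_json:
        meta = {
            "units": {
                u.unit_id: {
                    "kind": u.kind,
                    "display_name": u.display_name,
                    **({"area_fraction": u.area_fraction} if u.area_fraction else {}),
                }
                for u in m.units
            },
            "taxa": {
                "provisional": [t.taxon_id for t in m.taxa if t.provisional],
                "endemic": [t.taxon_id for t in m.taxa if t.endemic_flag],
            },
        }
        with open(str(path) + ".json", "w") as fh:
            json.dump(meta, fh, indent=1)


def aggregate_to_genus(m: PresenceAbsenceMatrix) -> PresenceAbsenceMatrix:
    """Collapse taxon rows to genus rows by cell-wise logical OR.

    A genus is present in a unit iff any member taxon is present there.
    Genus rows are ordered by first appearance; the unit set is unchanged.
    The operation is idempotent.
    """
    order: list[str] = []
    rows: dict[str, np.ndarray] = {}
    for t, row in zip(m.taxa, m.values):
        g = t.genus
        if g not in rows:
            order.append(g)
            rows[g] = row.copy()
        else:
            rows[g] = np.maximum(rows[g], row)
    vals = np.array([rows[g] for g in order], dtype=np.int8)
    taxa = [TaxonRecord(g, rank_note="genus") for g in order]
    return PresenceAbsenceMatrix(vals, taxa, list(m.units))


def subset_units(
    m: PresenceAbsenceMatrix, keep: Iterable[str], drop_empty_taxa: bool = False
) -> PresenceAbsenceMatrix:
    """Restrict (and reorder) columns to ``keep``.

    Taxon rows that become all-zero are retained by default so that
    "total taxa" denominators stay stable; pass ``drop_empty_taxa=True``
    to drop them.
    """
    keep = list(keep)
    if not keep:
        raise MatrixError("keep must list at least one unit")
    idx = {u: i for i, u in enumerate(m.unit_ids)}
    unknown = [u for u in keep if u not in idx]
    if unknown:
        raise MatrixError(f"unknown unit id(s): {unknown}")
    cols = [idx[u] for u in keep]
    vals = m.values[:, cols]
    taxa = list(m.taxa)
    if drop_empty_taxa:
        nz = vals.sum(axis=1) > 0
        vals = vals[nz]
        taxa = [t for t, k in zip(taxa, nz) if k]
        if len(taxa) == 0:
            raise MatrixError("all taxa empty after subsetting")
    return PresenceAbsenceMatrix(vals, taxa, [m.units[i] for i in cols])
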