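"""Assemblage matrices and their metadata.

The central object is :class:`AssemblageMatrix`, a taxon-by-context grid of
MNI counts (Minimum Number of Individuals — the smallest number of animals
that can account for the identified specimens of a taxon in an excavation
context). Every downstream stage — proportions, similarity graphs, community
detection — starts from one of these matrices.

File formats are plain UTF-8 CSV:

* MNI matrix: first column ``taxon_id``, header row of context ids, integer
  cells. Empty cells, ``-`` and the em dash ``—`` all mean "absent" (0), the
  convention used in printed species lists.
* Taxon metadata: columns ``taxon_id, scientific_name, common_name, class,
  habitats, food_status`` where ``habitats`` is a semicolon-joined subset of
  the five estuarine habitat classes.
* Context metadata: columns ``context_id, site_area, period_label,
  strat_order``.

Lines starting with ``#`` are comments in the metadata files.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "HABITATS",
    "SITE_AREAS",
    "AssemblageMatrix",
    "TaxonRecord",
    "ContextRecord",
    "ValidationReport",
    "read_mni_matrix",
    "write_mni_matrix",
    "read_taxon_metadata",
    "read_context_metadata",
    "validate",
    "context_totals",
]

#: The five estuarine habitat (salinity-regime) classes used for invertebrates.
HABITATS = (
    "tidal_stream",
    "estuarine_mangrove",
    "oyster_bed",
    "seagrass_meadow",
    "littoral",
)

SITE_AREAS = (
    "old_mound",
    "surf_clam_ridge",
    "low_mound",
    "browns_complex",
    "browns_mound_2",
    "randell_complex",
    "operation_p",
)

#: Cell values treated as "absent" when reading an MNI matrix.
ABSENT = {"", "-", "—"}


@dataclass(frozen=True)
class TaxonRecord:
    """Per-taxon metadata: names, coarse class, habitat membership."""

    taxon_id: str
    scientific_name: str = ""
    common_name: str = ""
    kingdom_class: str = "invertebrate"  # "invertebrate" | "vertebrate"
    habitats: frozenset[str] = frozenset()
    food_status: str | None = None  # "food" | "non_food" | "unknown" | None

    def __post_init__(self) -> None:
        if self.kingdom_class not in ("invertebrate", "vertebrate"):
            raise ValueError(f"bad class {self.kingdom_class!r} for {self.taxon_id!r}")
        bad = set(self.habitats) - set(HABITATS)
        if bad:
            raise ValueError(f"unknown habitat(s) {sorted(bad)} for {self.taxon_id!r}")


@dataclass(frozen=True)
class ContextRecord:
    """Per-context metadata: site area, period label, stratigraphic order."""

    context_id: str
    site_area: str
    period_label: str = ""
    strat_order: int | None = None

    def __post_init__(self) -> None:
        if self.site_area not in SITE_AREAS:
            raise ValueError(f"unknown site_area {self.site_area!r} for {self.context_id!r}")


@dataclass
class ValidationReport:
    errors: list[tuple[str, str, str]] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def is_valid(self) -> bool:
        return not self.errors


class AssemblageMatrix:
    """A taxon-by-context grid of non-negative integer MNI counts.

    Wraps a :class:`pandas.DataFrame` with taxa on the index and contexts on
    the columns. Row and column order is meaningful and preserved; identifiers
    must be unique.
    """

    def __init__(self, counts: pd.DataFrame):
        if counts.shape[0] < 1 or counts.shape[1] < 1:
            raise ValueError("matrix needs at least one taxon and one context")
        if counts.index.has_duplicates:
            dupes = counts.index[counts.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate taxon identifier(s): {dupes}")
        if counts.columns.has_duplicates:
            dupes = counts.columns[counts.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate context identifier(s): {dupes}")
        arr = counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(np.equal(np.mod(arr, 1), 0)):
                raise ValueError("counts must be integral")
        if (arr < 0).any():
            raise ValueError("counts must be non-negative")
        self._counts = counts.astype(np.int64)
        self._counts.index.name = "taxon_id"

    # -- basic accessors ---------------------------------------------------
    @property
    def counts(self) -> pd.DataFrame:
        return self._counts

    @property
    def taxa(self) -> list[str]:
        return list(self._counts.index)

    @property
    def contexts(self) -> list[str]:
        return list(self._counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self._counts.shape

    def __eq__(self, other) -> bool:
        return isinstance(other, AssemblageMatrix) and self._counts.equals(other._counts)

    def __repr__(self) -> str:
        return f"AssemblageMatrix({self.shape[0]} taxa x {self.shape[1]} contexts)"

    # -- subsetting --------------------------------------------------------
    def select_taxa(self, taxa: Iterable[str]) -> "AssemblageMatrix":
        taxa = list(taxa)
        missing = [t for t in taxa if t not in self._counts.index]
        if missing:
            raise KeyError(f"taxa not in matrix: {missing}")
        return AssemblageMatrix(self._counts.loc[taxa])

    def select_contexts(self, contexts: Iterable[str]) -> "AssemblageMatrix":
        contexts = list(contexts)
        missing = [c for c in contexts if c not in self._counts.columns]
        if missing:
            raise KeyError(f"contexts not in matrix: {missing}")
        return AssemblageMatrix(self._counts[contexts])


def read_mni_matrix(path: str | Path) -> AssemblageMatrix:
    """Read an MNI matrix CSV.

    Empty, ``-`` and ``—`` cells parse as 0. Duplicate taxon or context
    identifiers and non-integer cells are hard errors naming the offender.
    """
    with open(path, encoding="utf-8", newline="") as fh:
        rows = [r for r in csv.reader(fh) if r and not r[0].startswith("#")]
    if not rows:
        raise ValueError(f"{path}: empty file")
    header = rows[0]
    contexts = [c.strip() for c in header[1:]]
    seen: set[str] = set()
    for c in contexts:
        if c in seen:
            raise ValueError(f"{path}: duplicate context identifier {c!r}")
        seen.add(c)
    taxa: list[str] = []
    data: list[list[int]] = []
    seen_t: set[str] = set()
    for r in rows[1:]:
        tid = r[0].strip()
        if tid in seen_t:
            raise ValueError(f"{path}: duplicate taxon identifier {tid!r}")
        seen_t.add(tid)
        taxa.append(tid)
        vals: list[int] = []
        for ctx, cell in zip(contexts, r[1:]):
            cell = cell.strip()
            if cell in ABSENT:
                vals.append(0)
                continue
            try:
                vals.append(int(cell))
            except ValueError:
                raise ValueError(
                    f"{path}: non-integer cell {cell!r} at taxon {tid!r}, context {ctx!r}"
                ) from None
        if len(vals) != len(contexts):
            raise ValueError(f"{path}: row {tid!r} has {len(vals)} cells, expected {len(contexts)}")
        data.append(vals)
    df = pd.DataFrame(data, index=taxa, columns=contexts, dtype=np.int64)
    return AssemblageMatrix(df)


def write_mni_matrix(matrix: AssemblageMatrix, path: str | Path) -> None:
    """Write a matrix back to the CSV layout read by :func:`read_mni_matrix`."""
    matrix.counts.to_csv(path, encoding="utf-8", lineterminator="\n")


def _read_meta_rows(path: str | Path) -> list[dict[str, str]]:
    with open(path, encoding="utf-8", newline="") as fh:
        lines = [l for l in fh if not l.startswith("#")]
    return list(csv.DictReader(lines))


def read_taxon_metadata(path: str | Path) -> list[TaxonRecord]:
    """Read taxon metadata. Unknown habitat names are hard errors; a missing
    habitat cell means "unclassified" (empty set)."""
    records = []
    for row in _read_meta_rows(path):
        hab_cell = (row.get("habitats") or "").strip()
        habitats = frozenset(h.strip() for h in hab_cell.split(";") if h.strip())
        records.append(
            TaxonRecord(
                taxon_id=row["taxon_id"].strip(),
                scientific_name=(row.get("scientific_name") or "").strip(),
                common_name=(row.get("common_name") or "").strip(),
                kingdom_class=(row.get("class") or "invertebrate").strip(),
                habitats=habitats,
                food_status=(row.get("food_status") or None),
            )
        )
    return records


def read_context_metadata(path: str | Path) -> list[ContextRecord]:
    records = []
    for row in _read_meta_rows(path):
        so = (row.get("strat_order") or "").strip()
        records.append(
            ContextRecord(
                context_id=row["context_id"].strip(),
                site_area=row["site_area"].strip(),
                period_label=(row.get("period_label") or "").strip(),
                strat_order=int(so) if so else None,
            )
        )
    return records


def validate(
    matrix: "AssemblageMatrix | pd.DataFrame",
    taxa: Sequence[TaxonRecord] = (),
    contexts: Sequence[ContextRecord] = (),
) -> ValidationReport:
    """Cross-check a matrix against its metadata.

    Counts that violate the matrix invariants (negative or fractional cells)
    are errors; taxa or contexts missing from the metadata are warnings
    (analyses can proceed without them, they just lose attributes). A raw
    DataFrame may be passed to audit data that would not survive the
    :class:`AssemblageMatrix` constructor.
    """
    report = ValidationReport()
    counts = matrix.counts if isinstance(matrix, AssemblageMatrix) else matrix
    row_ids = list(counts.index)
    col_ids = list(counts.columns)
    arr = counts.to_numpy()
    for i, j in np.argwhere(arr < 0):
        report.errors.append((row_ids[i], col_ids[j], f"negative count {arr[i, j]}"))
    if not np.issubdtype(arr.dtype, np.integer):
        for i, j in np.argwhere(np.mod(arr, 1) != 0):
            report.errors.append((row_ids[i], col_ids[j], f"fractional count {arr[i, j]}"))
    if taxa:
        known = {t.taxon_id for t in taxa}
        for t in row_ids:
            if t not in known:
                report.warnings.append(f"taxon {t!r} has no metadata record")
        for t in sorted(known - set(row_ids)):
            report.warnings.append(f"metadata taxon {t!r} absent from matrix")
    if contexts:
        known_c = {c.context_id for c in contexts}
        for c in col_ids:
            if c not in known_c:
                report.warnings.append(f"context {c!r} has no metadata record")
    return report


def context_totals(matrix: AssemblageMatrix) -> dict[str, int]:
    """Total MNI per context (exact integer column sums)."""
    return {c: int(v) for c, v in matrix.counts.sum(axis=0).items()}
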