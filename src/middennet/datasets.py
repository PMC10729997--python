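"""Bundled Pineland Site Complex fixture data.

The MNI matrix is a hand-checked transcription of the published species list
for the 15 Pineland contexts (11 site-wide mound/midden layers plus the four
Operation P stratigraphic levels). One transcription note: the printed column
total for Operation P (P-10-105) is 9949 while the printed cells of that
column sum to 9950; the cells are kept verbatim, so ``context_totals``
reports 9950 there.

The taxon metadata table is a curated, editable stand-in: the published
study assigned invertebrate habitat classes following a companion
publication that does not print them, so the bundled ``habitats`` column is
this package's own curation from standard ecology of each taxon.
"""

from __future__ import annotations

from importlib import resources

from .assemblage import (
    AssemblageMatrix,
    ContextRecord,
    TaxonRecord,
    read_context_metadata,
    read_mni_matrix,
    read_taxon_metadata,
)

__all__ = [
    "load_pineland",
    "load_pineland_taxa",
    "load_pineland_contexts",
    "operation_p_contexts",
    "sitewide_contexts",
    "PRINTED_TOTALS",
]

#: Printed per-context totals of the source table, in column order.
PRINTED_TOTALS = {
    "Old Mound 1 (A-8-101)": 3480,
    "Surf Clam Ridge (Trench 11B-93)": 164,
    "Low Mound (A-1-77-1)": 2957,
    "Old Mound 2 (A-16-92)": 1561,
    "Brown's Complex 1 (C-6-92-1)": 2241,
    "Brown's Complex 2 (C-5-88-2)": 230,
    "Brown's Complex 3 (C-5-79-1)": 3293,
    "Randell Complex 1 (A-Prof-63)": 1762,
    "Randell Complex 2 (A-Prof-55)": 1518,
    "Brown's Complex Mound 2a (I-2-73)": 479,
    "Brown's Complex Mound 2b (I-2-66)": 1797,
    "Operation P (P-10-99)": 1949,
    "Operation P (P-10-101)": 1156,
    "Operation P (P-10-103)": 2631,
    "Operation P (P-10-105)": 9949,
}


def _data_path(name: str):
    return resources.files("middennet") / "data" / name


def load_pineland() -> AssemblageMatrix:
    """The 336-taxon x 15-context Pineland MNI matrix."""
    with resources.as_file(_data_path("pineland_mni.csv")) as p:
        return read_mni_matrix(p)


def load_pineland_taxa() -> list[TaxonRecord]:
    with resources.as_file(_data_path("pineland_taxa.csv")) as p:
        return read_taxon_metadata(p)


def load_pineland_contexts() -> list[ContextRecord]:
    with resources.as_file(_data_path("pineland_contexts.csv")) as p:
        return read_context_metadata(p)


def operation_p_contexts() -> list[str]:
    """The four Operation P levels, in column order (99, 101, 103, 105)."""
    return [c.context_id for c in load_pineland_contexts() if c.site_area == "operation_p"]


def sitewide_contexts() -> list[str]:
    """The eleven site-wide (non-Operation P) contexts, in column order."""
    return [c.context_id for c in load_pineland_contexts() if c.site_area != "operation_p"]
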