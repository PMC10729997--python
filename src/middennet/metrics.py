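"""Per-context and per-taxon assemblage statistics.

Percent MNI (a taxon's share of a context's total MNI) is the comparison
metric throughout; it is deliberately preferred over NISP-based measures,
which inflate fragmentation-prone taxa. On top of it sit the node-attribute
metrics (Shannon diversity, richness, ubiquity) and the habitat summaries
(exclusive-habitat filtering and collapsing taxon proportions to habitat
proportions).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .assemblage import HABITATS, AssemblageMatrix, TaxonRecord

__all__ = [
    "ProportionMatrix",
    "HabitatProfile",
    "percent_mni",
    "shannon_diversity",
    "richness",
    "ubiquity",
    "ubiquity_table",
    "filter_exclusive_habitat",
    "collapse_to_habitats",
    "metrics_table",
]


@dataclass
class ProportionMatrix:
    """Percent-MNI grid: each non-flagged column sums to 1.

    ``flagged`` lists contexts whose scoped total was zero; their columns are
    left as NaN rather than silently zeroed.
    """

    proportions: pd.DataFrame
    flagged: list[str]

    @property
    def taxa(self) -> list[str]:
        return list(self.proportions.index)

    @property
    def contexts(self) -> list[str]:
        return list(self.proportions.columns)


@dataclass
class HabitatProfile:
    """Habitat-by-context percent-MNI grid over habitat-classified taxa."""

    shares: pd.DataFrame  # index = habitats, columns = contexts
    flagged: list[str]


def percent_mni(
    matrix: AssemblageMatrix, taxa: Sequence[str] | None = None
) -> ProportionMatrix:
    """Percent MNI within a taxon scope, per context.

    ``taxa`` restricts the scope (e.g. invertebrates only); denominators are
    the scoped column totals. Contexts whose scoped total is zero are flagged
    and their proportions left undefined (NaN).
    """
    m = matrix if taxa is None else matrix.select_taxa(taxa)
    counts = m.counts.astype(float)
    totals = counts.sum(axis=0)
    flagged = [c for c in counts.columns if totals[c] == 0]
    with np.errstate(invalid="ignore", divide="ignore"):
        props = counts / totals
    props[flagged] = np.nan
    return ProportionMatrix(proportions=props, flagged=flagged)


def shannon_diversity(p: Sequence[float] | pd.Series, *, tol: float = 1e-9) -> float:
    """Shannon entropy H = -sum(p ln p) in nats of a proportion vector.

    The input must already be normalized (sum to 1 within ``tol``); zero
    entries contribute nothing.
    """
    arr = np.asarray(p, dtype=float)
    if arr.ndim != 1:
        raise ValueError("expected a 1-D proportion vector")
    if np.isnan(arr).any():
        raise ValueError("proportion vector contains NaN (flagged column?)")
    if (arr < 0).any():
        raise ValueError("proportions must be non-negative")
    if abs(arr.sum() - 1.0) > tol:
        raise ValueError(f"proportions sum to {arr.sum():.6g}, not 1")
    pos = arr[arr > 0]
    return float(-(pos * np.log(pos)).sum())


def richness(counts: Sequence[float] | pd.Series) -> int:
    """Number of taxa present (count >= 1) in a count vector."""
    arr = np.asarray(counts)
    return int((arr >= 1).sum())


def ubiquity(matrix: AssemblageMatrix, taxon_id: str) -> float:
    """Fraction of contexts in which a taxon occurs (MNI >= 1)."""
    if taxon_id not in matrix.counts.index:
        raise KeyError(f"unknown taxon {taxon_id!r}")
    row = matrix.counts.loc[taxon_id]
    return float((row >= 1).sum() / len(row))


def ubiquity_table(matrix: AssemblageMatrix) -> pd.Series:
    """Ubiquity for every taxon, as a Series indexed by taxon_id."""
    return (matrix.counts >= 1).sum(axis=1) / matrix.shape[1]


def filter_exclusive_habitat(
    matrix: AssemblageMatrix, taxa: Sequence[TaxonRecord]
) -> AssemblageMatrix:
    """Keep exactly the invertebrate taxa classified to a single habitat.

    Multi-habitat and unclassified taxa (and all vertebrates) are dropped;
    the context set is unchanged.
    """
    by_id = {t.taxon_id: t for t in taxa}
    keep = [
        tid
        for tid in matrix.taxa
        if (rec := by_id.get(tid)) is not None
        and rec.kingdom_class == "invertebrate"
        and len(rec.habitats) == 1
    ]
    if not keep:
        raise ValueError("no exclusive-habitat invertebrate taxa in matrix")
    return matrix.select_taxa(keep)


def collapse_to_habitats(
    matrix: AssemblageMatrix,
    taxa: Sequence[TaxonRecord],
    *,
    exclusive_only: bool = True,
    split_multi: bool = False,
) -> HabitatProfile:
    """Collapse taxon percent MNI into habitat percent MNI per context.

    By default the scope is the exclusive-habitat invertebrates (the same
    filter used for the habitat networks). With ``exclusive_only=False`` all
    habitat-classified invertebrates enter, and ``split_multi=True`` splits a
    multi-habitat taxon's MNI equally across its habitats; otherwise
    multi-habitat taxa are excluded. Habitat shares in each context sum to 1
    over the scoped (classified) MNI; contexts with zero scoped MNI are
    flagged.
    """
    by_id = {t.taxon_id: t for t in taxa}
    weights = pd.DataFrame(0.0, index=list(HABITATS), columns=matrix.taxa)
    for tid in matrix.taxa:
        rec = by_id.get(tid)
        if rec is None or rec.kingdom_class != "invertebrate" or not rec.habitats:
            continue
        if len(rec.habitats) > 1:
            if exclusive_only:
                continue
            if not split_multi:
                continue
            w = 1.0 / len(rec.habitats)
        else:
            w = 1.0
        for h in rec.habitats:
            weights.loc[h, tid] = w
    hab_mni = weights.to_numpy() @ matrix.counts.to_numpy().astype(float)
    shares = pd.DataFrame(hab_mni, index=list(HABITATS), columns=matrix.contexts)
    totals = shares.sum(axis=0)
    flagged = [c for c in shares.columns if totals[c] == 0]
    with np.errstate(invalid="ignore", divide="ignore"):
        shares = shares / totals
    shares[flagged] = np.nan
    return HabitatProfile(shares=shares, flagged=flagged)


def metrics_table(
    matrix: AssemblageMatrix, taxa: Sequence[str] | None = None
) -> pd.DataFrame:
    """Per-context summary (total MNI, richness, Shannon diversity).

    ``taxa`` optionally scopes the computation, mirroring :func:`percent_mni`.
    """
    m = matrix if taxa is None else matrix.select_taxa(taxa)
    props = percent_mni(m)
    out = []
    for c in m.contexts:
        col = m.counts[c]
        h = (
            float("nan")
            if c in props.flagged
            else shannon_diversity(props.proportions[c])
        )
        out.append(
            {
                "context_id": c,
                "total_mni": int(col.sum()),
                "richness": richness(col),
                "shannon_diversity": h,
            }
        )
    return pd.DataFrame(out).set_index("context_id")
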