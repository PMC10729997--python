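"""Two-mode and one-mode network construction from assemblage matrices.

Graphs are :class:`networkx.Graph` objects. Node attributes follow one
convention throughout: ``node_class`` is one of ``context``, ``species``,
``habitat`` or ``subgroup``; optional ``color_key`` (period label, habitat,
group id) and ``size_value`` (diversity, ubiquity) carry display metadata.
Two-mode (bipartite) graphs only ever tie nodes of different classes.

Similarity matrices are square symmetric :class:`pandas.DataFrame` objects
with unit diagonal and values in [0, 1]:

* Jaccard — presence/absence overlap ``|A∩B| / |A∪B|`` between contexts or
  between taxa;
* Renkonen percentage similarity — ``sum_c min(x_c, y_c)`` between taxon
  abundance profiles normalized to sum 1 across contexts, the standard
  community-ecology measure of abundance overlap.

Thresholding is strict (``>``) by default, matching the published wording
"greater than"; the ≥5 %-of-assemblage rule for subgroup ties is the one
inclusive cutoff.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Hashable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .assemblage import AssemblageMatrix, TaxonRecord
from .metrics import ProportionMatrix, percent_mni

__all__ = [
    "ThresholdSweep",
    "build_two_mode",
    "build_habitat_membership",
    "jaccard_similarity",
    "abundance_similarity",
    "threshold_graph",
    "max_connected_threshold",
    "project_subgroup_ties",
    "check_similarity",
    "write_graph",
]


def check_similarity(sim: pd.DataFrame, *, tol: float = 1e-12) -> None:
    """Assert the similarity-matrix invariants (symmetry, unit diagonal,
    values in [0, 1]); raises ValueError on violation."""
    if list(sim.index) != list(sim.columns):
        raise ValueError("similarity matrix must have identical row/column items")
    a = sim.to_numpy(dtype=float)
    if not np.allclose(a, a.T, atol=tol, equal_nan=True):
        raise ValueError("similarity matrix is not symmetric")
    if not np.allclose(np.diag(a), 1.0, atol=tol):
        raise ValueError("similarity diagonal must be 1")
    off = a[~np.eye(len(a), dtype=bool)]
    if ((off < -tol) | (off > 1 + tol)).any():
        raise ValueError("similarities must lie in [0, 1]")


def build_two_mode(
    matrix: AssemblageMatrix,
    tie_rule: str = "presence",
    *,
    context_attrs: Mapping[str, Mapping] | None = None,
    species_attrs: Mapping[str, Mapping] | None = None,
) -> nx.Graph:
    """Bipartite context-species graph.

    ``tie_rule="presence"`` draws an unweighted tie wherever MNI >= 1;
    ``"weight"`` weights each tie by the taxon's percent MNI in that
    context. Every taxon and context appears as a node even if isolated.
    """
    if tie_rule not in ("presence", "weight"):
        raise ValueError(f"unknown tie_rule {tie_rule!r}")
    g = nx.Graph()
    for c in matrix.contexts:
        g.add_node(c, node_class="context", **dict((context_attrs or {}).get(c, {})))
    for t in matrix.taxa:
        g.add_node(t, node_class="species", **dict((species_attrs or {}).get(t, {})))
    if tie_rule == "weight":
        props = percent_mni(matrix).proportions
    for t in matrix.taxa:
        row = matrix.counts.loc[t]
        for c in matrix.contexts:
            if row[c] >= 1:
                if tie_rule == "presence":
                    g.add_edge(t, c)
                else:
                    g.add_edge(t, c, weight=float(props.loc[t, c]))
    return g


def build_habitat_membership(
    matrix: AssemblageMatrix, taxa: Sequence[TaxonRecord]
) -> nx.Graph:
    """Bipartite habitat-species graph: each invertebrate present anywhere in
    the matrix is tied to every habitat it is classified to."""
    by_id = {t.taxon_id: t for t in taxa}
    present = matrix.counts.sum(axis=1) >= 1
    g = nx.Graph()
    for tid in matrix.taxa:
        rec = by_id.get(tid)
        if rec is None or rec.kingdom_class != "invertebrate" or not present[tid]:
            continue
        g.add_node(tid, node_class="species")
        for h in sorted(rec.habitats):
            if h not in g:
                g.add_node(h, node_class="habitat")
            g.add_edge(tid, h)
    return g


def jaccard_similarity(
    matrix: AssemblageMatrix, axis: str = "contexts", presence_threshold: int = 1
) -> pd.DataFrame:
    """Pairwise Jaccard similarity of presence sets between contexts or taxa.

    Presence means MNI >= ``presence_threshold``. The Jaccard coefficient of
    two empty presence sets is defined as 1 (identical emptiness) and
    emitted with a warning; such items are normally excluded upstream.
    """
    if axis not in ("contexts", "taxa"):
        raise ValueError(f"axis must be 'contexts' or 'taxa', got {axis!r}")
    pres = (matrix.counts.to_numpy() >= presence_threshold)
    if axis == "contexts":
        pres = pres.T
        items = matrix.contexts
    else:
        items = matrix.taxa
    if len(items) < 2:
        raise ValueError("need at least two items for pairwise similarity")
    p = pres.astype(np.float64)
    inter = p @ p.T
    sizes = p.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    if (sizes == 0).any():
        warnings.warn(
            "items with empty presence sets; their mutual Jaccard is defined as 1",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / np.where(union > 0, union, 1), 1.0)
    np.fill_diagonal(sim, 1.0)
    return pd.DataFrame(sim, index=items, columns=items)


def abundance_similarity(prop: ProportionMatrix) -> pd.DataFrame:
    """Renkonen percentage similarity between taxon abundance profiles.

    Each taxon's percent-MNI profile across contexts is renormalized to sum
    1 (flagged contexts are dropped first); the similarity of two taxa is
    the summed elementwise minimum of their normalized profiles. Taxa whose
    scoped total is zero are excluded with a warning.
    """
    props = prop.proportions.drop(columns=prop.flagged)
    totals = props.sum(axis=1)
    dropped = [t for t in props.index if totals[t] == 0]
    if dropped:
        warnings.warn(
            f"excluding {len(dropped)} taxa with zero scoped abundance", stacklevel=2
        )
        props = props.drop(index=dropped)
        totals = totals.drop(index=dropped)
    if props.shape[0] < 2:
        raise ValueError("need at least two taxa with positive abundance")
    x = props.to_numpy() / totals.to_numpy()[:, None]
    sim = np.minimum(x[:, None, :], x[None, :, :]).sum(axis=2)
    np.fill_diagonal(sim, 1.0)
    sim = np.clip(sim, 0.0, 1.0)
    sim = (sim + sim.T) / 2.0  # exact symmetry against float noise
    return pd.DataFrame(sim, index=props.index, columns=props.index)


def threshold_graph(
    sim: pd.DataFrame,
    t: float,
    strict: bool = True,
    *,
    node_attrs: Mapping[str, Mapping] | None = None,
    node_class: str = "species",
) -> nx.Graph:
    """One-mode graph with a tie wherever similarity exceeds ``t``.

    Strict means ``> t`` (the default — "greater than" cutoffs), non-strict
    ``>= t``. Every item stays in the graph, isolates included.
    """
    if not 0.0 <= t <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {t}")
    items = list(sim.index)
    g = nx.Graph()
    for it in items:
        g.add_node(it, node_class=node_class, **dict((node_attrs or {}).get(it, {})))
    a = sim.to_numpy(dtype=float)
    for i in range(len(items)):
        for j in range(i + 1, len(items)):
            v = a[i, j]
            if (v > t) if strict else (v >= t):
                g.add_edge(items[i], items[j], weight=float(v))
    return g


@dataclass
class ThresholdSweep:
    """Result of sweeping tie cutoffs over the distinct similarity values."""

    candidate_values: list[float]
    connected_at: list[bool]
    t_star: float
    scope: list  # items actually swept (positive-similarity scope)
    excluded: list  # items dropped for having no positive similarity

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"threshold": self.candidate_values, "connected": self.connected_at}
        )


def max_connected_threshold(
    sim: pd.DataFrame, *, on_disconnected: str = "error"
) -> ThresholdSweep:
    """The largest tie cutoff at which the graph is still one component.

    Sweeps the distinct observed off-diagonal similarity values (no
    continuous search) using inclusive (``>=``) ties at each candidate;
    ``t_star`` is the maximum value whose graph is a single connected
    component over the scoped items — the graph "just before it is broken
    apart". Items with no positive similarity to any other are excluded from
    the scope with a warning. If even the smallest positive value leaves the
    scope disconnected, raises (``on_disconnected="largest"`` instead
    restricts the scope to the largest component at that value and resweeps).
    """
    check_similarity(sim)
    a = sim.to_numpy(dtype=float).copy()
    np.fill_diagonal(a, 0.0)
    items = list(sim.index)
    has_pos = a.max(axis=1) > 0
    excluded = [it for it, ok in zip(items, has_pos) if not ok]
    if excluded:
        warnings.warn(
            f"excluding {len(excluded)} item(s) with no positive similarity "
            "from the connectivity scope",
            stacklevel=2,
        )
    scope_ix = np.flatnonzero(has_pos)
    if len(scope_ix) < 2:
        raise ValueError("fewer than two items with positive similarity")
    sub = a[np.ix_(scope_ix, scope_ix)]
    scope = [items[i] for i in scope_ix]
    values = sorted({float(v) for v in sub[np.triu_indices(len(sub), 1)] if v > 0})

    def connected(v: float) -> bool:
        g = nx.from_numpy_array(sub >= v)
        return nx.is_connected(g)

    connected_at = [connected(v) for v in values]
    good = [v for v, ok in zip(values, connected_at) if ok]
    if not good:
        if on_disconnected == "largest":
            g = nx.from_numpy_array(sub >= values[0])
            # largest component; ties broken toward the lexicographically first
            comp = min(
                nx.connected_components(g),
                key=lambda c: (-len(c), sorted(str(scope[i]) for i in c)),
            )
            keep = [scope[i] for i in sorted(comp)]
            return max_connected_threshold(
                sim.loc[keep, keep], on_disconnected="error"
            )
        raise ValueError("scoped items are disconnected even at the minimum positive similarity")
    return ThresholdSweep(
        candidate_values=values,
        connected_at=connected_at,
        t_star=max(good),
        scope=scope,
        excluded=excluded,
    )


def project_subgroup_ties(
    matrix: AssemblageMatrix,
    partition: Mapping[Hashable, int],
    cutoff: float = 0.05,
    *,
    context_attrs: Mapping[str, Mapping] | None = None,
) -> nx.Graph:
    """Bipartite context-subgroup graph weighted by summed percent MNI.

    A subgroup is tied to a context when its member taxa together make up at
    least ``cutoff`` of the context's total MNI (inclusive — "at least 5%").
    Percent MNI is computed over the full matrix passed in; with
    ``cutoff=0`` the weights out of each context sum to 1 wherever the
    partition covers all scoped taxa.
    """
    from .communities import Partition  # cycle-free: communities imports netbuild lazily

    if isinstance(partition, Partition):
        partition = partition.assignment
    missing = [t for t in partition if t not in matrix.counts.index]
    if missing:
        raise ValueError(f"partition taxa absent from matrix: {missing[:5]}")
    props = percent_mni(matrix).proportions
    groups = sorted(set(partition.values()))
    g = nx.Graph()
    for c in matrix.contexts:
        g.add_node(
            f"context:{c}",
            node_class="context",
            label=c,
            **dict((context_attrs or {}).get(c, {})),
        )
    for gr in groups:
        g.add_node(f"group:{gr}", node_class="subgroup", label=str(gr))
    for gr in groups:
        members = [t for t, gg in partition.items() if gg == gr]
        w = props.loc[members].sum(axis=0)
        for c in matrix.contexts:
            val = float(w[c]) if not np.isnan(w[c]) else 0.0
            if val >= cutoff and val > 0:
                g.add_edge(f"context:{c}", f"group:{gr}", weight=val)
    return g


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------


def write_graph(g: nx.Graph, basepath: str | Path) -> list[Path]:
    """Write a graph as GraphML plus plain edge-list and node-attribute CSVs.

    ``basepath`` is a path without extension; returns the files written.
    Output is deterministic for identically-constructed graphs.
    """
    basepath = Path(basepath)
    basepath.parent.mkdir(parents=True, exist_ok=True)
    gml = basepath.with_suffix(".graphml")
    clean = nx.Graph()
    for n, attrs in g.nodes(data=True):
        clean.add_node(str(n), **{k: v for k, v in attrs.items() if v is not None})
    for u, v, attrs in g.edges(data=True):
        clean.add_edge(str(u), str(v), **{k: w for k, w in attrs.items() if w is not None})
    nx.write_graphml(clean, gml, named_key_ids=True)

    edges_csv = basepath.parent / (basepath.name + "_edges.csv")
    with open(edges_csv, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(["source", "target", "weight"])
        for u, v, attrs in g.edges(data=True):
            w.writerow([u, v, attrs.get("weight", "")])

    nodes_csv = basepath.parent / (basepath.name + "_nodes.csv")
    keys = sorted({k for _, attrs in g.nodes(data=True) for k in attrs})
    with open(nodes_csv, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(["node"] + keys)
        for n, attrs in g.nodes(data=True):
            w.writerow([n] + [attrs.get(k, "") for k in keys])
    return [gml, edges_csv, nodes_csv]
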