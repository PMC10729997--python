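"""End-to-end orchestration of the two published analyses.

``run_stratigraphic`` reproduces the within-column (Operation P) sequence:
habitat membership network, exclusive-habitat species networks, habitat
collapse, the 60 %-similarity species network with its Girvan-Newman
partition, and the layer-subgroup projection. ``run_sitewide`` reproduces
the 15-context sequence: the diversity-sized two-mode network, the
Jaccard > 0.33 context network, the Jaccard > 0.40 species network sized by
ubiquity and partitioned, the context-subgroup projection, and the
group-composition table with base-group exclusion.

Both return a :class:`StageManifest` listing every artifact written, the
resolved parameters, and summary counts. Runs are deterministic: identical
config and inputs give bit-identical outputs.

Scope conventions: the stratigraphic stages work on invertebrates only; the
site-wide stages use all taxa. Group labels are arbitrary integers
renumbered 1..k by descending total MNI — matching published group numbers
is only ever possible up to permutation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .assemblage import (
    AssemblageMatrix,
    ContextRecord,
    TaxonRecord,
    read_context_metadata,
    read_mni_matrix,
    read_taxon_metadata,
)
from .communities import (
    GirvanNewmanClustering,
    Partition,
    best_partition,
    girvan_newman,
)
from .datasets import (
    load_pineland,
    load_pineland_contexts,
    load_pineland_taxa,
)
from .metrics import (
    collapse_to_habitats,
    filter_exclusive_habitat,
    metrics_table,
    percent_mni,
    ubiquity_table,
)
from .netbuild import (
    abundance_similarity,
    build_habitat_membership,
    build_two_mode,
    jaccard_similarity,
    max_connected_threshold,
    project_subgroup_ties,
    threshold_graph,
    write_graph,
)

__all__ = [
    "DEFAULT_CONFIG",
    "StageManifest",
    "GroupCompositionTable",
    "load_config",
    "run_stratigraphic",
    "run_sitewide",
    "group_composition",
    "recover_synthetic",
]

#: Resolved defaults; thresholds are the published cutoffs.
DEFAULT_CONFIG: dict = {
    "strat_similarity_threshold": 0.60,
    "sitewide_context_threshold": 0.33,
    "sitewide_species_threshold": 0.40,
    "subgroup_tie_cutoff": 0.05,
    "strat_n_groups": None,  # None = best-modularity partition
    "sitewide_n_groups": None,
    "diversity_metric": "shannon",  # or "richness", for node sizes
    "habitat_collapse_exclusive_only": True,
    "habitat_collapse_split_multi": False,
    "excluded_groups": [],  # group ids dropped from the composition table
    "renormalize_excluded": False,
    "mni_matrix": None,  # paths; None = bundled fixture
    "taxon_metadata": None,
    "context_metadata": None,
}


def load_config(path: str | Path | None = None, **overrides) -> dict:
    """Resolve a YAML config file over the defaults; unknown keys are errors."""
    cfg = dict(DEFAULT_CONFIG)
    loaded = {}
    if path is not None:
        with open(path, encoding="utf-8") as fh:
            loaded = yaml.safe_load(fh) or {}
    for src in (loaded, overrides):
        for k, v in src.items():
            if k not in DEFAULT_CONFIG:
                raise KeyError(f"unknown config key {k!r}")
            cfg[k] = v
    return cfg


def _load_inputs(
    cfg: Mapping,
) -> tuple[AssemblageMatrix, list[TaxonRecord], list[ContextRecord]]:
    matrix = (
        read_mni_matrix(cfg["mni_matrix"]) if cfg["mni_matrix"] else load_pineland()
    )
    taxa = (
        read_taxon_metadata(cfg["taxon_metadata"])
        if cfg["taxon_metadata"]
        else load_pineland_taxa()
    )
    contexts = (
        read_context_metadata(cfg["context_metadata"])
        if cfg["context_metadata"]
        else load_pineland_contexts()
    )
    return matrix, taxa, contexts


@dataclass
class StageManifest:
    """What a pipeline stage produced: inputs, parameters, outputs, counts."""

    stage_name: str
    inputs: dict = field(default_factory=dict)
    parameters: dict = field(default_factory=dict)
    outputs: list[str] = field(default_factory=list)
    summary_counts: dict = field(default_factory=dict)

    def add_graph(self, name: str, g, outdir: Path) -> None:
        paths = write_graph(g, outdir / name)
        self.outputs.extend(str(p) for p in paths)
        self.summary_counts[name] = {
            "nodes": g.number_of_nodes(),
            "edges": g.number_of_edges(),
        }

    def add_table(self, name: str, df: pd.DataFrame, outdir: Path, index=True) -> None:
        p = outdir / f"{name}.csv"
        df.to_csv(p, encoding="utf-8", lineterminator="\n", index=index)
        self.outputs.append(str(p))
        self.summary_counts[name] = {"rows": int(df.shape[0])}

    def write(self, outdir: Path) -> Path:
        p = outdir / f"{self.stage_name}_manifest.json"
        with open(p, "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "stage_name": self.stage_name,
                    "inputs": self.inputs,
                    "parameters": self.parameters,
                    "outputs": sorted(self.outputs),
                    "summary_counts": self.summary_counts,
                },
                fh,
                indent=2,
                sort_keys=True,
            )
            fh.write("\n")
        return p


@dataclass
class GroupCompositionTable:
    """Group-by-context percent-MNI shares, optionally with groups dropped."""

    shares: pd.DataFrame  # index = group ids, columns = contexts
    excluded_groups: list[int]


def group_composition(
    matrix: AssemblageMatrix,
    partition: Partition | Mapping,
    excluded_groups: Sequence[int] = (),
    *,
    renormalize: bool = False,
) -> GroupCompositionTable:
    """Per-context share of each detected group's summed MNI.

    Shares are of the context's *total* MNI, so dropping a ubiquitous "base"
    group leaves the remaining columns summing below 1 (the excluded group
    is removed from the display, not from the assemblages);
    ``renormalize=True`` rescales the remaining groups to sum 1 instead.
    """
    assignment = partition.assignment if isinstance(partition, Partition) else partition
    props = percent_mni(matrix).proportions
    groups = sorted(set(assignment.values()))
    rows = {}
    for g in groups:
        members = [t for t, gg in assignment.items() if gg == g]
        rows[g] = props.loc[members].sum(axis=0)
    shares = pd.DataFrame(rows).T
    shares.index.name = "group_id"
    excluded = [g for g in excluded_groups if g in groups]
    if excluded:
        shares = shares.drop(index=excluded)
        if renormalize:
            shares = shares / shares.sum(axis=0)
    return GroupCompositionTable(shares=shares, excluded_groups=excluded)


def _invertebrate_ids(matrix: AssemblageMatrix, taxa: Sequence[TaxonRecord]) -> list[str]:
    inv = {t.taxon_id for t in taxa if t.kingdom_class == "invertebrate"}
    return [t for t in matrix.taxa if t in inv]


def _fit_partition(graph, n_groups, matrix: AssemblageMatrix) -> tuple[Partition, "pd.DataFrame"]:
    """Run community detection on a thresholded graph and relabel groups by
    descending total MNI."""
    dendro = girvan_newman(graph)
    part = (
        best_partition(dendro)
        if n_groups is None
        else dendro.partition_with_n_groups(int(n_groups))
    )
    totals = matrix.counts.sum(axis=1)
    part = part.relabel_by_size({t: int(totals.get(t, 0)) for t in part.assignment})
    return part, dendro.to_frame()


def run_stratigraphic(config: Mapping | None = None, out_dir: str | Path = "out") -> StageManifest:
    """The Operation P (four-level) analysis, invertebrates only.

    Emits, in order: the habitat-membership two-mode graph, the
    layer-exclusive-species graph colored by habitat, the layer-habitat
    collapsed weighted graph, the exclusive-species one-mode graph at the
    similarity cutoff, its community partition, and the layer-subgroup
    weighted graph with the >= 5 %-MNI tie rule.
    """
    cfg = dict(DEFAULT_CONFIG, **(config or {}))
    outdir = Path(out_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    matrix, taxa, contexts = _load_inputs(cfg)
    if not any(t.habitats for t in taxa):
        raise ValueError("habitat metadata is required for the stratigraphic analysis")

    op_ctx = [c.context_id for c in contexts if c.site_area == "operation_p"]
    op_ctx = [c for c in matrix.contexts if c in op_ctx]
    if not op_ctx:
        raise ValueError("no operation_p contexts in the matrix")
    sub = matrix.select_contexts(op_ctx)
    inv = sub.select_taxa(_invertebrate_ids(sub, taxa))
    # only taxa actually identified in these levels
    inv = inv.select_taxa([t for t in inv.taxa if inv.counts.loc[t].sum() >= 1])
    by_id = {t.taxon_id: t for t in taxa}
    ctx_attrs = {
        c.context_id: {"color_key": c.period_label, "strat_order": c.strat_order}
        for c in contexts
        if c.strat_order is not None
    }

    man = StageManifest(
        stage_name="stratigraphic",
        inputs={"contexts": op_ctx, "n_invertebrate_taxa": inv.shape[0]},
        parameters={
            "similarity_threshold": cfg["strat_similarity_threshold"],
            "subgroup_tie_cutoff": cfg["subgroup_tie_cutoff"],
            "n_groups": cfg["strat_n_groups"],
        },
    )

    # habitat membership (two-mode habitat x species)
    man.add_graph("habitat_membership", build_habitat_membership(inv, taxa), outdir)

    # layers x exclusive-habitat species, colored by habitat
    excl = filter_exclusive_habitat(inv, taxa)
    sp_attrs = {
        t: {"color_key": next(iter(by_id[t].habitats))} for t in excl.taxa
    }
    man.add_graph(
        "exclusive_species_two_mode",
        build_two_mode(excl, "presence", context_attrs=ctx_attrs, species_attrs=sp_attrs),
        outdir,
    )

    # layers x habitats, weighted by collapsed percent MNI
    profile = collapse_to_habitats(
        inv,
        taxa,
        exclusive_only=cfg["habitat_collapse_exclusive_only"],
        split_multi=cfg["habitat_collapse_split_multi"],
    )
    import networkx as nx

    hg = nx.Graph()
    for c in profile.shares.columns:
        hg.add_node(c, node_class="context", **ctx_attrs.get(c, {}))
    for h in profile.shares.index:
        hg.add_node(h, node_class="habitat")
    for h in profile.shares.index:
        for c in profile.shares.columns:
            v = profile.shares.loc[h, c]
            if not np.isnan(v) and v > 0:
                hg.add_edge(c, h, weight=float(v))
    man.add_graph("habitat_collapse", hg, outdir)
    man.add_table("habitat_shares", profile.shares, outdir)

    # exclusive-species one-mode similarity network
    sim = abundance_similarity(percent_mni(excl))
    sg = threshold_graph(
        sim, cfg["strat_similarity_threshold"], strict=True, node_attrs=sp_attrs
    )
    man.add_graph("species_similarity", sg, outdir)

    # community detection
    part, dendro_frame = _fit_partition(sg, cfg["strat_n_groups"], excl)
    for n in sg.nodes:
        sg.nodes[n]["group_id"] = part.assignment[n]
    man.add_table("species_partition", part.to_frame(), outdir, index=False)
    man.add_table("dendrogram", dendro_frame, outdir, index=False)
    man.summary_counts["species_partition"]["groups"] = part.n_groups
    man.parameters["best_q"] = part.q

    # layers x subgroups, >= 5% MNI ties (denominator: invertebrate assemblage)
    pg = project_subgroup_ties(
        inv, part, cfg["subgroup_tie_cutoff"], context_attrs=ctx_attrs
    )
    man.add_graph("subgroup_ties", pg, outdir)

    man.write(outdir)
    return man


def run_sitewide(config: Mapping | None = None, out_dir: str | Path = "out") -> StageManifest:
    """The 15-context site-wide analysis, all taxa.

    Emits: the context-species two-mode graph sized by diversity and colored
    by period, the context one-mode Jaccard graph, the species one-mode
    Jaccard graph sized by ubiquity with its community partition, the
    context-subgroup projection, and the group-composition table with
    configurable base-group exclusion.
    """
    cfg = dict(DEFAULT_CONFIG, **(config or {}))
    outdir = Path(out_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    matrix, taxa, contexts = _load_inputs(cfg)

    mtable = metrics_table(matrix)
    size_col = (
        "shannon_diversity" if cfg["diversity_metric"] == "shannon" else "richness"
    )
    by_ctx = {c.context_id: c for c in contexts}
    ctx_attrs = {
        c: {
            "color_key": by_ctx[c].period_label if c in by_ctx else "",
            "size_value": float(mtable.loc[c, size_col]),
        }
        for c in matrix.contexts
    }
    ubi = ubiquity_table(matrix)
    sp_attrs = {t: {"size_value": float(ubi[t])} for t in matrix.taxa}

    man = StageManifest(
        stage_name="sitewide",
        inputs={"contexts": matrix.contexts, "n_taxa": matrix.shape[0]},
        parameters={
            "context_threshold": cfg["sitewide_context_threshold"],
            "species_threshold": cfg["sitewide_species_threshold"],
            "subgroup_tie_cutoff": cfg["subgroup_tie_cutoff"],
            "n_groups": cfg["sitewide_n_groups"],
            "diversity_metric": cfg["diversity_metric"],
        },
    )

    man.add_table("context_metrics", mtable, outdir)
    man.add_graph(
        "two_mode",
        build_two_mode(matrix, "presence", context_attrs=ctx_attrs, species_attrs=sp_attrs),
        outdir,
    )

    ctx_sim = jaccard_similarity(matrix, axis="contexts")
    man.add_graph(
        "context_jaccard",
        threshold_graph(
            ctx_sim,
            cfg["sitewide_context_threshold"],
            strict=True,
            node_attrs=ctx_attrs,
            node_class="context",
        ),
        outdir,
    )

    sp_sim = jaccard_similarity(matrix, axis="taxa")
    spg = threshold_graph(
        sp_sim, cfg["sitewide_species_threshold"], strict=True, node_attrs=sp_attrs
    )
    part, dendro_frame = _fit_partition(spg, cfg["sitewide_n_groups"], matrix)
    for n in spg.nodes:
        spg.nodes[n]["group_id"] = part.assignment[n]
    man.add_graph("species_jaccard", spg, outdir)
    man.add_table("species_partition", part.to_frame(), outdir, index=False)
    man.add_table("dendrogram", dendro_frame, outdir, index=False)
    man.summary_counts["species_partition"]["groups"] = part.n_groups
    man.parameters["best_q"] = part.q

    man.add_graph(
        "subgroup_ties",
        project_subgroup_ties(
            matrix, part, cfg["subgroup_tie_cutoff"], context_attrs=ctx_attrs
        ),
        outdir,
    )

    comp = group_composition(
        matrix,
        part,
        cfg["excluded_groups"],
        renormalize=cfg["renormalize_excluded"],
    )
    man.add_table("group_composition", comp.shares, outdir)
    man.parameters["excluded_groups"] = list(comp.excluded_groups)

    man.write(outdir)
    return man


def recover_synthetic(matrix: AssemblageMatrix, *, n_groups: int | None = None) -> Partition:
    """The planted-partition recovery pipeline used for benchmarking.

    Renkonen similarity on percent-MNI profiles, tie cutoff at the maximum
    connectivity-preserving threshold, Girvan-Newman, best-modularity
    partition (or a fixed group count).
    """
    sim = abundance_similarity(percent_mni(matrix))
    sweep = max_connected_threshold(sim, on_disconnected="largest")
    keep = sweep.scope
    model = GirvanNewmanClustering(
        threshold=sweep.t_star, strict=False, n_communities=n_groups
    )
    model.fit(sim.loc[keep, keep])
    part = model.partition_
    # items outside the connectivity scope become their own singleton groups
    assignment = dict(part.assignment)
    next_g = max(assignment.values(), default=-1) + 1
    for t in matrix.taxa:
        if t not in assignment:
            assignment[t] = next_g
            next_g += 1
    return Partition(assignment, part.q)
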