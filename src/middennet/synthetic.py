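"""Synthetic assemblage matrices with planted species packages.

The generator emulates the statistical structure the network analysis
assumes: blocks ("packages") of species that co-occur in similar
proportions across a subset of contexts, an optional ubiquitous "base"
package present everywhere, stray background occurrences, and blockwise
habitat labels. With the planted partition in hand, every pipeline stage —
similarity, thresholding, community detection — can be scored for recovery
without any real data.

Counts are built per context as a multinomial draw of the context total
over the species active there; a species' expected share is its group's
Dirichlet weight, so members of one package keep similar relative
abundances wherever the package is supported ("found together in similar
proportions"). Poisson strays at ``background_rate`` are then added to
every cell. The generator is a test scaffold, not a demographic model; no
attempt is made to fit its parameters to real assemblages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .assemblage import HABITATS, AssemblageMatrix, TaxonRecord
from .communities import Partition

__all__ = ["SyntheticSpec", "SyntheticTruth", "generate", "recovery_score"]


@dataclass
class SyntheticSpec:
    """Parameters of the planted-package generator.

    Defaults follow the recovery benchmark conditions: 8 contexts, 4
    packages of 10 species each supported on disjoint pairs of contexts,
    within-package Dirichlet concentration 50 (tightly similar member
    profiles), stray rate 0.2 expected MNI per species per unsupported
    context, and ~500 MNI per context.
    """

    n_contexts: int = 8
    n_groups: int = 4
    species_per_group: int = 10
    base_group_size: int = 0
    context_support: Mapping[int, Sequence[int]] | None = None  # group -> context indices
    within_group_concentration: float = 50.0
    background_rate: float = 0.2
    context_total: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_contexts, self.n_groups, self.species_per_group) < 1:
            raise ValueError("sizes must be >= 1")
        if self.base_group_size < 0 or self.background_rate < 0:
            raise ValueError("base_group_size and background_rate must be >= 0")
        if self.context_total < 1:
            raise ValueError("context_total must be >= 1")
        if self.context_support is not None:
            for g, ctxs in self.context_support.items():
                if not (0 <= g < self.n_groups):
                    raise ValueError(f"support for unknown group {g}")
                if len(ctxs) == 0:
                    raise ValueError(f"group {g} has empty context support")

    def resolved_support(self) -> dict[int, list[int]]:
        """Default support: contexts split into contiguous, near-equal,
        disjoint blocks, one per group."""
        if self.context_support is not None:
            return {g: list(c) for g, c in self.context_support.items()}
        edges = np.linspace(0, self.n_contexts, self.n_groups + 1).astype(int)
        return {
            g: list(range(edges[g], max(edges[g + 1], edges[g] + 1)))
            for g in range(self.n_groups)
        }


@dataclass
class SyntheticTruth:
    """A generated matrix with its planted partition and habitat labels."""

    matrix: AssemblageMatrix
    true_partition: Partition
    habitat_labels: dict[str, str]
    taxa: list[TaxonRecord] = field(default_factory=list)


def generate(spec: SyntheticSpec) -> SyntheticTruth:
    """Draw one synthetic assemblage. Identical spec (incl. seed) gives an
    identical matrix."""
    rng = np.random.default_rng(spec.seed)
    support = spec.resolved_support()

    species: list[str] = []
    group_of: dict[str, int] = {}
    for g in range(spec.n_groups):
        for i in range(spec.species_per_group):
            sid = f"sp_g{g + 1}_{i + 1:02d}"
            species.append(sid)
            group_of[sid] = g
    base: list[str] = [f"sp_base_{i + 1:02d}" for i in range(spec.base_group_size)]
    all_species = species + base
    contexts = [f"ctx_{j + 1:02d}" for j in range(spec.n_contexts)]

    # one Dirichlet weight vector per package: members keep these relative
    # abundances in every supported context
    alpha = spec.within_group_concentration
    gweights = {
        g: rng.dirichlet(np.full(spec.species_per_group, alpha))
        for g in range(spec.n_groups)
    }
    base_w = (
        rng.dirichlet(np.full(spec.base_group_size, alpha))
        if spec.base_group_size
        else None
    )

    counts = np.zeros((len(all_species), spec.n_contexts), dtype=np.int64)
    ix = {s: i for i, s in enumerate(all_species)}
    for j in range(spec.n_contexts):
        rates = np.zeros(len(all_species))
        for g, ctxs in support.items():
            if j in ctxs:
                for i_m, sid in enumerate(
                    species[g * spec.species_per_group : (g + 1) * spec.species_per_group]
                ):
                    rates[ix[sid]] = gweights[g][i_m]
        if base_w is not None:  # base package: abundant everywhere
            for i_m, sid in enumerate(base):
                rates[ix[sid]] = base_w[i_m]
        if rates.sum() == 0:
            raise ValueError(f"context {j} supported by no group and no base package")
        counts[:, j] += rng.multinomial(spec.context_total, rates / rates.sum())
    if spec.background_rate > 0:
        counts += rng.poisson(spec.background_rate, size=counts.shape)

    matrix = AssemblageMatrix(
        pd.DataFrame(counts, index=all_species, columns=contexts)
    )
    truth = Partition({s: group_of[s] for s in species}, q=float("nan"))

    # habitat labels assigned blockwise so the exclusive-habitat filter and
    # habitat collapse have structured synthetic behaviour
    habitat_labels = {
        s: HABITATS[group_of[s] % len(HABITATS)] for s in species
    }
    records = [
        TaxonRecord(
            taxon_id=s,
            scientific_name=s,
            kingdom_class="invertebrate",
            habitats=frozenset({habitat_labels[s]}),
        )
        for s in species
    ] + [
        TaxonRecord(
            taxon_id=s,
            scientific_name=s,
            kingdom_class="invertebrate",
            habitats=frozenset(HABITATS[:2]),  # base species: multi-habitat
        )
        for s in base
    ]
    return SyntheticTruth(
        matrix=matrix, true_partition=truth, habitat_labels=habitat_labels, taxa=records
    )


def recovery_score(found: Partition | Mapping, truth: Partition | Mapping) -> float:
    """Adjusted Rand Index between two partitions of the same node set.

    1 iff identical up to label permutation; ~0 for chance agreement.
    """
    fa = found.assignment if isinstance(found, Partition) else found
    ta = truth.assignment if isinstance(truth, Partition) else truth
    if set(fa) != set(ta):
        raise ValueError("partitions cover different node sets")
    nodes = sorted(fa, key=str)
    return float(
        adjusted_rand_score([ta[n] for n in nodes], [fa[n] for n in nodes])
    )
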