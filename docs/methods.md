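# Methods

This note documents the models, conventions and design choices behind
`middennet`, in the order data flows through the package.

## Assemblage matrices and the bundled fixture

The unit of observation is an excavation context (a stratigraphic layer or
sampled stratum) and the unit of abundance is MNI, the minimum number of
individual animals accounting for a taxon's identified specimens. Matrices
are non-negative integer grids with unique taxon and context identifiers;
row/column order is preserved from the source file. In MNI CSVs the empty
cell, `-` and the em dash `—` all mean absence, the convention of printed
species lists. Combined names (`Nassarius/Phrontis vibex`) and `cf.` /
`sp.` / `spp.` qualifiers are kept as distinct verbatim identifiers — no
lumping beyond what the printed source table already did — because silently
merging rows would change every downstream network's node set.

The bundled Pineland fixture (336 taxa × 15 contexts) is a hand-checked
transcription. Fourteen of its fifteen column sums match the printed totals
row exactly; the Operation P (P-10-105) cells sum to 9950 against a printed
total of 9949. The cells are kept verbatim and the discrepancy is treated
as a one-count erratum in the source table; the transcription-fidelity test
flags exactly that context. The printed context header `P-1-103` is
normalized to `P-10-103` (the text names levels 99–105 of trench P-10).

Habitat designations for invertebrate taxa — the five salinity-regime
classes tidal stream, estuarine mangrove, oyster bed, seagrass meadow and
littoral zone — are not printed in the source study. The bundled
`pineland_taxa.csv` is therefore a curated, editable stand-in assembled
from the standard ecology of each taxon; it is versioned with the package
and clearly labelled in its header. Terrestrial taxa (land snails) and taxa
identified only to a very coarse level carry an empty habitat set and drop
out of habitat-scoped analyses. Analyses that need exact habitat behaviour
are tested with synthetic labels, not this table.

The Brown's Complex Mound 2 period labels follow stratigraphic order
(I-2-73 deeper = Caloosahatchee III, I-2-66 = Caloosahatchee IV); the
source text is internally inconsistent about these two labels, and nothing
beyond node colouring depends on them.

## Ecology metrics

* `percent_mni` normalizes each context column within a taxon scope; a
  context whose scoped total is zero is *flagged* (NaN column), never
  silently zeroed.
* Diversity for node sizing is Shannon `H = −Σ p ln p` in nats (natural
  log: only relative node sizes matter and the source study does not name
  its index); richness is computed alongside and can size nodes instead via
  `diversity_metric: richness`.
* Presence means MNI ≥ 1 everywhere (ubiquity, richness, Jaccard): no
  abundance floor.
* The habitat collapse defaults to exclusive-habitat invertebrates — the
  same scope as the exclusive-habitat networks — because the source figures
  introduce that filter immediately beforehand; `exclusive_only=False,
  split_multi=True` instead splits multi-habitat taxa equally across their
  habitats. Either way habitat shares per context sum to 1 over classified
  MNI.
* No rarefaction, sample-size standardization or NISP-based metrics: MNI
  with percent MNI is deliberately the only abundance currency.

## Similarity and thresholding

Jaccard similarity uses presence sets. Two *empty* presence sets get
similarity 1 (identical emptiness) with a warning; such items are normally
excluded before a similarity stage.

The "similar presence and abundance" species metric is Renkonen percentage
similarity: percent-MNI profiles are renormalized per taxon across contexts
and `S = Σ min`. The source study never names the measure its GUI tool
computed; Renkonen is the standard abundance-overlap coefficient with the
required [0, 1] "percent similarity" semantics. Note that the obvious
alternative, 1 − ½·Manhattan distance on normalized profiles, is
algebraically identical to Renkonen, so no separate option is provided.

Thresholds are strict (`>`) wherever the published wording is "greater
than" (0.60, 0.33, 0.40); the one inclusive rule is the "at least 5 %"
cutoff for context-subgroup ties. `max_connected_threshold` sweeps only the
distinct observed similarity values, uses `≥` at each candidate, and
returns the largest value keeping the scoped graph one component; items
with no positive similarity are excluded from the scope with a warning, and
a scope that is disconnected even at the minimum positive value either
raises or (configurably) restricts to the largest component.

## Community detection

Girvan–Newman is implemented from first principles:

* **Edge betweenness** by Brandes' accumulation over unweighted shortest
  paths. Each unordered vertex pair contributes once (path a–b–c scores 2
  on each edge; a tree edge separating parts of sizes p and q scores p·q).
  Thresholded graphs are treated as unweighted — a tie is a tie once the
  cutoff is applied. Two kernels exist: a numba-compiled CSR kernel
  (default; the site-wide species network has ~4 600 edges and the full
  removal sequence recomputes betweenness after every removal) and a
  plain-Python reference, cross-checked against each other, against
  exhaustive path enumeration, and against networkx in the tests.
* **Removal loop**: the maximum-betweenness edge is removed; equal maxima
  (within 1e-9, guarding float accumulation) are broken by the
  lexicographically smallest endpoint pair, making the whole dendrogram
  deterministic. Betweenness is recomputed only inside the component that
  lost the edge. Every step records the component partition and its
  modularity *on the original edge set*, the standard convention.
* **Selection**: best-Q by default, ties broken toward fewer groups then
  the earliest step; a fixed target group count (`strat_n_groups`,
  `sitewide_n_groups`) picks the earliest partition with exactly that many
  components. Isolated nodes pass through as singleton groups and affect Q
  only through their zero degree.

The `GirvanNewmanClustering` estimator wraps this as a scikit-learn-style
clusterer (`fit` on a graph or a precomputed similarity matrix, `labels_`,
`get_params`/`set_params`), so it composes with sklearn tooling; the
functional API (`girvan_newman`, `best_partition`, …) remains the primary
surface for the pipeline.

## Pipelines

The stratigraphic analysis scopes to invertebrates identified in the four
Operation P levels; the site-wide analysis uses all taxa in all 15 contexts
(a filter flag can restrict to the 11 site-wide contexts). Group labels are
renumbered 1..k by descending total member MNI — published group numbers
are a display artifact, so label matching is only ever up to permutation.
The group-composition table keeps excluded "base" groups in the
denominators (shares are of the whole assemblage and the base row is
dropped from display, matching the wording that the group was removed from
the charts, not the assemblages); `renormalize_excluded: true` rescales
instead.

Configuration is one flat YAML file over explicit defaults (the published
cutoffs); unknown keys are hard errors. An empty or absent config runs the
bundled fixture end to end. All outputs (GraphML, CSVs, JSON manifests) are
deterministic: re-running a stage with the same config and inputs is
bit-identical, and nothing embeds wall-clock content.

On the fixture, best-Q detection finds 5 Operation P packages —
coinciding with the published count — and 24 site-wide groups of which 13
have more than one member (the published reading is 6 or 7, stated
inconsistently in the source). The site-wide count is *not* expected to
reproduce exactly: it depends on unpublished habitat designations, the GUI
tool's unnamed similarity and stopping rules, and how isolates are counted;
both the raw and non-singleton counts are reported side by side.

## Synthetic benchmark

The generator plants `n_groups` packages of `species_per_group` species.
Each package has one Dirichlet weight vector (concentration
`within_group_concentration`; higher = more similar member profiles) and a
set of supported contexts (default: disjoint contiguous blocks). Per
context, the context total (default 500 MNI) is drawn multinomially over
the species active there, so package members keep similar relative
abundances wherever their package is supported; independent Poisson strays
(`background_rate`, default 0.2 expected MNI per species per context) are
added everywhere. An optional base package is abundant in every context to
exercise base-group exclusion, and habitat labels are assigned blockwise to
exercise the habitat stages. Defaults (8 contexts, 4 packages of 10,
concentration 50, total 500, strays 0.2) are the recovery benchmark
conditions.

What the benchmark shows: the full pipeline (Renkonen →
connectivity-preserving threshold → Girvan–Newman → best-Q) recovers the
planted partition with ARI ≥ 0.9 in ≥ 18 of 20 seeds. What it does not
show: real assemblages are not Dirichlet-multinomial blocks — taphonomy,
mixed deposition, and gradient (rather than block) structure are absent, so
benchmark success bounds algorithmic correctness, not archaeological
validity. Uniform stray noise inflates all profile similarities together,
so recovery degrades only once strays rival the planted signal; the
degradation test uses a wide rate spread for that reason.

## Numerical conventions and limitations

* Proportion sums are checked to 1e-9; similarity symmetry to 1e-12 (the
  Renkonen matrix is symmetrized exactly after computation).
* Betweenness tie detection uses a 1e-9 absolute tolerance.
* Tie weights are stored as fractions (0.07) and rendered as percentages
  only in prose.
* Graph layout is out of scope: node positions in the source figures are a
  display artifact of the original GUI tool, and GraphML exports leave
  layout to the viewer.
* No taxonomic-name resolution is attempted; identifiers are verbatim.
* Whether `sp.` and `spp.` rows of one genus were one node or two in the
  source analyses is unknowable from the publication; the fixture keeps
  them distinct as printed.
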