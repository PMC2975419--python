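# Methods

This note records the model, the defaults, and the design choices made
where the design was genuinely open.  Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Pairs and formats

All pairwise data are unordered protein pairs; the canonical form sorts
the two identifiers lexicographically, and self-interactions are excluded
everywhere (none of the evidence or scoring rules is well defined for
them).  Tables are plain TSV (UTF-8, `#` comments, no quoting);
ontologies are OBO 1.2 parsed with `obonet`, keeping `[Term]` stanzas
only, dropping obsolete terms, and treating both `is_a` and `part_of` as
ancestry (the common convention for annotation propagation; the edge
set is configurable).  Network files round-trip through 12 significant
digits, which is what the byte-identity reproducibility guarantee rests
on.

## Gold standards

**Positives (GSP)** are the union of curated interaction pairs and an
all-pairs expansion of enzyme complexes with *fewer than* 18 members
(exclusive bound).  The rationale for the bound is that large complexes
are dominated by indirect co-membership; the threshold is a parameter
(`max_complex_size`).  Provenance per pair is recorded as
curated/complex/both.

**Negatives (GSN)** pair proteins whose high-confidence
cellular-component annotations are disjoint.  Only evidence codes IC,
IDA and IPI qualify by default.  Disjointness is tested on *directly
annotated* CC terms, not ancestor-closed sets: closure would make nearly
every pair share the CC root and empty the set.  A `propagate` option
tests closure minus ontology roots instead, for annotations made at
heterogeneous depths.  Because the all-vs-all disjoint set can be
enormous, the GSN can be subsampled with a seeded RNG.

Pairs appearing in both sets are removed from both during reconciliation
and recorded (`removed_overlap`) — the same bookkeeping a contaminated
curated input would force on real data.

## Evidence layers

Each layer defines values only on its *coverage*; pairs outside coverage
are "evidence absent" and contribute the neutral LR 1 at integration —
never a zero score.

- **ortholog (per organism)** — interactions of a source organism
  transferred through an ortholog map; every cross-product of the two
  ortholog sets is emitted.  Boolean, presence-only.
- **coexpression** — Pearson correlation of expression vectors (≥ 3
  samples required; zero-variance genes uncovered).  Groups of
  experiments are concatenated into one matrix by default.
- **domain** — flag 1 iff some domain of one protein is known to
  interact with some domain of the other (homotypic pairs count).
  Domainless proteins are covered with flag 0: absence of domains is
  informative for the gate.
- **ssbp** — smallest shared biological process: annotations are
  propagated to all ancestors, each BP term's size is its propagated
  protein count, and a pair's score is the smallest size among shared
  terms.  Propagated counting is used because unpropagated counts
  degenerate (most specific terms would have size 1).  Pairs sharing no
  BP term are uncovered.
- **gene_fusion** — two proteins hitting the same composite protein with
  aligned intervals overlapping by less than `min_gap_fraction` (default
  0.2) of the shorter interval.  Interval lengths are inclusive.
- **gene_neighbor** — orthologs on the same contig with intergenic gap
  ≤ `max_distance` (default 5,000 bp) in at least `min_genomes`
  (default 2) reference genomes.
- **phylo_profile** — fraction of matching presence/absence bits across
  ≥ 4 reference genomes (mutual information available as an option);
  all-present and all-absent profiles are uninformative and uncovered.

## Likelihood-ratio calibration

For a layer cut into `B` bins with pseudocount `c` (default 0.5,
Jeffreys-style, which keeps every LR finite and positive):

```
LR(bin) = [(n_pos_in_bin + c) / (N_pos + cB)] / [(n_neg_in_bin + c) / (N_neg + cB)]
```

with counts restricted to gold pairs inside coverage.  Binary layers use
their two flags as bins; presence-only projection layers cover every
pair with implicit flag 0 for counting, but only the *present* flag ever
contributes at network scoring — absence of a reported interolog is
treated as missing evidence, not counter-evidence.

Continuous layers are discretized by supervised entropy-gain splitting:
greedy recursive binary splits maximizing information gain, stopping at
`max_bins` leaves (pipeline default 5), non-positive gain, or a leaf
below `min_leaf` (default 20).  This is a CART-style splitter; exact
reproduction of a particular decision-tree package (pruning, gain
ratio) is out of scope.  Bin edges are upper-inclusive: bin *i* covers
`(edge[i-1], edge[i]]`.

## Integration

`O_post = O_prior × LR_ortholog × LR_coexpression × LR_functional`, where

- `LR_ortholog` is the **maximum** across source organisms (the
  per-organism interactomes estimate the same quantity);
- `LR_functional` is the **maximum** of the gene-neighbor, gene-fusion,
  phylogenetic-profile and SSBP LRs, admitted only when the pair has
  domain support (the *domain gate*), else 1.  Taking a maximum rather
  than a product avoids double-counting four mutually dependent
  sequence-derived signals; the gate demands a physically plausible
  contact interface before a functional-linkage signal may enter.
  A `domain_mode="lr"` option multiplies the domain layer's own LR in
  as well.
- missing evidence contributes 1.

A compatibility option (`raw_r_as_lr`) feeds the Pearson correlation in
directly as the coexpression "LR" (clamped below at 1e-6).  This mode is
statistically improper — a correlation is not a likelihood ratio — and
exists only to mimic a historical convention; the default learns a
binned LR for coexpression like any other continuous layer.

**Prior odds** are a required input: the ratio of interacting to
non-interacting pairs in the target proteome is not estimable from the
gold standard alone.  The synthetic pipeline defaults to the GSP/GSN
size ratio as a crude data-driven stand-in.

**Tiers.**  The high cutoff is derived from the posterior-odds-one
criterion `cutoff = 1 / O_prior`, kept as an exact rational so that
`cutoff × O_prior = 1` holds identically.  The medium cutoff is the
minimum per-organism ortholog LR — interolog transfer being the most
trusted single signal, its weakest organism marks the medium floor.
When that minimum exceeds the high cutoff (which happens whenever the
interolog layers are stronger than the prior demands, e.g. in the dense
synthetic world where the prior odds are ~0.1), the medium cutoff is
clamped to the high cutoff and the medium tier is empty; on a
genome-scale prior (odds ≪ 1/LR_ortholog) the two cutoffs separate.
Tier boundaries are inclusive at the lower edge.  Pairs supported by no
evidence at all never enter the network, whatever their neutral LR.

## Function annotation

Unknown proteins are assigned one term each by simulated annealing on
the energy `E = −(number of edges whose endpoints share ≥ 1 term)`,
with Metropolis acceptance and geometric cooling (defaults t0 = 1.0,
α = 0.9, 100 steps per temperature, t_min = 1e-3).  The candidate
vocabulary per unknown is its neighbors' known terms (global vocabulary
for isolated unknowns).  The unweighted edge-match energy is the
simplest guilt-by-association form; an edge-weighted variant was
considered and rejected for the default because the LR scale varies by
orders of magnitude across evidence types.  The best-seen state is
returned, so the reported energy never exceeds the initial one, and the
whole procedure is deterministic given its seed.

Multi-term output comes from the significance step, not the annealer:
for every candidate (protein, term) pair, the observed statistic is the
number of network neighbors known to carry the term, the null shuffles
which known protein carries which term set network-wide, and
`p = (r + 1)/(n + 1)`.  The default significance threshold is 0.0517,
preserving a conventional cutoff of this annotation scheme; it is an
unusual-looking constant (essentially 0.05) and is an ordinary
configurable parameter here.  Annotation runs on the high+medium
network jointly by default; per-tier runs are available by passing a
different tier set.

## Validation analyses

- **Conservation** — predictions are reverse-mapped through ortholog maps
  into a reference organism and looked up in its interactome; pairs
  whose *only* supporting evidence is that organism's own interolog
  layer are excluded to avoid circularity.
- **Pathway hubs** — proteins in strictly more than `hub_min_pathways`
  (default 10) pathways vs the network-wide mean degree.
- **Neighborhood enrichment** — hypergeometric upper-tail p-values for
  ancestor-propagated GO terms among the seeds' first-level neighbors
  (seeds excluded from their own neighborhood by default), with
  Benjamini–Hochberg correction.

## The synthetic world

The generator emulates the *shape* of the real inputs, not any
particular proteome:

- **Topology**: a planted-partition model (default 300 proteins, 10
  modules, within-module edge probability 0.3, between 0.005), chosen
  because the validations (modules, complexes, pathways) presuppose
  modular structure.  Enzyme complexes are within-module cliques (five
  of size 3–6 plus one 20-member complex that exercises the expansion
  bound).
- **Boolean evidence channels** (interolog per organism, domain, gene
  fusion, gene neighbor) are drawn conditionally independent given
  true-pair status with per-channel (tpr, fpr) — exactly the
  naive-Bayes assumption, so the integration's statistical contract is
  testable in-model — and the raw tables (source interactomes + ortholog
  maps, domain/DDI tables, fusion hits, gene coordinates) are
  constructed to realize those flags *exactly*.  Defaults: ortholog
  (0.40, 5e-4) per organism, domain (0.80, 0.05), gene fusion
  (0.10, 1e-3), gene neighbor (0.15, 2e-3) — informative but far from
  perfect, with the domain channel deliberately permissive since it
  acts as a gate.
- **Continuous channels** are governed by their own noise parameters
  rather than (tpr, fpr): expression is a module latent profile plus
  Gaussian noise (30 samples, noise sd 1.0 → within-module r ≈ 0.5);
  SSBP structure comes from one module-specific BP term per protein
  under a two-level ontology; profiles are module bit signatures over
  20 genomes with 10% per-protein bit flips.
- **Annotations**: every protein gets one CC localization term (one per
  module) with code IDA; 10% of proteins are withheld from BP
  annotation entirely ("function-unknown").  Gold positives sample 40%
  of true pairs; gold negatives sample localization-disjoint non-pairs
  at 10× the positive count.
- Regeneration from (params, seed) is bit-identical; per-stage seeds are
  derived from the global seed by stable hashing.

What the world does **not** emulate — and hence what passing tests do
not show about real data: realistic degree distributions and hub
structure, GO term-depth heterogeneity, correlated evidence layers (a
dependence between channels can be emulated by reusing one channel's
flags, but the default world is exactly independent), identifier
mapping noise, and incomplete ortholog coverage (maps are one-to-one and
total by default).  Within-module coexpression is uniform, so
coexpression separates modules, not individual true pairs inside a
module.

## Problem sizes and numerics

The test suite and the acceptance script run at deliberately modest
scale: the default 300-protein world (44,850 pairs), a 10,000-pair
calibration experiment, 499 permutations for annotation significance,
and an annealing battery of all connected ≤ 5-node graphs plus a spread
of 6-node graphs at 100 seeded runs each.  These sizes are the
package's own choice of a unit of reproducible evidence; every one of
them is a parameter.

Numerical conventions: LR bins upper-inclusive; tier bounds
lower-inclusive; pseudocount 0.5 per bin; the auto high cutoff stored as
an exact rational; discretization requires a strictly positive
information gain (ties broken toward no split) and cuts placed midway
between adjacent distinct scores; duplicate pair rows merge keeping the
maximum score; permutation p-values use the add-one estimator, so the
smallest attainable p is 1/(n_permutations + 1).

## Known limitations

- The conditional-independence assumption between the three integrated
  factors is asserted, not tested; with dependent layers the posterior
  odds are overconfident (the maximum rule for the functional factor is
  a blunt mitigation, not a fix).
- Prior odds must be supplied; the GSP/GSN ratio default is biased
  toward the gold-standard sampling, not the proteome-wide rate.
- The annealer assigns a single term per protein; multi-functional
  proteins are only captured through the significance step.
- Evidence layers are recalibrated from scratch per run; there is no
  mechanism for importing externally calibrated LR tables.
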