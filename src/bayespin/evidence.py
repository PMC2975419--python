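"""Per-pair evidence signals.

Seven heterogeneous signals feed the Bayesian integration:

* **ortholog** — interactions observed in another organism, transferred to
  the query proteome through an ortholog map (interologs); one boolean
  layer per source organism.
* **coexpression** — Pearson correlation of expression profiles.
* **domain** — a pair is supported when the two proteins carry a pair of
  domains known to interact (homotypic pairs count).
* **ssbp** — smallest shared biological process: the member count of the
  smallest GO BP term annotating both proteins after ancestor propagation;
  the smaller the shared term, the more specific the shared function.
* **gene_fusion** — homologs of the two proteins align to essentially
  non-overlapping regions of a single protein elsewhere (Rosetta stone).
* **gene_neighbor** — orthologs of the two proteins lie close together on
  the same contig in enough reference genomes.
* **phylo_profile** — similarity of presence/absence vectors across
  reference genomes.

Each layer carries values only on its *coverage*: pairs outside coverage
are "evidence absent", never score 0.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
from sklearn.metrics import mutual_info_score

from .io_formats import AnnotationTable, ExpressionMatrix, OntologyDag
from .pairs import Pair, SelfPairError, canonical_pair

log = logging.getLogger(__name__)

EVIDENCE_NAMES = (
    "ortholog",
    "coexpression",
    "domain",
    "ssbp",
    "gene_neighbor",
    "gene_fusion",
    "phylo_profile",
)


@dataclass
class EvidenceLayer:
    """Per-pair scores or flags for one evidence type.

    ``binary`` layers hold {0, 1} flags.  When ``complete`` is set, any
    pair absent from ``values`` is implicitly flag 0 and still covered
    (used for projection-style layers that only emit hits over a known
    pair universe); otherwise absent pairs are outside coverage.
    """

    name: str
    values: Dict[Pair, float] = field(default_factory=dict)
    binary: bool = False
    complete: bool = False

    def __post_init__(self) -> None:
        for pair, v in self.values.items():
            if not np.isfinite(v):
                raise ValueError(f"layer {self.name}: non-finite score for {pair}")
            if self.binary and v not in (0.0, 1.0):
                raise ValueError(f"layer {self.name}: binary layer with value {v}")

    @property
    def coverage(self) -> Set[Pair]:
        return set(self.values)

    def value(self, pair: Pair) -> Optional[float]:
        v = self.values.get(pair)
        if v is None and self.complete:
            return 0.0
        return v

    def flagged(self) -> Set[Pair]:
        return {p for p, v in self.values.items() if v == 1.0}

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class OrthologMap:
    """Source-organism protein -> set of query-proteome orthologs."""

    organism: str
    mapping: Dict[str, Set[str]]

    def __post_init__(self) -> None:
        for src, targets in self.mapping.items():
            if not targets:
                raise ValueError(f"ortholog map {self.organism}: empty target set for {src}")


@dataclass
class PhyloProfile:
    """Presence/absence bit vectors over an ordered reference-genome list."""

    genomes: List[str]
    vectors: Dict[str, np.ndarray]

    def __post_init__(self) -> None:
        n = len(self.genomes)
        if n < 1:
            raise ValueError("phylogenetic profile needs >= 1 genome")
        for protein, vec in self.vectors.items():
            vec = np.asarray(vec, dtype=int)
            if vec.shape != (n,):
                raise ValueError(f"profile length mismatch for {protein}")
            if not np.isin(vec, (0, 1)).all():
                raise ValueError(f"non-binary profile for {protein}")
            self.vectors[protein] = vec


@dataclass
class GeneContextTable:
    """Gene coordinates per reference genome plus ortholog links.

    ``genomes`` maps genome id -> gene -> (contig, start, end, strand);
    ``links`` maps genome id -> query protein -> genes in that genome.
    """

    genomes: Dict[str, Dict[str, Tuple[str, int, int, str]]]
    links: Dict[str, Dict[str, Set[str]]]

    def __post_init__(self) -> None:
        for genome, genes in self.genomes.items():
            for gene, (contig, start, end, strand) in genes.items():
                if start > end:
                    raise ValueError(f"{genome}/{gene}: start {start} > end {end}")
                if start <= 0:
                    raise ValueError(f"{genome}/{gene}: non-positive coordinate {start}")
                if strand not in {"+", "-"}:
                    raise ValueError(f"{genome}/{gene}: bad strand {strand!r}")


# ---------------------------------------------------------------------------
# ortholog projection


def project_orthologs(source_ppi, omap: OrthologMap) -> EvidenceLayer:
    """Transfer a source-organism interactome through an ortholog map.

    Every cross-product of the two proteins' ortholog sets yields a flagged
    query pair; self-pairs arising from shared orthologs are dropped.
    """
    if not omap.mapping:
        log.warning("ortholog map for %s is empty", omap.organism)
    values: Dict[Pair, float] = {}
    pairs = source_ppi.pairs if hasattr(source_ppi, "pairs") else set(source_ppi)
    for x, y in pairs:
        for a in omap.mapping.get(x, ()):
            for b in omap.mapping.get(y, ()):
                try:
                    values[canonical_pair(a, b)] = 1.0
                except SelfPairError:
                    continue
    return EvidenceLayer(
        name=f"ortholog:{omap.organism}", values=values, binary=True, complete=True
    )


# ---------------------------------------------------------------------------
# coexpression


def coexpression_scores(
    expr: ExpressionMatrix,
    pairs: Optional[Iterable[Pair]] = None,
) -> EvidenceLayer:
    """Pearson correlation of expression vectors for each covered pair.

    A pair is covered when both genes are present and neither vector has
    zero variance.  With ``pairs=None`` every gene pair is scored.
    """
    if len(expr.samples) < 3:
        raise ValueError(f"need >= 3 samples for correlation, got {len(expr.samples)}")
    stds = expr.values.std(axis=1)
    informative = {g for g, s in zip(expr.genes, stds) if s > 0}
    values: Dict[Pair, float] = {}
    if pairs is None:
        genes = sorted(informative)
        idx = [expr.genes.index(g) for g in genes]
        if len(genes) >= 2:
            corr = np.corrcoef(expr.values[idx])
            for i, j in itertools.combinations(range(len(genes)), 2):
                values[canonical_pair(genes[i], genes[j])] = float(corr[i, j])
    else:
        for pair in pairs:
            a, b = pair
            if a not in informative or b not in informative:
                continue
            va, vb = expr.vector(a), expr.vector(b)
            r = float(np.corrcoef(va, vb)[0, 1])
            values[canonical_pair(a, b)] = r
    return EvidenceLayer(name="coexpression", values=values)


# ---------------------------------------------------------------------------
# domain support


def domain_support(
    protein_domains: Mapping[str, Set[str]],
    ddi: Set[Pair],
    pairs: Iterable[Pair],
) -> EvidenceLayer:
    """Flag 1 when any domain of one protein interacts with any of the other.

    ``ddi`` holds canonical (sorted) domain pairs and may contain homotypic
    pairs.  Proteins without domains yield flag 0 but stay covered.
    """
    by_domain: Dict[str, Set[str]] = {}
    for protein, domains in protein_domains.items():
        for d in domains:
            by_domain.setdefault(d, set()).add(protein)
    flagged: Set[Pair] = set()
    for d, e in ddi:
        for a in by_domain.get(d, ()):
            for b in by_domain.get(e, ()):
                if a != b:
                    flagged.add(canonical_pair(a, b))
    values = {
        canonical_pair(*p): (1.0 if canonical_pair(*p) in flagged else 0.0)
        for p in pairs
    }
    return EvidenceLayer(name="domain", values=values, binary=True)


# ---------------------------------------------------------------------------
# smallest shared biological process


def propagate_bp_annotations(
    annotations: AnnotationTable, dag: OntologyDag
) -> Dict[str, Set[str]]:
    """Protein -> ancestor-closed set of BP terms (direct terms included)."""
    direct = annotations.protein_terms(aspect="BP")
    out: Dict[str, Set[str]] = {}
    for protein, terms in direct.items():
        closed: Set[str] = set()
        for term in terms:
            if term not in dag.terms:
                continue
            closed.add(term)
            closed.update(dag.ancestors(term))
        if closed:
            out[protein] = closed
    return out


def ssbp_scores(
    annotations: AnnotationTable,
    dag: OntologyDag,
    pairs: Iterable[Pair],
) -> EvidenceLayer:
    """Smallest-shared-BP-term member count per pair.

    Annotations are propagated to all ancestors; the per-term size is the
    number of proteins annotated (after propagation) to the term.  The
    score of a pair is the minimum size over terms shared by both
    proteins; pairs sharing no BP term are outside coverage.
    """
    propagated = propagate_bp_annotations(annotations, dag)
    term_size: Dict[str, int] = {}
    for terms in propagated.values():
        for t in terms:
            term_size[t] = term_size.get(t, 0) + 1
    values: Dict[Pair, float] = {}
    for pair in pairs:
        a, b = pair
        ta = propagated.get(a)
        tb = propagated.get(b)
        if not ta or not tb:
            continue
        shared = ta & tb
        if not shared:
            continue
        values[canonical_pair(a, b)] = float(min(term_size[t] for t in shared))
    return EvidenceLayer(name="ssbp", values=values)


# ---------------------------------------------------------------------------
# gene fusion


def gene_fusion_pairs(
    hits: Sequence[Tuple[str, str, int, int, str]],
    min_gap_fraction: float = 0.2,
    pairs: Optional[Iterable[Pair]] = None,
) -> EvidenceLayer:
    """Rosetta-stone flags from homology hits onto composite proteins.

    ``hits`` rows are (query_protein, target_protein, target_start,
    target_end, genome) with coordinates on the target.  A pair is flagged
    when both proteins hit the same target with aligned intervals whose
    overlap is below ``min_gap_fraction`` of the shorter interval.
    """
    if not 0 <= min_gap_fraction < 1:
        raise ValueError(f"min_gap_fraction must be in [0, 1), got {min_gap_fraction}")
    by_target: Dict[str, List[Tuple[str, int, int]]] = {}
    for query, target, start, end, _genome in hits:
        if start > end:
            raise ValueError(f"hit of {query} on {target}: start {start} > end {end}")
        by_target.setdefault(target, []).append((query, start, end))
    flagged: Set[Pair] = set()
    for target_hits in by_target.values():
        for (qa, sa, ea), (qb, sb, eb) in itertools.combinations(target_hits, 2):
            if qa == qb:
                continue
            overlap = max(0, min(ea, eb) - max(sa, sb) + 1)
            shorter = min(ea - sa + 1, eb - sb + 1)
            if overlap < min_gap_fraction * shorter:
                flagged.add(canonical_pair(qa, qb))
    if pairs is None:
        values = {p: 1.0 for p in flagged}
        return EvidenceLayer(name="gene_fusion", values=values, binary=True, complete=True)
    values = {canonical_pair(*p): (1.0 if canonical_pair(*p) in flagged else 0.0) for p in pairs}
    return EvidenceLayer(name="gene_fusion", values=values, binary=True)


# ---------------------------------------------------------------------------
# phylogenetic profile


def phylo_profile_scores(
    profiles: PhyloProfile,
    pairs: Optional[Iterable[Pair]] = None,
    metric: str = "hamming_similarity",
) -> EvidenceLayer:
    """Profile-similarity scores over the reference-genome panel.

    ``hamming_similarity`` is the fraction of matching bits; ``mutual_information``
    uses the 2x2 co-occurrence table.  All-zero and all-one profiles are
    uninformative and excluded from coverage.
    """
    if metric not in {"hamming_similarity", "mutual_information"}:
        raise ValueError(f"unknown metric {metric!r}")
    if len(profiles.genomes) < 4:
        raise ValueError("phylogenetic profiles need >= 4 genomes")
    informative = {
        p: v for p, v in profiles.vectors.items() if 0 < int(v.sum()) < len(v)
    }
    if pairs is None:
        pair_list = [
            canonical_pair(a, b) for a, b in itertools.combinations(sorted(informative), 2)
        ]
    else:
        pair_list = [canonical_pair(*p) for p in pairs]
    values: Dict[Pair, float] = {}
    for pair in pair_list:
        a, b = pair
        va = informative.get(a)
        vb = informative.get(b)
        if va is None or vb is None:
            continue
        if metric == "hamming_similarity":
            values[pair] = float((va == vb).mean())
        else:
            values[pair] = float(mutual_info_score(va, vb))
    return EvidenceLayer(name="phylo_profile", values=values)


# ---------------------------------------------------------------------------
# gene neighbor


def _intergenic_gap(g1: Tuple[str, int, int, str], g2: Tuple[str, int, int, str]) -> Optional[int]:
    """Gap in bp between two genes on the same contig (0 when overlapping)."""
    if g1[0] != g2[0]:
        return None
    gap = max(g1[1], g2[1]) - min(g1[2], g2[2]) - 1
    return max(0, gap)


def gene_neighbor_pairs(
    context: GeneContextTable,
    max_distance: int = 5000,
    min_genomes: int = 2,
    pairs: Optional[Iterable[Pair]] = None,
) -> EvidenceLayer:
    """Conserved chromosomal adjacency flags.

    A pair is flagged when, in at least ``min_genomes`` reference genomes,
    orthologs of the two proteins sit on the same contig with an
    intergenic gap of at most ``max_distance`` bp.
    """
    if max_distance <= 0:
        raise ValueError(f"max_distance must be > 0, got {max_distance}")
    if min_genomes < 1:
        raise ValueError(f"min_genomes must be >= 1, got {min_genomes}")

    def genomes_adjacent(a: str, b: str) -> int:
        count = 0
        for genome, coords in context.genomes.items():
            links = context.links.get(genome, {})
            found = False
            for ga in links.get(a, ()):
                ca = coords.get(ga)
                if ca is None:
                    continue
                for gb in links.get(b, ()):
                    cb = coords.get(gb)
                    if cb is None:
                        continue
                    gap = _intergenic_gap(ca, cb)
                    if gap is not None and gap <= max_distance:
                        found = True
                        break
                if found:
                    break
            if found:
                count += 1
        return count

    if pairs is None:
        proteins = sorted({p for links in context.links.values() for p in links})
        pair_list = [canonical_pair(a, b) for a, b in itertools.combinations(proteins, 2)]
        values = {
            p: 1.0 for p in pair_list if genomes_adjacent(p[0], p[1]) >= min_genomes
        }
        return EvidenceLayer(name="gene_neighbor", values=values, binary=True, complete=True)
    values = {}
    for pair in pairs:
        pair = canonical_pair(*pair)
        values[pair] = 1.0 if genomes_adjacent(pair[0], pair[1]) >= min_genomes else 0.0
    return EvidenceLayer(name="gene_neighbor", values=values, binary=True)
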