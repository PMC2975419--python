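"""Network validation analyses.

Three checks of a predicted interactome against independent resources:

* **conservation** — map predicted pairs back into a reference organism
  through ortholog maps and look the mapped pairs up in that organism's
  curated interactome (pairs whose only supporting evidence was the
  reference organism's own interolog layer are excluded to avoid
  circularity);
* **pathway hubs** — proteins joining many pathways should be network
  hubs: compare their mean degree with the network-wide mean;
* **neighborhood enrichment** — hypergeometric GO-term overrepresentation
  (with Benjamini-Hochberg correction) in the first-level neighborhood of
  a seed protein set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Set, Tuple

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .bayes import ScoredNetwork, ORTHOLOG_PREFIX
from .evidence import OrthologMap
from .io_formats import AnnotationTable, OntologyDag
from .pairs import Pair, SelfPairError, canonical_pair

log = logging.getLogger(__name__)


@dataclass
class ConservationReport:
    """Rows: (query pair, organism, mapped pair, found in reference)."""

    rows: List[Tuple[Pair, str, Pair, bool]] = field(default_factory=list)

    def found(self, organism: Optional[str] = None) -> List[Tuple[Pair, str, Pair, bool]]:
        return [
            r for r in self.rows if r[3] and (organism is None or r[1] == organism)
        ]

    def n_found_pairs(self, organism: Optional[str] = None) -> int:
        """Distinct query pairs with at least one conserved mapped pair."""
        return len({r[0] for r in self.found(organism)})


@dataclass
class EnrichmentRow:
    term_id: str
    p_value: float
    q_value: float
    k: int  # annotated proteins in the tested set
    K: int  # annotated proteins in the background
    n: int  # tested-set size
    N: int  # background size

    def __post_init__(self) -> None:
        if not (0 <= self.k <= min(self.K, self.n)):
            raise ValueError(f"inconsistent counts for {self.term_id}")
        if not 0 < self.p_value <= 1:
            raise ValueError(f"p-value out of range for {self.term_id}")


def map_conservation(
    predicted: ScoredNetwork,
    maps: Mapping[str, OrthologMap],
    references: Mapping[str, object],
    exclude_sources: Set[str] = frozenset(),
) -> ConservationReport:
    """Reverse-map predicted pairs into reference organisms and look them up.

    ``maps`` must carry *reversed* ortholog maps (query protein -> proteins
    of the reference organism).  A predicted pair is skipped for an
    organism in ``exclude_sources`` when that organism's interolog layer is
    its only supporting evidence.
    """
    rows: List[Tuple[Pair, str, Pair, bool]] = []
    excluded_keys = {f"{ORTHOLOG_PREFIX}{org}" for org in exclude_sources}
    for pair, score in sorted(predicted.rows.items()):
        contributing = set(score.evidence_lrs)
        if contributing and contributing <= excluded_keys:
            continue
        a, b = pair
        for organism, omap in maps.items():
            ref = references[organism]
            ref_pairs = ref.pairs if hasattr(ref, "pairs") else set(ref)
            for x in sorted(omap.mapping.get(a, ())):
                for y in sorted(omap.mapping.get(b, ())):
                    try:
                        mapped = canonical_pair(x, y)
                    except SelfPairError:
                        continue
                    rows.append((pair, organism, mapped, mapped in ref_pairs))
    return ConservationReport(rows=rows)


def hub_degree_report(
    network: ScoredNetwork,
    pathway_membership: Mapping[str, Set[str]],
    hub_min_pathways: int = 10,
) -> Tuple[Optional[float], float]:
    """(mean degree of pathway hubs, mean degree of all network nodes).

    Hubs are proteins joining *strictly more than* ``hub_min_pathways``
    pathways.  Returns ``None`` for the hub mean when there are no hubs.
    """
    if hub_min_pathways < 1:
        raise ValueError(f"hub_min_pathways must be >= 1, got {hub_min_pathways}")
    degree = network.degree()
    nodes = network.nodes()
    if not nodes:
        raise ValueError("empty network")
    hubs = {
        p for p in nodes if len(pathway_membership.get(p, ())) > hub_min_pathways
    }
    mean_all = sum(degree.get(n, 0) for n in nodes) / len(nodes)
    if not hubs:
        return None, mean_all
    mean_hubs = sum(degree.get(h, 0) for h in hubs) / len(hubs)
    return mean_hubs, mean_all


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n); k = 0 gives 1 exactly."""
    if k <= 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def neighborhood_enrichment(
    seed_set: Set[str],
    network: ScoredNetwork,
    annotations: AnnotationTable,
    dag: Optional[OntologyDag] = None,
    background: Optional[Set[str]] = None,
    include_seeds: bool = False,
    aspect: Optional[str] = None,
) -> List[EnrichmentRow]:
    """GO-term overrepresentation in the seeds' first-level neighborhood.

    Annotations are ancestor-propagated when a DAG is supplied.  For each
    term annotating at least one neighbor, the hypergeometric upper-tail
    p-value of the neighbor count is computed against the background
    (default: all network nodes); q-values are Benjamini-Hochberg.
    """
    adj = network.adjacency()
    neighbors: Set[str] = set()
    for s in seed_set:
        neighbors |= adj.get(s, set())
    if not include_seeds:
        neighbors -= set(seed_set)
    if not neighbors:
        raise ValueError("seed set has no network neighbors")
    if background is None:
        background = network.nodes()
    if not neighbors <= background:
        raise ValueError("background must contain every seed neighbor")

    direct = annotations.protein_terms(aspect=aspect)
    annotated: Dict[str, Set[str]] = {}
    for protein, terms in direct.items():
        if protein not in background:
            continue
        closed = set()
        for t in terms:
            if dag is not None and t in dag.terms:
                closed.add(t)
                closed.update(dag.ancestors(t))
            else:
                closed.add(t)
        annotated[protein] = closed

    term_background: Dict[str, int] = {}
    term_hits: Dict[str, int] = {}
    for protein, terms in sorted(annotated.items()):
        for t in terms:
            term_background[t] = term_background.get(t, 0) + 1
            if protein in neighbors:
                term_hits[t] = term_hits.get(t, 0) + 1

    N = len(background)
    n = len(neighbors)
    terms = sorted(term_hits)
    pvals = [
        hypergeom_upper_tail(term_hits[t], N, term_background[t], n) for t in terms
    ]
    if pvals:
        _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    else:
        qvals = []
    rows = [
        EnrichmentRow(
            term_id=t,
            p_value=p,
            q_value=float(q),
            k=term_hits[t],
            K=term_background[t],
            n=n,
            N=N,
        )
        for t, p, q in zip(terms, pvals, qvals)
    ]
    rows.sort(key=lambda r: (r.p_value, r.term_id))
    return rows
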