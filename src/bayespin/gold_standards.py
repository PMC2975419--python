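"""Gold standard positive / negative interaction sets.

The positive set (GSP) is the union of curated interaction pairs and a
bounded all-pairs expansion of small enzyme complexes: complexes with
``max_size`` or more members are assumed to be dominated by indirect
co-membership and contribute nothing.  The negative set (GSN) pairs
proteins whose experimentally supported cellular-component annotations are
disjoint.  Pairs that land in both sets are removed from both during
reconciliation and recorded.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Set

import numpy as np

from .io_formats import AnnotationTable, OntologyDag, PairTable
from .pairs import Pair, canonical_pair

log = logging.getLogger(__name__)

DEFAULT_EVIDENCE_CODES = frozenset({"IC", "IDA", "IPI"})
DEFAULT_MAX_COMPLEX_SIZE = 18


@dataclass
class GoldStandard:
    """Reconciled labeled pair sets used to calibrate evidence layers."""

    positives: Set[Pair]
    negatives: Set[Pair]
    provenance: Dict[Pair, str] = field(default_factory=dict)
    removed_overlap: Set[Pair] = field(default_factory=set)

    def __post_init__(self) -> None:
        overlap = self.positives & self.negatives
        if overlap:
            raise ValueError(f"gold standard not reconciled: {len(overlap)} overlapping pairs")

    @property
    def n_positive(self) -> int:
        return len(self.positives)

    @property
    def n_negative(self) -> int:
        return len(self.negatives)

    def label(self, pair: Pair) -> Optional[bool]:
        if pair in self.positives:
            return True
        if pair in self.negatives:
            return False
        return None


def expand_complexes(
    complexes: Mapping[str, Set[str]],
    max_size: int = DEFAULT_MAX_COMPLEX_SIZE,
) -> Set[Pair]:
    """All unordered member pairs of complexes with < ``max_size`` members.

    The bound is exclusive: a complex with exactly ``max_size`` members
    contributes nothing.  Size-1 complexes trivially contribute no pairs.
    """
    if max_size < 2:
        raise ValueError(f"max_size must be >= 2, got {max_size}")
    pairs: Set[Pair] = set()
    for members in complexes.values():
        if not members:
            raise ValueError("empty complex in complex table")
        if len(members) >= max_size:
            continue
        for a, b in itertools.combinations(sorted(members), 2):
            pairs.add(canonical_pair(a, b))
    return pairs


def build_gsp(
    curated: PairTable,
    complexes: Mapping[str, Set[str]],
    max_complex_size: int = DEFAULT_MAX_COMPLEX_SIZE,
) -> tuple[Set[Pair], Dict[Pair, str]]:
    """Union curated pairs with bounded complex expansion.

    Returns the positive pair set and a provenance map with values in
    {``curated``, ``complex``, ``both``}.
    """
    curated_pairs = curated.pairs
    complex_pairs = expand_complexes(complexes, max_complex_size)
    positives = curated_pairs | complex_pairs
    if not positives:
        raise ValueError("gold standard positive set is empty; cannot calibrate evidence")
    provenance = {}
    for pair in positives:
        in_cur = pair in curated_pairs
        in_cx = pair in complex_pairs
        provenance[pair] = "both" if (in_cur and in_cx) else ("curated" if in_cur else "complex")
    return positives, provenance


def build_gsn(
    annotations: AnnotationTable,
    allowed_codes: Set[str] = DEFAULT_EVIDENCE_CODES,
    protein_universe: Optional[Set[str]] = None,
    ontology: Optional[OntologyDag] = None,
    propagate: bool = False,
    max_pairs: Optional[int] = None,
    seed: int = 0,
) -> Set[Pair]:
    """Pairs of proteins with disjoint high-quality localization annotations.

    A pair qualifies as a negative iff both proteins carry at least one
    cellular-component annotation with an allowed evidence code and their
    allowed-code CC term sets are disjoint.  By default disjointness is
    tested on directly annotated terms; with ``propagate`` the test uses
    ancestor-closed sets minus ontology roots (closure including roots
    would make every pair share the CC root and empty the set).

    ``max_pairs`` subsamples the (potentially enormous) result with a
    seeded RNG.
    """
    if not allowed_codes:
        raise ValueError("allowed_codes must be non-empty")
    cc_terms = annotations.protein_terms(aspect="CC", codes=set(allowed_codes))
    if propagate:
        if ontology is None:
            raise ValueError("propagate=True requires an ontology")
        roots = ontology.roots()
        cc_terms = {
            p: {t for term in ts for t in ({term} | set(ontology.ancestors(term)))} - set(roots)
            for p, ts in cc_terms.items()
        }
        cc_terms = {p: ts for p, ts in cc_terms.items() if ts}
    qualified = sorted(cc_terms)
    if protein_universe is not None:
        qualified = [p for p in qualified if p in protein_universe]
    negatives: Set[Pair] = set()
    for a, b in itertools.combinations(qualified, 2):
        if cc_terms[a].isdisjoint(cc_terms[b]):
            negatives.add(canonical_pair(a, b))
    if not negatives:
        log.warning("gold standard negative set is empty")
    if max_pairs is not None and len(negatives) > max_pairs:
        rng = np.random.default_rng(seed)
        ordered = sorted(negatives)
        idx = rng.choice(len(ordered), size=max_pairs, replace=False)
        negatives = {ordered[i] for i in sorted(idx)}
    return negatives


def reconcile(
    positives: Set[Pair],
    negatives: Set[Pair],
    provenance: Optional[Dict[Pair, str]] = None,
) -> GoldStandard:
    """Remove pairs present in both sets from both, recording the overlap."""
    overlap = set(positives) & set(negatives)
    pos = set(positives) - overlap
    neg = set(negatives) - overlap
    if not pos or not neg:
        raise ValueError(
            "gold standard empty after reconciliation "
            f"(positives={len(pos)}, negatives={len(neg)})"
        )
    prov = {p: t for p, t in (provenance or {}).items() if p in pos}
    return GoldStandard(
        positives=pos, negatives=neg, provenance=prov, removed_overlap=overlap
    )
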