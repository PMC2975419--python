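"""Guilt-by-association function annotation over the interaction network.

Function-unknown proteins are assigned terms by minimizing, with simulated
annealing, the number of network edges whose endpoints share no term:

    E(assignment) = - sum over edges (u, v) of match(u, v)

where ``match`` is 1 when the two endpoints share at least one term
(known or currently assigned).  Each unknown protein carries exactly one
term during the search, drawn from its neighbors' known terms (or, for
isolated unknowns, from the global vocabulary).  Metropolis acceptance
with geometric cooling; the best state seen is returned, so the reported
energy never exceeds the initial one.

Significance of a (protein, term) annotation is scored by permutation:
the observed statistic is the number of network neighbors already known
to carry the term, and the null redistributes the known proteins' term
sets network-wide.  The add-one estimate p = (r + 1) / (n + 1) is used.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Set, Tuple

import numpy as np

from .pairs import Pair

log = logging.getLogger(__name__)

DEFAULT_SIGNIFICANCE = 0.0517  # conventional threshold of this scheme; see docs


@dataclass
class AnnealSchedule:
    """Geometric cooling schedule."""

    t0: float = 1.0
    alpha: float = 0.9
    steps_per_t: int = 100
    t_min: float = 1e-3

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.steps_per_t < 0:
            raise ValueError("steps_per_t must be >= 0")
        if self.t0 <= self.t_min:
            raise ValueError(f"t0 ({self.t0}) must exceed t_min ({self.t_min})")


@dataclass
class AnnealState:
    """Best assignment found, its energy, and the final temperature."""

    assignment: Dict[str, str]
    energy: float
    temperature: float
    rng_seed: int


@dataclass
class AnnotationResult:
    """Permutation-scored (protein, term) annotation pairs."""

    rows: List[Tuple[str, str, float, int, bool]] = field(default_factory=list)
    threshold: float = DEFAULT_SIGNIFICANCE

    def significant(self) -> List[Tuple[str, str, float]]:
        return [(p, t, pv) for p, t, pv, _n, sig in self.rows if sig]

    def __len__(self) -> int:
        return len(self.rows)


def _edges_of(network) -> List[Pair]:
    if hasattr(network, "rows"):
        return list(network.rows)
    return list(network)


def candidate_vocabulary(
    edges: Iterable[Pair],
    known: Mapping[str, Set[str]],
    unknowns: Set[str],
) -> Dict[str, Tuple[str, ...]]:
    """Candidate term tuple per unknown: neighbors' known terms, sorted.

    Unknowns with no annotated neighbor fall back to the global vocabulary
    (union of all known terms).
    """
    adj: Dict[str, Set[str]] = {}
    for a, b in edges:
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    global_vocab = tuple(sorted({t for ts in known.values() for t in ts}))
    if not global_vocab:
        raise ValueError("no known annotations: cannot build a candidate vocabulary")
    vocab: Dict[str, Tuple[str, ...]] = {}
    for u in sorted(unknowns):
        terms = {t for nb in adj.get(u, ()) if nb in known for t in known[nb]}
        vocab[u] = tuple(sorted(terms)) if terms else global_vocab
    return vocab


def annotation_energy(
    edges: Iterable[Pair],
    known: Mapping[str, Set[str]],
    assignment: Mapping[str, str],
) -> float:
    """-(number of edges whose endpoints share at least one term)."""

    def terms(p: str) -> FrozenSet[str]:
        if p in known:
            return frozenset(known[p])
        t = assignment.get(p)
        return frozenset((t,)) if t is not None else frozenset()

    e = 0
    for a, b in edges:
        if terms(a) & terms(b):
            e -= 1
    return float(e)


def anneal_annotations(
    network,
    known: Mapping[str, Set[str]],
    unknowns: Set[str],
    schedule: Optional[AnnealSchedule] = None,
    seed: int = 0,
) -> AnnealState:
    """Simulated-annealing term assignment for the unknown proteins.

    Deterministic given ``seed``; the best-seen assignment is returned, so
    the final energy is never above the initial one.
    """
    if not unknowns:
        raise ValueError("no unknown proteins to annotate")
    schedule = schedule or AnnealSchedule()
    edges = _edges_of(network)
    vocab = candidate_vocabulary(edges, known, unknowns)
    rng = np.random.default_rng(seed)

    # adjacency restricted to edges that can change: those touching an unknown
    unknown_list = sorted(unknowns)
    incident: Dict[str, List[str]] = {u: [] for u in unknown_list}
    for a, b in edges:
        if a in unknowns:
            incident[a].append(b)
        if b in unknowns:
            incident[b].append(a)

    assignment = {
        u: vocab[u][int(rng.integers(len(vocab[u])))] for u in unknown_list
    }

    def terms(p: str) -> FrozenSet[str]:
        if p in known:
            return frozenset(known[p])
        return frozenset((assignment[p],)) if p in assignment else frozenset()

    def local_energy(u: str, term: str) -> int:
        """Contribution of edges incident to u when u carries ``term``."""
        e = 0
        for nb in incident[u]:
            nb_terms = terms(nb)
            if term in nb_terms:
                e -= 1
        return e

    energy = annotation_energy(edges, known, assignment)
    best_energy = energy
    best_assignment = dict(assignment)

    t = schedule.t0
    movable = [u for u in unknown_list if len(vocab[u]) > 1]
    while t > schedule.t_min and movable:
        for _ in range(schedule.steps_per_t):
            u = movable[int(rng.integers(len(movable)))]
            current = assignment[u]
            options = vocab[u]
            proposal = options[int(rng.integers(len(options)))]
            if proposal == current:
                continue
            d_e = local_energy(u, proposal) - local_energy(u, current)
            if d_e <= 0 or rng.random() < math.exp(-d_e / t):
                assignment[u] = proposal
                energy += d_e
                if energy < best_energy:
                    best_energy = energy
                    best_assignment = dict(assignment)
        t *= schedule.alpha
    return AnnealState(
        assignment=best_assignment,
        energy=best_energy,
        temperature=t,
        rng_seed=seed,
    )


def annotation_pvalues(
    network,
    known: Mapping[str, Set[str]],
    result: AnnealState,
    n_permutations: int = 999,
    seed: int = 0,
    threshold: float = DEFAULT_SIGNIFICANCE,
) -> AnnotationResult:
    """Permutation p-values for every candidate (unknown, term) pair.

    For each unknown protein every term in its candidate vocabulary (plus
    the annealed assignment) is tested.  The null shuffles which known
    protein carries which term set, network-wide; p = (r + 1) / (n + 1)
    where r counts permutations with statistic >= observed.
    """
    if n_permutations < 1:
        raise ValueError(f"n_permutations must be >= 1, got {n_permutations}")
    edges = _edges_of(network)
    unknowns = set(result.assignment)
    vocab = candidate_vocabulary(edges, known, unknowns)
    adj: Dict[str, Set[str]] = {}
    for a, b in edges:
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)

    known_list = sorted(known)
    known_index = {p: i for i, p in enumerate(known_list)}
    term_sets = [frozenset(known[p]) for p in known_list]

    tests: List[Tuple[str, str, List[int], int]] = []  # protein, term, nbr idx, observed
    for u in sorted(unknowns):
        nbr_idx = [known_index[nb] for nb in sorted(adj.get(u, ())) if nb in known_index]
        terms = set(vocab[u]) | {result.assignment[u]}
        for term in sorted(terms):
            observed = sum(1 for i in nbr_idx if term in term_sets[i])
            tests.append((u, term, nbr_idx, observed))

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(tests), dtype=int)
    n_known = len(known_list)
    for _ in range(n_permutations):
        perm = rng.permutation(n_known)
        for j, (_u, term, nbr_idx, observed) in enumerate(tests):
            stat = sum(1 for i in nbr_idx if term in term_sets[perm[i]])
            if stat >= observed:
                exceed[j] += 1

    rows = []
    for j, (u, term, _nbr, _obs) in enumerate(tests):
        p = (int(exceed[j]) + 1) / (n_permutations + 1)
        rows.append((u, term, p, n_permutations, p < threshold))
    return AnnotationResult(rows=rows, threshold=threshold)


def write_annotation_result(result: AnnotationResult, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("protein\tterm\tp_value\tn_permutations\tsignificant\n")
        for protein, term, p, n, sig in sorted(result.rows):
            fh.write(f"{protein}\t{term}\t{p:.12g}\t{n}\t{'1' if sig else '0'}\n")
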