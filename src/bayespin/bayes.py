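"""Likelihood-ratio calibration and naive-Bayes evidence integration.

Each evidence layer is calibrated against the gold standard: the score
range is binned (binary layers use their two flags, continuous layers use
entropy-based supervised discretization) and each bin receives a
likelihood ratio

    LR(bin) = P(bin | interacting) / P(bin | non-interacting)

with optional additive smoothing.  Under the conditional-independence
assumption the posterior odds of interaction are

    O_post = O_prior * prod_i LR_i .

Because the genome-context signals (gene neighbor, gene fusion,
phylogenetic profile) and the shared-biological-process signal all proxy
functional linkage rather than physical contact, they are collapsed into a
single "functional" factor: the *maximum* LR among the four, admitted only
when the pair is supported by an interacting domain pair (the domain
gate).  The total LR is the product of the best ortholog-interactome LR,
the coexpression LR and the functional factor; pairs are then tiered
high / medium / low by LR cutoffs.
"""

from __future__ import annotations

import logging
import math
from bisect import bisect_left
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple, Union

import numpy as np

from .evidence import EvidenceLayer
from .gold_standards import GoldStandard
from .pairs import Pair

log = logging.getLogger(__name__)

TIERS = ("high", "medium", "low")


# ---------------------------------------------------------------------------
# LR models


@dataclass
class LRModel:
    """Learned bin -> likelihood-ratio mapping for one evidence type.

    ``kind`` is ``binary`` (bins = absent/present flags) or ``binned``
    (bins = half-open intervals cut at ``edges``; bin ``i`` covers
    ``(edges[i-1], edges[i]]`` with open ends at +-infinity).
    """

    evidence_name: str
    kind: str
    lr: Dict[int, float]
    edges: Optional[Tuple[float, ...]] = None
    pseudocount: float = 0.0
    n_pos_used: int = 0
    n_neg_used: int = 0

    def __post_init__(self) -> None:
        if self.kind not in {"binary", "binned"}:
            raise ValueError(f"kind must be binary|binned, got {self.kind!r}")
        for b, v in self.lr.items():
            if not (math.isfinite(v) and v > 0):
                raise ValueError(
                    f"{self.evidence_name}: LR for bin {b} is {v}; "
                    "use a pseudocount to keep ratios finite and positive"
                )

    @property
    def n_bins(self) -> int:
        return len(self.lr)

    def bin_of(self, value: float) -> int:
        if self.kind == "binary":
            return int(value)
        return bisect_left(self.edges or (), value)

    def lookup(self, value: float) -> float:
        return self.lr[self.bin_of(value)]

    @property
    def lr_present(self) -> float:
        """LR of the 'present' flag of a binary layer."""
        if self.kind != "binary":
            raise ValueError(f"{self.evidence_name} is not a binary model")
        return self.lr[1]


BinSpec = Union[str, Sequence[float]]


def estimate_lr(
    layer: EvidenceLayer,
    gold: GoldStandard,
    bins: BinSpec = "binary",
    pseudocount: float = 0.5,
) -> LRModel:
    """Calibrate one evidence layer against the gold standard.

    With ``B`` bins and pseudocount ``c``::

        LR(bin) = [(n_pos_in_bin + c) / (N_pos + c*B)]
                / [(n_neg_in_bin + c) / (N_neg + c*B)]

    Counts are restricted to gold pairs inside the layer's coverage
    (complete binary layers cover every pair, with implicit flag 0).
    """
    if pseudocount < 0:
        raise ValueError(f"pseudocount must be >= 0, got {pseudocount}")
    if isinstance(bins, str):
        if bins != "binary":
            raise ValueError(f"bins must be 'binary' or a sequence of cuts, got {bins!r}")
        kind, edges, n_bins = "binary", None, 2
    else:
        kind = "binned"
        edges = tuple(sorted(float(e) for e in bins))
        n_bins = len(edges) + 1

    def bin_of(value: float) -> int:
        return int(value) if kind == "binary" else bisect_left(edges, value)

    pos_counts = [0] * n_bins
    neg_counts = [0] * n_bins
    for pair_set, counts in ((gold.positives, pos_counts), (gold.negatives, neg_counts)):
        for pair in pair_set:
            v = layer.value(pair)
            if v is None:
                continue
            counts[bin_of(v)] += 1
    n_pos = sum(pos_counts)
    n_neg = sum(neg_counts)
    if n_pos == 0 or n_neg == 0:
        raise ValueError(
            f"layer {layer.name}: gold standard provides {n_pos} positives and "
            f"{n_neg} negatives inside coverage; cannot estimate LRs"
        )
    c = float(pseudocount)
    lr: Dict[int, float] = {}
    for b in range(n_bins):
        p_pos = (pos_counts[b] + c) / (n_pos + c * n_bins)
        p_neg = (neg_counts[b] + c) / (n_neg + c * n_bins)
        if p_pos == 0 or p_neg == 0:
            raise ValueError(
                f"layer {layer.name}: bin {b} has a zero class count; "
                "use a positive pseudocount"
            )
        lr[b] = p_pos / p_neg
    return LRModel(
        evidence_name=layer.name,
        kind=kind,
        lr=lr,
        edges=edges,
        pseudocount=c,
        n_pos_used=n_pos,
        n_neg_used=n_neg,
    )


# ---------------------------------------------------------------------------
# supervised discretization


def _entropy(n_pos: int, n_neg: int) -> float:
    n = n_pos + n_neg
    if n == 0:
        return 0.0
    h = 0.0
    for k in (n_pos, n_neg):
        if k:
            p = k / n
            h -= p * math.log2(p)
    return h


def supervised_discretize(
    scores: Sequence[float],
    labels: Sequence[int],
    max_bins: int = 8,
    min_leaf: int = 10,
) -> List[float]:
    """Entropy-gain recursive binary splitting of a score axis.

    Greedily applies the split with the largest information gain until the
    bin budget is exhausted, no split has positive gain, or a split would
    create a leaf smaller than ``min_leaf``.  Returns sorted cut points;
    cut ``c`` separates values ``<= c`` from values ``> c``.
    """
    if len(scores) != len(labels):
        raise ValueError("scores and labels must have equal length")
    if len(scores) < 2 * min_leaf:
        raise ValueError(f"need >= {2 * min_leaf} labeled points, got {len(scores)}")
    order = np.argsort(np.asarray(scores, dtype=float), kind="stable")
    xs = np.asarray(scores, dtype=float)[order]
    ys = np.asarray(labels, dtype=int)[order]
    if xs[0] == xs[-1]:
        log.warning("all scores identical; single bin")
        return []

    def best_split(lo: int, hi: int) -> Optional[Tuple[float, float, int]]:
        """Best (gain, cut, split_index) for xs[lo:hi]; None if no legal split."""
        seg_y = ys[lo:hi]
        n = hi - lo
        total_pos = int(seg_y.sum())
        base = _entropy(total_pos, n - total_pos)
        best: Optional[Tuple[float, float, int]] = None
        cum_pos = 0
        for i in range(1, n):
            cum_pos += int(seg_y[i - 1])
            if xs[lo + i] == xs[lo + i - 1]:
                continue
            if i < min_leaf or n - i < min_leaf:
                continue
            h = (i / n) * _entropy(cum_pos, i - cum_pos) + ((n - i) / n) * _entropy(
                total_pos - cum_pos, n - i - (total_pos - cum_pos)
            )
            gain = base - h
            if gain > 1e-12 and (best is None or gain > best[0]):
                cut = (xs[lo + i - 1] + xs[lo + i]) / 2.0
                best = (gain, cut, lo + i)
        return best

    segments: List[Tuple[int, int]] = [(0, len(xs))]
    cuts: List[float] = []
    while len(segments) < max_bins:
        candidates = [(best_split(lo, hi), (lo, hi)) for lo, hi in segments]
        candidates = [(c, seg) for c, seg in candidates if c is not None]
        if not candidates:
            break
        (gain, cut, split_at), (lo, hi) = max(candidates, key=lambda t: t[0][0])
        segments.remove((lo, hi))
        segments.extend([(lo, split_at), (split_at, hi)])
        cuts.append(cut)
    return sorted(cuts)


# ---------------------------------------------------------------------------
# combination rules


def combine_functional(
    lr_neighbor: Optional[float] = None,
    lr_fusion: Optional[float] = None,
    lr_profile: Optional[float] = None,
    lr_ssbp: Optional[float] = None,
    domain_flag: bool = False,
) -> float:
    """Domain-gated maximum over the functional-linkage LRs.

    The four inputs proxy shared function, not physical contact, and are
    mutually dependent (all sequence-derived), so instead of multiplying
    them the combination takes their maximum — and admits it only when the
    pair is supported by an interacting domain pair.  Without domain
    support, or with no functional evidence at all, the factor is 1.
    """
    present = [x for x in (lr_neighbor, lr_fusion, lr_profile, lr_ssbp) if x is not None]
    for x in present:
        if x <= 0:
            raise ValueError(f"LR values must be positive, got {x}")
    if not domain_flag or not present:
        return 1.0
    return max(present)


def posterior_from_lrs(lrs: Iterable[float], prior_odds: float) -> Tuple[float, float]:
    """Naive-Bayes product: (lr_total, posterior_odds)."""
    lr_total = 1.0
    for lr in lrs:
        if lr <= 0:
            raise ValueError(f"LR values must be positive, got {lr}")
        lr_total *= lr
    return lr_total, prior_odds * lr_total


def integrate(
    lr_ortholog_by_organism: Mapping[str, float],
    lr_coexp: Optional[float],
    lr_functional: float,
    config: "IntegrationConfig",
) -> Tuple[float, float]:
    """Final product of the three independent factors.

    The ortholog factor is the *largest* LR across source organisms (the
    per-organism interactomes are alternative estimates of the same
    signal); missing evidence contributes the neutral LR 1.
    """
    lr_orth = max(lr_ortholog_by_organism.values()) if lr_ortholog_by_organism else 1.0
    lrs = [lr_orth, lr_coexp if lr_coexp is not None else config.missing_lr, lr_functional]
    return posterior_from_lrs(lrs, config.prior_odds)


def derive_medium_cutoff(lr_models_ortholog: Mapping[str, LRModel]) -> float:
    """Minimum single-flag ortholog LR across source organisms.

    Ortholog transfer is the most trusted single signal, so the weakest
    organism's LR marks the floor of the medium-confidence tier.
    """
    if not lr_models_ortholog:
        raise ValueError("need at least one ortholog LR model")
    return min(m.lr_present for m in lr_models_ortholog.values())


# ---------------------------------------------------------------------------
# configuration / network


@dataclass
class IntegrationConfig:
    """Prior odds and tier cutoffs.

    With ``high_cutoff=None`` the high-confidence cutoff is derived from
    the posterior-odds-one criterion: O_post = O_prior * LR = 1, i.e.
    cutoff = 1 / O_prior (kept as an exact rational so cutoff * prior_odds
    is exactly 1).  ``medium_cutoff=None`` defaults to the high cutoff
    (empty medium tier) until a value — typically from
    :func:`derive_medium_cutoff` — is supplied.
    """

    prior_odds: float
    high_cutoff: Optional[Union[float, Fraction]] = None
    medium_cutoff: Optional[Union[float, Fraction]] = None
    missing_lr: float = 1.0

    def __post_init__(self) -> None:
        if not (self.prior_odds > 0 and math.isfinite(self.prior_odds)):
            raise ValueError(f"prior_odds must be a positive finite real, got {self.prior_odds}")
        if self.high_cutoff is None:
            self.high_cutoff = Fraction(1) / Fraction(self.prior_odds)
        if self.high_cutoff <= 0:
            raise ValueError("high_cutoff must be > 0")
        if self.medium_cutoff is None:
            self.medium_cutoff = self.high_cutoff  # same exact value; empty medium tier
        if self.medium_cutoff <= 0:
            raise ValueError("medium_cutoff must be > 0")
        if self.medium_cutoff > self.high_cutoff:
            raise ValueError(
                f"medium_cutoff {self.medium_cutoff} exceeds high_cutoff {self.high_cutoff}"
            )


@dataclass
class PairScore:
    """Scores of one network pair: per-evidence LRs, totals and tier."""

    evidence_lrs: Dict[str, float]
    lr_functional: float
    lr_total: float
    posterior_odds: float
    tier: str


@dataclass
class ScoredNetwork:
    """Pairs with integrated LRs, posterior odds and confidence tiers."""

    rows: Dict[Pair, PairScore] = field(default_factory=dict)
    config: Optional[IntegrationConfig] = None

    def __len__(self) -> int:
        return len(self.rows)

    def __contains__(self, pair: Pair) -> bool:
        return pair in self.rows

    def nodes(self) -> Set[str]:
        return {p for pair in self.rows for p in pair}

    def edges(self, tiers: Optional[Set[str]] = None) -> List[Pair]:
        if tiers is None:
            return list(self.rows)
        return [pair for pair, score in self.rows.items() if score.tier in tiers]

    def subnetwork(self, tiers: Set[str]) -> "ScoredNetwork":
        rows = {p: s for p, s in self.rows.items() if s.tier in tiers}
        return ScoredNetwork(rows=rows, config=self.config)

    def adjacency(self, tiers: Optional[Set[str]] = None) -> Dict[str, Set[str]]:
        adj: Dict[str, Set[str]] = {}
        for a, b in self.edges(tiers):
            adj.setdefault(a, set()).add(b)
            adj.setdefault(b, set()).add(a)
        return adj

    def degree(self) -> Dict[str, int]:
        return {n: len(nbrs) for n, nbrs in self.adjacency().items()}

    def tier_counts(self) -> Dict[str, int]:
        counts = {t: 0 for t in TIERS}
        for score in self.rows.values():
            counts[score.tier] += 1
        return counts


def _tier_of(lr_total: float, config: IntegrationConfig) -> str:
    if lr_total >= config.high_cutoff:
        return "high"
    if lr_total >= config.medium_cutoff:
        return "medium"
    return "low"


def assign_tiers(
    lr_total: Mapping[Pair, float],
    config: IntegrationConfig,
    supported: Optional[Set[Pair]] = None,
) -> ScoredNetwork:
    """Tier a plain pair -> LR mapping (no per-evidence breakdown).

    Pairs not in ``supported`` (when given) are excluded: a pair backed by
    zero evidence layers never enters the network, whatever its neutral LR.
    Tier boundaries are inclusive at the lower edge.
    """
    rows: Dict[Pair, PairScore] = {}
    for pair, lr in lr_total.items():
        if supported is not None and pair not in supported:
            continue
        rows[pair] = PairScore(
            evidence_lrs={},
            lr_functional=1.0,
            lr_total=float(lr),
            posterior_odds=config.prior_odds * float(lr),
            tier=_tier_of(lr, config),
        )
    return ScoredNetwork(rows=rows, config=config)


# ---------------------------------------------------------------------------
# whole-network scoring

FUNCTIONAL_LAYERS = ("gene_neighbor", "gene_fusion", "phylo_profile", "ssbp")
ORTHOLOG_PREFIX = "ortholog:"
RAW_R_FLOOR = 1e-6  # clamp for non-positive correlations in raw-r mode


def score_pairs(
    layers: Mapping[str, EvidenceLayer],
    models: Mapping[str, LRModel],
    config: IntegrationConfig,
    candidate_pairs: Optional[Iterable[Pair]] = None,
    domain_layer: str = "domain",
    domain_mode: str = "gate",
    raw_r_as_lr: bool = False,
) -> ScoredNetwork:
    """Score candidate pairs with every calibrated layer and tier them.

    Boolean layers contribute their 'present' LR only when flagged;
    continuous layers contribute the LR of the bin holding their score;
    pairs outside a layer's coverage get the neutral LR 1 from it.  Pairs
    with no supporting evidence at all (no ortholog flag, no coexpression
    coverage, and no domain-admitted functional evidence) are dropped.

    ``domain_mode='gate'`` uses domain support only as the admission gate
    for the functional factor; ``'lr'`` additionally multiplies the domain
    layer's own LR into the total.  ``raw_r_as_lr`` is a compatibility
    mode that feeds the Pearson correlation itself in as the coexpression
    "LR" (clamped below at a small positive floor) instead of a
    calibrated binned LR; it is statistically improper and off by default.
    """
    if domain_mode not in {"gate", "lr"}:
        raise ValueError(f"domain_mode must be gate|lr, got {domain_mode!r}")
    if candidate_pairs is None:
        universe: Set[Pair] = set()
        for layer in layers.values():
            if layer.binary:
                universe |= layer.flagged()
            else:
                universe |= layer.coverage
        candidate_pairs = universe
    dom = layers.get(domain_layer)
    rows: Dict[Pair, PairScore] = {}
    for pair in candidate_pairs:
        evidence_lrs: Dict[str, float] = {}
        ortholog_lrs: Dict[str, float] = {}
        functional: Dict[str, Optional[float]] = {n: None for n in FUNCTIONAL_LAYERS}
        lr_coexp: Optional[float] = None
        for name, layer in layers.items():
            if name == domain_layer:
                continue
            if raw_r_as_lr and name == "coexpression":
                v = layer.value(pair)
                if v is not None:
                    lr_coexp = max(v, RAW_R_FLOOR)
                    evidence_lrs[name] = lr_coexp
                continue
            model = models.get(name)
            if model is None:
                continue
            v = layer.value(pair)
            if v is None:
                continue
            if layer.binary:
                if v != 1.0:
                    continue  # unflagged boolean evidence is absence, not counter-evidence
                lr = model.lr_present
            else:
                lr = model.lookup(v)
            if name.startswith(ORTHOLOG_PREFIX):
                ortholog_lrs[name[len(ORTHOLOG_PREFIX):]] = lr
                evidence_lrs[name] = lr
            elif name == "coexpression":
                lr_coexp = lr
                evidence_lrs[name] = lr
            elif name in FUNCTIONAL_LAYERS:
                functional[name] = lr
                evidence_lrs[name] = lr
            else:
                log.debug("layer %s does not fit the integration scheme; ignored", name)
        domain_flag = bool(dom is not None and dom.value(pair) == 1.0)
        lr_functional = combine_functional(
            lr_neighbor=functional["gene_neighbor"],
            lr_fusion=functional["gene_fusion"],
            lr_profile=functional["phylo_profile"],
            lr_ssbp=functional["ssbp"],
            domain_flag=domain_flag,
        )
        supported = (
            bool(ortholog_lrs)
            or lr_coexp is not None
            or (domain_flag and any(v is not None for v in functional.values()))
        )
        if not supported:
            continue
        lr_total, post = integrate(ortholog_lrs, lr_coexp, lr_functional, config)
        if domain_mode == "lr" and dom is not None and domain_layer in models:
            v = dom.value(pair)
            if v == 1.0:
                dlr = models[domain_layer].lr_present
                evidence_lrs[domain_layer] = dlr
                lr_total *= dlr
                post = config.prior_odds * lr_total
        rows[pair] = PairScore(
            evidence_lrs=evidence_lrs,
            lr_functional=lr_functional,
            lr_total=lr_total,
            posterior_odds=post,
            tier=_tier_of(lr_total, config),
        )
    return ScoredNetwork(rows=rows, config=config)
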