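"""Self-contained synthetic interactome world with planted ground truth.

The generator emulates every input the pipeline consumes — proteome,
true interactome, curated pairs, enzyme complexes, GO ontology and
annotations, expression matrix, per-organism source interactomes with
ortholog maps, domain/DDI tables, fusion-hit and gene-context tables,
phylogenetic profiles — so every stage is testable without downloads.

Topology is a planted-partition model: proteins belong to functional
modules, pairs inside a module interact with probability ``p_within`` and
pairs across modules with ``p_between``; enzyme complexes are cliques
sampled inside modules.  The boolean evidence channels (ortholog transfer
per organism, domain support, gene fusion, gene neighbor) are generated
conditionally independent given true-pair status with per-layer
(tpr, fpr), exactly the naive-Bayes assumption, and the raw input tables
are constructed to realize those flags exactly.  Coexpression arises from
a shared module latent profile plus Gaussian noise; shared-biological-
process structure from one module-specific BP term per protein; profile
similarity from module bit signatures with per-protein flips.

Everything is regenerable bit-identically from (params, seed).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import pandas as pd
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

from .evidence import EvidenceLayer, GeneContextTable, OrthologMap, PhyloProfile
from .gold_standards import GoldStandard
from .io_formats import AnnotationTable, ExpressionMatrix, OntologyDag, PairTable
from .pairs import Pair, canonical_pair

BP_ROOT = "GO:BP_ROOT"
CC_ROOT = "GO:CC_ROOT"


@dataclass(frozen=True)
class LayerSignal:
    """Per-layer true/false positive rates for a boolean evidence channel."""

    tpr: float
    fpr: float

    def __post_init__(self) -> None:
        for name, v in (("tpr", self.tpr), ("fpr", self.fpr)):
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


DEFAULT_SIGNALS: Dict[str, LayerSignal] = {
    "ortholog": LayerSignal(tpr=0.40, fpr=5e-4),
    "domain": LayerSignal(tpr=0.80, fpr=0.05),
    "gene_fusion": LayerSignal(tpr=0.10, fpr=1e-3),
    "gene_neighbor": LayerSignal(tpr=0.15, fpr=2e-3),
}


@dataclass(frozen=True)
class WorldParams:
    """Generating conditions of the synthetic world.

    Defaults describe a small but structured interactome: 300 proteins in
    10 modules, dense within-module interaction, two source organisms for
    interolog transfer, and noise levels at which each evidence channel is
    informative but far from perfect.
    """

    n_proteins: int = 300
    n_modules: int = 10
    p_within: float = 0.30
    p_between: float = 0.005
    organisms: Tuple[str, ...] = ("scer", "cele")
    evidence_signal: Mapping[str, LayerSignal] = field(
        default_factory=lambda: dict(DEFAULT_SIGNALS)
    )
    n_samples: int = 30
    expr_noise_sd: float = 1.0
    n_genomes: int = 20
    phylo_flip: float = 0.10
    frac_gold_pos: float = 0.40
    neg_pos_ratio: float = 10.0
    frac_unknown: float = 0.10
    n_complexes: int = 5
    complex_size_range: Tuple[int, int] = (3, 6)
    oversize_complex: int = 20

    def __post_init__(self) -> None:
        checks = {
            "n_proteins": self.n_proteins >= 20,
            "n_modules": 1 <= self.n_modules <= self.n_proteins // 2,
            "p_within": 0 < self.p_within < 1,
            "p_between": 0 <= self.p_between < self.p_within,
            "n_samples": self.n_samples >= 3,
            "expr_noise_sd": self.expr_noise_sd > 0,
            "n_genomes": self.n_genomes >= 4,
            "phylo_flip": 0 <= self.phylo_flip < 0.5,
            "frac_gold_pos": 0 < self.frac_gold_pos <= 1,
            "neg_pos_ratio": self.neg_pos_ratio > 0,
            "frac_unknown": 0 <= self.frac_unknown < 1,
            "n_complexes": self.n_complexes >= 0,
        }
        for name, ok in checks.items():
            if not ok:
                raise ValueError(f"parameter {name} out of range: {getattr(self, name)}")
        for layer in ("ortholog", "domain", "gene_fusion", "gene_neighbor"):
            if layer not in self.evidence_signal:
                raise ValueError(f"parameter evidence_signal missing layer {layer}")


@dataclass
class SyntheticWorld:
    """A generated world: raw pipeline inputs plus the planted truth."""

    params: WorldParams
    seed: int
    proteins: List[str]
    module_of: Dict[str, int]
    true_ppi: Set[Pair]
    complexes: Dict[str, Set[str]]
    curated: PairTable
    ontology: OntologyDag
    annotations: AnnotationTable
    bp_term_of_module: Dict[int, str]
    location_of_module: Dict[int, str]
    unknown_proteins: Set[str]
    gold: GoldStandard
    ortholog_maps: Dict[str, OrthologMap]
    source_interactomes: Dict[str, PairTable]
    protein_domains: Dict[str, Set[str]]
    ddi: Set[Pair]
    fusion_hits: List[Tuple[str, str, int, int, str]]
    gene_context: GeneContextTable
    phylo: PhyloProfile
    expression: ExpressionMatrix
    flags: Dict[str, Set[Pair]]  # planted per-channel flag sets

    def __post_init__(self) -> None:
        if not self.gold.positives <= self.true_ppi:
            raise AssertionError("gold positives must be true pairs")
        if self.gold.negatives & self.true_ppi:
            raise AssertionError("gold negatives must not be true pairs")

    def known_bp(self) -> Dict[str, Set[str]]:
        """Protein -> directly annotated BP terms (unknown proteins absent)."""
        return self.annotations.protein_terms(aspect="BP")


def _draw_flags(
    rng: np.random.Generator,
    all_pairs: Sequence[Pair],
    is_true: np.ndarray,
    signal: LayerSignal,
) -> Set[Pair]:
    u = rng.random(len(all_pairs))
    thresholds = np.where(is_true, signal.tpr, signal.fpr)
    return {all_pairs[i] for i in np.flatnonzero(u < thresholds)}


def generate_world(params: Optional[WorldParams] = None, seed: int = 42) -> SyntheticWorld:
    """Generate a complete world; identical (params, seed) give identical worlds."""
    params = params or WorldParams()
    rng = np.random.default_rng(seed)

    proteins = [f"AT{i + 1:05d}" for i in range(params.n_proteins)]
    blocks = np.array_split(np.arange(params.n_proteins), params.n_modules)
    module_of = {proteins[i]: m for m, block in enumerate(blocks) for i in block}
    module_members = {
        m: [proteins[i] for i in block] for m, block in enumerate(blocks)
    }

    # --- true interactome: planted partition ------------------------------
    all_pairs: List[Pair] = [
        canonical_pair(a, b) for a, b in itertools.combinations(proteins, 2)
    ]
    same_module = np.array(
        [module_of[a] == module_of[b] for a, b in all_pairs], dtype=bool
    )
    u = rng.random(len(all_pairs))
    prob = np.where(same_module, params.p_within, params.p_between)
    true_ppi: Set[Pair] = {all_pairs[i] for i in np.flatnonzero(u < prob)}

    # --- enzyme complexes: within-module cliques --------------------------
    complexes: Dict[str, Set[str]] = {}
    sizes = list(
        rng.integers(
            params.complex_size_range[0],
            params.complex_size_range[1] + 1,
            size=params.n_complexes,
        )
    )
    if params.oversize_complex:
        sizes.append(params.oversize_complex)
    for k, size in enumerate(sizes):
        candidates = [m for m, mem in module_members.items() if len(mem) >= size]
        if not candidates:  # no module can host a complex this large
            continue
        m = int(rng.choice(candidates))
        members = sorted(
            rng.choice(module_members[m], size=int(size), replace=False)
        )
        complexes[f"CPX{k:03d}"] = set(members)
        for a, b in itertools.combinations(members, 2):
            true_ppi.add(canonical_pair(a, b))

    is_true = np.array([p in true_ppi for p in all_pairs], dtype=bool)

    # --- ontology, annotations, localization ------------------------------
    bp_term_of_module = {m: f"GO:BP_M{m:02d}" for m in module_members}
    location_of_module = {m: f"GO:CC_L{m:02d}" for m in module_members}
    terms = (
        {BP_ROOT, CC_ROOT}
        | set(bp_term_of_module.values())
        | set(location_of_module.values())
    )
    parents = {t: frozenset({BP_ROOT}) for t in bp_term_of_module.values()}
    parents.update({t: frozenset({CC_ROOT}) for t in location_of_module.values()})
    namespace = {BP_ROOT: "BP", CC_ROOT: "CC"}
    namespace.update({t: "BP" for t in bp_term_of_module.values()})
    namespace.update({t: "CC" for t in location_of_module.values()})
    ontology = OntologyDag(
        terms=frozenset(terms), parents=parents, namespace=namespace
    )

    n_unknown = int(round(params.frac_unknown * params.n_proteins))
    unknown_proteins = set(
        rng.choice(proteins, size=n_unknown, replace=False)
    ) if n_unknown else set()
    ann_rows = []
    for p in proteins:
        m = module_of[p]
        ann_rows.append((p, location_of_module[m], "CC", "IDA"))
        if p not in unknown_proteins:
            ann_rows.append((p, bp_term_of_module[m], "BP", "IDA"))
    annotations = AnnotationTable.from_rows(ann_rows)

    # --- gold standard ----------------------------------------------------
    true_sorted = sorted(true_ppi)
    n_pos = max(1, int(round(params.frac_gold_pos * len(true_sorted))))
    pos_idx = rng.choice(len(true_sorted), size=n_pos, replace=False)
    gold_pos = {true_sorted[i] for i in sorted(pos_idx)}
    neg_candidates = [
        all_pairs[i]
        for i in np.flatnonzero(~is_true)
        if location_of_module[module_of[all_pairs[i][0]]]
        != location_of_module[module_of[all_pairs[i][1]]]
    ]
    n_neg = min(len(neg_candidates), int(round(params.neg_pos_ratio * n_pos)))
    neg_idx = rng.choice(len(neg_candidates), size=n_neg, replace=False)
    gold_neg = {neg_candidates[i] for i in sorted(neg_idx)}
    gold = GoldStandard(
        positives=gold_pos,
        negatives=gold_neg,
        provenance={p: "curated" for p in gold_pos},
        removed_overlap=set(),
    )
    curated = PairTable(scores={p: None for p in gold_pos})

    # --- boolean evidence channels (fixed draw order for determinism) -----
    flags: Dict[str, Set[Pair]] = {}
    for org in params.organisms:
        flags[f"ortholog:{org}"] = _draw_flags(
            rng, all_pairs, is_true, params.evidence_signal["ortholog"]
        )
    for channel in ("domain", "gene_fusion", "gene_neighbor"):
        flags[channel] = _draw_flags(
            rng, all_pairs, is_true, params.evidence_signal[channel]
        )

    # ortholog maps + relabeled source interactomes
    ortholog_maps: Dict[str, OrthologMap] = {}
    source_interactomes: Dict[str, PairTable] = {}
    for org in params.organisms:
        src_of = {p: f"{org.upper()}{i + 1:05d}" for i, p in enumerate(proteins)}
        mapping = {src: {p} for p, src in src_of.items()}
        ortholog_maps[org] = OrthologMap(organism=org, mapping=mapping)
        src_pairs = {
            canonical_pair(src_of[a], src_of[b]): None
            for a, b in sorted(flags[f"ortholog:{org}"])
        }
        source_interactomes[org] = PairTable(scores=src_pairs)

    # domain tables realizing the planted domain flags exactly
    protein_domains: Dict[str, Set[str]] = {p: set() for p in proteins}
    ddi: Set[Pair] = set()
    for k, (a, b) in enumerate(sorted(flags["domain"])):
        da, db = f"PF{k:05d}A", f"PF{k:05d}B"
        protein_domains[a].add(da)
        protein_domains[b].add(db)
        ddi.add((da, db))

    # fusion hits: each flagged pair hits its own composite target
    fusion_hits: List[Tuple[str, str, int, int, str]] = []
    for k, (a, b) in enumerate(sorted(flags["gene_fusion"])):
        target = f"FUS{k:05d}"
        fusion_hits.append((a, target, 1, 100, "fusref"))
        fusion_hits.append((b, target, 121, 220, "fusref"))

    # gene context: each flagged pair adjacent on a private contig in 2 genomes
    ctx_genomes: Dict[str, Dict[str, Tuple[str, int, int, str]]] = {}
    ctx_links: Dict[str, Dict[str, Set[str]]] = {}
    for genome in ("ctxA", "ctxB"):
        coords: Dict[str, Tuple[str, int, int, str]] = {}
        links: Dict[str, Set[str]] = {}
        for k, (a, b) in enumerate(sorted(flags["gene_neighbor"])):
            contig = f"{genome}_c{k:05d}"
            ga, gb = f"{genome}_g{k:05d}a", f"{genome}_g{k:05d}b"
            coords[ga] = (contig, 1000, 1800, "+")
            coords[gb] = (contig, 2001, 2800, "+")
            links.setdefault(a, set()).add(ga)
            links.setdefault(b, set()).add(gb)
        ctx_genomes[genome] = coords
        ctx_links[genome] = links
    gene_context = GeneContextTable(genomes=ctx_genomes, links=ctx_links)

    # phylogenetic profiles: module signature + per-protein bit flips
    signatures = {
        m: rng.integers(0, 2, size=params.n_genomes) for m in sorted(module_members)
    }
    vectors: Dict[str, np.ndarray] = {}
    for p in proteins:
        flips = rng.random(params.n_genomes) < params.phylo_flip
        vectors[p] = np.where(flips, 1 - signatures[module_of[p]], signatures[module_of[p]])
    phylo = PhyloProfile(
        genomes=[f"G{j:02d}" for j in range(params.n_genomes)], vectors=vectors
    )

    # expression: module latent profile + protein-level Gaussian noise
    latent = rng.normal(size=(params.n_modules, params.n_samples))
    noise = rng.normal(scale=params.expr_noise_sd, size=(params.n_proteins, params.n_samples))
    values = np.array([latent[module_of[p]] for p in proteins]) + noise
    expression = ExpressionMatrix(
        genes=list(proteins),
        samples=[f"S{j:02d}" for j in range(params.n_samples)],
        values=values,
    )

    return SyntheticWorld(
        params=params,
        seed=seed,
        proteins=proteins,
        module_of=module_of,
        true_ppi=true_ppi,
        complexes=complexes,
        curated=curated,
        ontology=ontology,
        annotations=annotations,
        bp_term_of_module=bp_term_of_module,
        location_of_module=location_of_module,
        unknown_proteins=unknown_proteins,
        gold=gold,
        ortholog_maps=ortholog_maps,
        source_interactomes=source_interactomes,
        protein_domains=protein_domains,
        ddi=ddi,
        fusion_hits=fusion_hits,
        gene_context=gene_context,
        phylo=phylo,
        expression=expression,
        flags=flags,
    )


def mask_annotations(
    world: SyntheticWorld, frac: float, seed: int = 0
) -> Tuple[AnnotationTable, List[Tuple[str, str]]]:
    """Hide a fraction of BP annotations, keeping every module represented.

    Returns the masked annotation table and the hidden (protein, term)
    pairs; masked ∪ hidden partitions the original annotations.  If a
    draw would silence an entire module it is rejected; after 100 failed
    draws an error is raised.
    """
    if not 0 < frac < 1:
        raise ValueError(f"frac must be in (0, 1), got {frac}")
    df = world.annotations.df
    bp = df[df["aspect"] == "BP"].reset_index(drop=True)
    other = df[df["aspect"] != "BP"]
    n_hidden = max(1, int(round(frac * len(bp))))
    annotated_modules = {world.module_of[p] for p in bp["protein"]}
    rng = np.random.default_rng(seed)
    for _attempt in range(100):
        idx = set(rng.choice(len(bp), size=n_hidden, replace=False).tolist())
        kept = bp.drop(index=list(idx))
        kept_modules = {world.module_of[p] for p in kept["protein"]}
        if kept_modules == annotated_modules:
            hidden = [
                (bp.at[i, "protein"], bp.at[i, "term"]) for i in sorted(idx)
            ]
            masked = AnnotationTable(df=pd.concat([other, kept], ignore_index=True))
            return masked, hidden
    raise ValueError("could not mask annotations without silencing a module")


def write_world(world: SyntheticWorld, out_dir) -> None:
    """Write every raw input table of the world in the pipeline's dialects.

    Truth files (true interactome, gold labels) go next to the inputs so
    downstream evaluation needs no access to the generator.
    """
    from pathlib import Path

    from . import io_formats as io

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    io.write_pair_table(world.curated, out / "curated.tsv")
    io.write_complexes(world.complexes, out / "complexes.tsv")
    io.write_obo(
        world.ontology.terms,
        world.ontology.parents,
        world.ontology.namespace,
        out / "ontology.obo",
    )
    io.write_annotations(world.annotations, out / "annotations.tsv")
    io.write_expression(world.expression, out / "expression.tsv")
    for org, omap in world.ortholog_maps.items():
        io.write_ortholog_map(omap.mapping, out / f"orthologs_{org}.tsv")
        io.write_pair_table(world.source_interactomes[org], out / f"interactome_{org}.tsv")
    io.write_ortholog_map(world.protein_domains, out / "domains.tsv")
    io.write_ddi(world.ddi, out / "ddi.tsv")
    io.write_fusion_hits(world.fusion_hits, out / "fusion_hits.tsv")
    io.write_gene_context(world.gene_context, out / "gene_coords.tsv", out / "gene_links.tsv")
    io.write_phylo_profiles(world.phylo, out / "phylo_profiles.tsv")
    io.write_pair_table(PairTable(scores={p: None for p in world.true_ppi}), out / "true_ppi.tsv")
    io.write_pair_table(
        PairTable(scores={p: None for p in world.gold.positives}), out / "gold_positives.tsv"
    )
    io.write_pair_table(
        PairTable(scores={p: None for p in world.gold.negatives}), out / "gold_negatives.tsv"
    )


# ---------------------------------------------------------------------------
# independent-Bernoulli evidence world for calibration checks


def generate_bernoulli_evidence(
    n_pairs: int,
    prior: float,
    signals: Sequence[LayerSignal],
    seed: int = 0,
) -> Tuple[List[EvidenceLayer], GoldStandard, np.ndarray, np.ndarray]:
    """Labeled pairs with conditionally independent binary evidence.

    Each pair is interacting with probability ``prior``; evidence channel
    ``j`` fires with probability ``signals[j].tpr`` on interacting pairs
    and ``signals[j].fpr`` otherwise.  Returns fully covered binary
    layers, the (complete) gold standard, the label vector and the
    n_pairs x n_channels evidence matrix.
    """
    if not 0 < prior < 1:
        raise ValueError(f"prior must be in (0, 1), got {prior}")
    rng = np.random.default_rng(seed)
    labels = rng.random(n_pairs) < prior
    evidence = np.zeros((n_pairs, len(signals)), dtype=int)
    for j, sig in enumerate(signals):
        p = np.where(labels, sig.tpr, sig.fpr)
        evidence[:, j] = rng.random(n_pairs) < p
    pairs = [canonical_pair(f"A{i:06d}", f"B{i:06d}") for i in range(n_pairs)]
    layers = [
        EvidenceLayer(
            name=f"ev{j}",
            values={pairs[i]: float(evidence[i, j]) for i in range(n_pairs)},
            binary=True,
        )
        for j in range(len(signals))
    ]
    gold = GoldStandard(
        positives={pairs[i] for i in np.flatnonzero(labels)},
        negatives={pairs[i] for i in np.flatnonzero(~labels)},
    )
    return layers, gold, labels, evidence


def true_posterior_probability(
    evidence: np.ndarray, prior: float, signals: Sequence[LayerSignal]
) -> np.ndarray:
    """Exact P(interacting | evidence) under the generating model."""
    odds = np.full(evidence.shape[0], prior / (1 - prior))
    for j, sig in enumerate(signals):
        e = evidence[:, j].astype(bool)
        lr = np.where(e, sig.tpr / sig.fpr, (1 - sig.tpr) / (1 - sig.fpr))
        odds = odds * lr
    return odds / (1 + odds)
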