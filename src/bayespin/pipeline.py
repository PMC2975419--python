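"""End-to-end orchestration of the prediction pipeline.

Chains the stages gold-standard construction -> evidence scoring -> LR
calibration -> integration/tiering -> function annotation on in-memory
inputs (typically a :class:`~bayespin.synthetic.SyntheticWorld`).  Each
stage derives its own RNG seed from the global seed by stable hashing, so
a run is reproducible end to end from (config, seed).
"""

from __future__ import annotations

import hashlib
import itertools
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Set, Tuple

import numpy as np
from sklearn.metrics import roc_auc_score

from . import annotation as ann
from . import bayes, evidence, gold_standards, io_formats
from .pairs import Pair, canonical_pair
from .synthetic import SyntheticWorld, WorldParams, generate_world

log = logging.getLogger(__name__)

CONTINUOUS_LAYERS = ("coexpression", "ssbp", "phylo_profile")


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed derived from the global seed (< 2**31)."""
    digest = hashlib.blake2s(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class PipelineResult:
    world: SyntheticWorld
    gold: gold_standards.GoldStandard
    layers: Dict[str, evidence.EvidenceLayer]
    models: Dict[str, bayes.LRModel]
    config: bayes.IntegrationConfig
    network: bayes.ScoredNetwork
    anneal_state: Optional[ann.AnnealState] = None
    annotation_result: Optional[ann.AnnotationResult] = None
    report: Dict[str, object] = field(default_factory=dict)


def build_gold(
    world: SyntheticWorld,
    seed: int,
    neg_pos_ratio: float = 10.0,
    max_complex_size: int = 18,
) -> Tuple[gold_standards.GoldStandard, Dict[str, int]]:
    """Gold standard from the world's raw inputs (curated + complexes + CC)."""
    gsp, provenance = gold_standards.build_gsp(
        world.curated, world.complexes, max_complex_size
    )
    gsn = gold_standards.build_gsn(
        world.annotations,
        allowed_codes=set(gold_standards.DEFAULT_EVIDENCE_CODES),
        protein_universe=set(world.proteins),
        max_pairs=int(round(neg_pos_ratio * len(gsp))),
        seed=seed,
    )
    gold = gold_standards.reconcile(gsp, gsn, provenance)
    counts = {
        "gsp_n": gold.n_positive,
        "gsn_n": gold.n_negative,
        "removed_overlap_n": len(gold.removed_overlap),
    }
    return gold, counts


def compute_layers(
    world: SyntheticWorld,
    pairs: Optional[List[Pair]] = None,
) -> Dict[str, evidence.EvidenceLayer]:
    """All seven evidence layers from the world's raw input tables."""
    if pairs is None:
        pairs = [
            canonical_pair(a, b)
            for a, b in itertools.combinations(world.proteins, 2)
        ]
    layers: Dict[str, evidence.EvidenceLayer] = {}
    for org, omap in world.ortholog_maps.items():
        layer = evidence.project_orthologs(world.source_interactomes[org], omap)
        layers[layer.name] = layer
    layers["coexpression"] = evidence.coexpression_scores(world.expression, pairs)
    layers["domain"] = evidence.domain_support(world.protein_domains, world.ddi, pairs)
    layers["ssbp"] = evidence.ssbp_scores(world.annotations, world.ontology, pairs)
    layers["gene_fusion"] = evidence.gene_fusion_pairs(world.fusion_hits)
    layers["gene_neighbor"] = evidence.gene_neighbor_pairs(world.gene_context)
    layers["phylo_profile"] = evidence.phylo_profile_scores(world.phylo, pairs)
    return layers


def fit_models(
    layers: Mapping[str, evidence.EvidenceLayer],
    gold: gold_standards.GoldStandard,
    pseudocount: float = 0.5,
    max_bins: int = 5,
    min_leaf: int = 20,
) -> Dict[str, bayes.LRModel]:
    """Calibrate every layer: binary layers on their flags, continuous
    layers on supervised (entropy-gain) score bins."""
    models: Dict[str, bayes.LRModel] = {}
    for name, layer in layers.items():
        if layer.binary:
            models[name] = bayes.estimate_lr(layer, gold, "binary", pseudocount)
            continue
        scores, labels = [], []
        for pair_set, label in ((gold.positives, 1), (gold.negatives, 0)):
            for pair in pair_set:
                v = layer.value(pair)
                if v is not None:
                    scores.append(v)
                    labels.append(label)
        if len(scores) < 2 * min_leaf:
            log.warning("layer %s: too few labeled points (%d); skipped", name, len(scores))
            continue
        cuts = bayes.supervised_discretize(scores, labels, max_bins, min_leaf)
        models[name] = bayes.estimate_lr(layer, gold, cuts, pseudocount)
    return models


def make_config(
    gold: gold_standards.GoldStandard,
    models: Mapping[str, bayes.LRModel],
    prior_odds: Optional[float] = None,
) -> bayes.IntegrationConfig:
    """Integration config with auto cutoffs.

    ``prior_odds`` defaults to the gold-standard positive/negative ratio
    (a crude but data-driven estimate).  The high cutoff comes from the
    posterior-odds-one identity; the medium cutoff is the weakest
    per-organism ortholog LR, clamped to the high cutoff when the
    interolog layers are stronger than the prior demands.
    """
    if prior_odds is None:
        prior_odds = gold.n_positive / gold.n_negative
    ortholog_models = {
        name[len(bayes.ORTHOLOG_PREFIX):]: m
        for name, m in models.items()
        if name.startswith(bayes.ORTHOLOG_PREFIX)
    }
    config = bayes.IntegrationConfig(prior_odds=prior_odds)
    if ortholog_models:
        medium = bayes.derive_medium_cutoff(ortholog_models)
        if medium > config.high_cutoff:
            log.info(
                "medium cutoff %.3g exceeds high cutoff %.3g; clamping",
                medium,
                float(config.high_cutoff),
            )
            medium = config.high_cutoff  # keep the exact value; medium tier empty
        config = bayes.IntegrationConfig(
            prior_odds=prior_odds, medium_cutoff=medium
        )
    return config


def ranking_auroc(
    network: bayes.ScoredNetwork,
    true_pairs: Set[Pair],
    universe: Iterable[Pair],
) -> float:
    """AUROC of lr_total for true-pair recovery over a pair universe.

    Pairs absent from the network carry the neutral LR 1 (no evidence).
    """
    universe = list(universe)
    y = np.array([p in true_pairs for p in universe], dtype=int)
    scores = np.array(
        [network.rows[p].lr_total if p in network.rows else 1.0 for p in universe]
    )
    return float(roc_auc_score(y, scores))


def run_synthetic_pipeline(
    seed: int,
    params: Optional[WorldParams] = None,
    out_dir: Optional[Path] = None,
    prior_odds: Optional[float] = None,
    neg_pos_ratio: float = 10.0,
    annotate: bool = True,
    n_permutations: int = 199,
    annotation_tiers: Set[str] = frozenset({"high", "medium"}),
    known_annotations: Optional[Mapping[str, Set[str]]] = None,
    unknowns: Optional[Set[str]] = None,
) -> PipelineResult:
    """Generate a world and run every stage on it.

    ``known_annotations``/``unknowns`` may override the world's own
    annotation split (used for masked-recovery experiments).  When
    ``out_dir`` is given, ``network.tsv``, ``annotations.tsv`` and
    ``report.json`` are written there.
    """
    t_start = time.time()
    world = generate_world(params, seed=stage_seed(seed, "world"))
    gold, gold_counts = build_gold(
        world, seed=stage_seed(seed, "gsn"), neg_pos_ratio=neg_pos_ratio
    )
    all_pairs = [
        canonical_pair(a, b) for a, b in itertools.combinations(world.proteins, 2)
    ]
    layers = compute_layers(world, all_pairs)
    models = fit_models(layers, gold)
    config = make_config(gold, models, prior_odds)
    network = bayes.score_pairs(layers, models, config, candidate_pairs=all_pairs)

    report: Dict[str, object] = {
        "seed": seed,
        "n_proteins": len(world.proteins),
        **gold_counts,
        "prior_odds": config.prior_odds,
        "high_cutoff": float(config.high_cutoff),
        "medium_cutoff": float(config.medium_cutoff),
        "tier_counts": network.tier_counts(),
        "lr_models": {
            name: {str(b): v for b, v in sorted(m.lr.items())}
            for name, m in sorted(models.items())
        },
    }

    anneal_state = None
    annotation_result = None
    if annotate:
        known = (
            dict(known_annotations)
            if known_annotations is not None
            else world.known_bp()
        )
        sub = network.subnetwork(set(annotation_tiers))
        nodes = sub.nodes()
        target_unknowns = (
            set(unknowns) if unknowns is not None else set(world.unknown_proteins)
        )
        target_unknowns = {u for u in target_unknowns if u in nodes}
        if target_unknowns:
            anneal_state = ann.anneal_annotations(
                sub, known, target_unknowns, seed=stage_seed(seed, "anneal")
            )
            annotation_result = ann.annotation_pvalues(
                sub,
                known,
                anneal_state,
                n_permutations=n_permutations,
                seed=stage_seed(seed, "permute"),
            )
            report["annotated_proteins"] = len(anneal_state.assignment)
            report["annotation_pairs"] = len(annotation_result)
            report["significant_annotation_pairs"] = len(
                annotation_result.significant()
            )
        else:
            log.warning("no function-unknown proteins inside the annotation tiers")

    report["wall_time_s"] = round(time.time() - t_start, 2)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        io_formats.write_network(network, out_dir / "network.tsv", "tsv")
        if annotation_result is not None:
            ann.write_annotation_result(annotation_result, out_dir / "annotations.tsv")
        else:
            (out_dir / "annotations.tsv").write_text(
                "protein\tterm\tp_value\tn_permutations\tsignificant\n"
            )
        import json

        (out_dir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))

    return PipelineResult(
        world=world,
        gold=gold,
        layers=layers,
        models=models,
        config=config,
        network=network,
        anneal_state=anneal_state,
        annotation_result=annotation_result,
        report=report,
    )
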