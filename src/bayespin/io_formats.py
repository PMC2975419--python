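"""Readers and writers for every external table the pipeline touches.

All files are plain TSV (tab separated, UTF-8, ``#``-prefixed comment lines
ignored, no quoting) except the ontology, which is OBO 1.2.  Readers
validate eagerly and hand every other module a typed in-memory object, so
the rest of the package never sees a file path.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import networkx as nx
import numpy as np
import obonet
import pandas as pd

from .pairs import Pair, SelfPairError, canonical_pair

log = logging.getLogger(__name__)

_NAMESPACE_CODE = {
    "biological_process": "BP",
    "cellular_component": "CC",
    "molecular_function": "MF",
}

ASPECTS = ("BP", "CC", "MF")


# ---------------------------------------------------------------------------
# low-level TSV scanning


def _iter_tsv_rows(path) -> Iterable[Tuple[int, List[str]]]:
    """Yield (1-based line number, fields) for data lines of a TSV file."""
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line.split("\t")


# ---------------------------------------------------------------------------
# pair tables


@dataclass
class PairTable:
    """Canonical unordered pairs with an optional per-pair score.

    ``scores`` maps each canonical pair to a float score or ``None`` when
    the table carries no score.  Duplicate input rows are merged keeping
    the maximum score; self-pairs are dropped (and counted by the reader).
    """

    scores: Dict[Pair, Optional[float]] = field(default_factory=dict)

    @property
    def pairs(self) -> Set[Pair]:
        return set(self.scores)

    def __len__(self) -> int:
        return len(self.scores)

    def __contains__(self, pair: Pair) -> bool:
        return pair in self.scores

    def __iter__(self):
        return iter(self.scores)

    @classmethod
    def from_rows(cls, rows: Iterable[Tuple], has_score: bool = False) -> "PairTable":
        scores: Dict[Pair, Optional[float]] = {}
        n_self = 0
        for row in rows:
            a, b = row[0], row[1]
            try:
                pair = canonical_pair(a, b)
            except SelfPairError:
                n_self += 1
                continue
            score = float(row[2]) if has_score else None
            if pair not in scores:
                scores[pair] = score
            elif has_score:
                prev = scores[pair]
                scores[pair] = score if prev is None else max(prev, score)
        if n_self:
            log.warning("dropped %d self-pairs while building pair table", n_self)
        return cls(scores)


def read_pair_table(path, has_score: bool = False) -> PairTable:
    """Read a two-or-three column pair TSV into a canonical :class:`PairTable`."""
    rows = []
    n_self = 0
    for lineno, fields in _iter_tsv_rows(path):
        if len(fields) < 2 or (has_score and len(fields) < 3):
            raise ValueError(f"{path}: malformed row at line {lineno}: {fields!r}")
        a, b = fields[0], fields[1]
        if has_score:
            try:
                score = float(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}: bad score at line {lineno}: {fields[2]!r}") from exc
            rows.append((a, b, score))
        else:
            rows.append((a, b))
    if not rows:
        log.warning("%s: empty pair table", path)
    table = PairTable.from_rows(rows, has_score=has_score)
    return table


def write_pair_table(table: PairTable, path, has_score: bool = False) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for pair in sorted(table.scores):
            score = table.scores[pair]
            if has_score and score is not None:
                fh.write(f"{pair[0]}\t{pair[1]}\t{score:.12g}\n")
            else:
                fh.write(f"{pair[0]}\t{pair[1]}\n")


# ---------------------------------------------------------------------------
# ontology


@dataclass
class OntologyDag:
    """A GO-style DAG: term ids, parent links (is_a/part_of) and namespaces."""

    terms: FrozenSet[str]
    parents: Dict[str, FrozenSet[str]]
    namespace: Dict[str, str]
    _ancestor_cache: Dict[str, FrozenSet[str]] = field(
        default_factory=dict, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        for term, ps in self.parents.items():
            missing = set(ps) - set(self.terms)
            if missing:
                raise ValueError(f"term {term} has unresolved parents: {sorted(missing)}")
        graph = nx.DiGraph()
        graph.add_nodes_from(self.terms)
        for term, ps in self.parents.items():
            for p in ps:
                graph.add_edge(term, p)
        if not nx.is_directed_acyclic_graph(graph):
            cycle = nx.find_cycle(graph)
            raise ValueError(f"ontology contains a cycle: {cycle}")

    def ancestors(self, term: str) -> FrozenSet[str]:
        """All strict ancestors of ``term`` through is_a/part_of links."""
        cached = self._ancestor_cache.get(term)
        if cached is not None:
            return cached
        out: Set[str] = set()
        stack = list(self.parents.get(term, ()))
        while stack:
            t = stack.pop()
            if t in out:
                continue
            out.add(t)
            stack.extend(self.parents.get(t, ()))
        result = frozenset(out)
        self._ancestor_cache[term] = result
        return result

    def roots(self) -> FrozenSet[str]:
        return frozenset(t for t in self.terms if not self.parents.get(t))

    def aspect_of(self, term: str) -> Optional[str]:
        return self.namespace.get(term)


def read_obo(path, relationships: Sequence[str] = ("is_a", "part_of")) -> OntologyDag:
    """Load an OBO 1.2 ontology; obsolete terms are excluded.

    Both ``is_a`` and ``part_of`` edges count as ancestry by default, which
    matches common GO practice for annotation propagation.
    """
    graph = obonet.read_obo(path, ignore_obsolete=True)
    terms: Set[str] = set()
    parents: Dict[str, Set[str]] = {}
    namespace: Dict[str, str] = {}
    for node, data in graph.nodes(data=True):
        terms.add(node)
        ns = data.get("namespace")
        if ns in _NAMESPACE_CODE:
            namespace[node] = _NAMESPACE_CODE[ns]
    for child, parent, key in graph.edges(keys=True):
        if key not in relationships:
            continue
        if parent not in terms:
            raise ValueError(f"{path}: dangling parent reference {parent} (from {child})")
        parents.setdefault(child, set()).add(parent)
    return OntologyDag(
        terms=frozenset(terms),
        parents={t: frozenset(ps) for t, ps in parents.items()},
        namespace=namespace,
    )


# ---------------------------------------------------------------------------
# annotations


@dataclass
class AnnotationTable:
    """Protein -> ontology-term annotations with evidence codes.

    Backed by a DataFrame with columns ``protein``, ``term``, ``aspect``,
    ``evidence_code``; rows are unique.
    """

    df: pd.DataFrame

    COLUMNS = ("protein", "term", "aspect", "evidence_code")

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.df.columns)
        if missing:
            raise ValueError(f"annotation table missing columns: {sorted(missing)}")
        self.df = self.df.loc[:, list(self.COLUMNS)].drop_duplicates().reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @classmethod
    def from_rows(cls, rows: Iterable[Tuple[str, str, str, str]]) -> "AnnotationTable":
        return cls(pd.DataFrame(list(rows), columns=list(cls.COLUMNS)))

    def protein_terms(
        self,
        aspect: Optional[str] = None,
        codes: Optional[Set[str]] = None,
    ) -> Dict[str, Set[str]]:
        """Map each protein to its (directly annotated) term set, filtered."""
        df = self.df
        if aspect is not None:
            df = df[df["aspect"] == aspect]
        if codes is not None:
            df = df[df["evidence_code"].isin(codes)]
        out: Dict[str, Set[str]] = {}
        for protein, term in zip(df["protein"], df["term"]):
            out.setdefault(protein, set()).add(term)
        return out

    def proteins(self) -> Set[str]:
        return set(self.df["protein"])


def read_annotations(
    path,
    ontology: Optional[OntologyDag] = None,
    unknown_terms: str = "keep",
) -> AnnotationTable:
    """Read a GAF-like TSV: protein, term, evidence code[, aspect].

    When an ontology is supplied the aspect is taken from the term's
    namespace; rows whose term is absent from the ontology are kept,
    dropped or fatal per ``unknown_terms`` in {keep, drop, error}.
    """
    if unknown_terms not in {"keep", "drop", "error"}:
        raise ValueError(f"unknown_terms must be keep|drop|error, got {unknown_terms!r}")
    rows = []
    n_unknown = 0
    for lineno, fields in _iter_tsv_rows(path):
        if len(fields) < 3:
            raise ValueError(f"{path}: expected >=3 columns at line {lineno}")
        protein, term, code = fields[0], fields[1], fields[2].upper()
        aspect = fields[3] if len(fields) > 3 else ""
        if ontology is not None:
            if term in ontology.terms:
                aspect = ontology.aspect_of(term) or aspect
            else:
                n_unknown += 1
                if unknown_terms == "error":
                    raise ValueError(f"{path}: unknown term {term} at line {lineno}")
                if unknown_terms == "drop":
                    continue
        if aspect and aspect not in ASPECTS:
            raise ValueError(f"{path}: bad aspect {aspect!r} at line {lineno}")
        rows.append((protein, term, aspect, code))
    if n_unknown:
        log.warning("%s: %d rows with terms absent from the ontology", path, n_unknown)
    return AnnotationTable.from_rows(rows)


def write_annotations(table: AnnotationTable, path) -> None:
    df = table.df.loc[:, ["protein", "term", "evidence_code", "aspect"]]
    df.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# expression


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values (arbitrary units)."""

    genes: List[str]
    samples: List[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene ids in expression matrix")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample ids in expression matrix")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValueError(
                f"expression matrix shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        self._index = {g: i for i, g in enumerate(self.genes)}

    def vector(self, gene: str) -> Optional[np.ndarray]:
        i = self._index.get(gene)
        return None if i is None else self.values[i]

    def __contains__(self, gene: str) -> bool:
        return gene in self._index


def read_expression(path) -> ExpressionMatrix:
    """First column gene id, header row of sample ids."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    return ExpressionMatrix(
        genes=[str(g) for g in df.index],
        samples=[str(s) for s in df.columns],
        values=df.to_numpy(dtype=float),
    )


def write_expression(matrix: ExpressionMatrix, path) -> None:
    df = pd.DataFrame(matrix.values, index=matrix.genes, columns=matrix.samples)
    df.to_csv(path, sep="\t", float_format="%.12g")


# ---------------------------------------------------------------------------
# miscellaneous evidence inputs


def read_complexes(path) -> Dict[str, Set[str]]:
    """TSV of (complex_id, protein_id) rows -> complex_id -> member set."""
    complexes: Dict[str, Set[str]] = {}
    for lineno, fields in _iter_tsv_rows(path):
        if len(fields) < 2:
            raise ValueError(f"{path}: expected 2 columns at line {lineno}")
        complexes.setdefault(fields[0], set()).add(fields[1])
    return complexes


def write_complexes(complexes: Mapping[str, Set[str]], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for cid in sorted(complexes):
            for member in sorted(complexes[cid]):
                fh.write(f"{cid}\t{member}\n")


def read_ortholog_map(path) -> Dict[str, Set[str]]:
    """TSV of (source_protein, target_protein) -> source -> target set."""
    mapping: Dict[str, Set[str]] = {}
    for lineno, fields in _iter_tsv_rows(path):
        if len(fields) < 2:
            raise ValueError(f"{path}: expected 2 columns at line {lineno}")
        mapping.setdefault(fields[0], set()).add(fields[1])
    return mapping


def write_ortholog_map(mapping: Mapping[str, Set[str]], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for src in sorted(mapping):
            for tgt in sorted(mapping[src]):
                fh.write(f"{src}\t{tgt}\n")


def read_domain_table(path) -> Dict[str, Set[str]]:
    """TSV of (protein_id, domain_id) -> protein -> domain set."""
    return read_ortholog_map(path)


def read_ddi(path) -> Set[Pair]:
    """TSV of interacting domain pairs (homotypic pairs allowed)."""
    ddi: Set[Pair] = set()
    for lineno, fields in _iter_tsv_rows(path):
        if len(fields) < 2:
            raise ValueError(f"{path}: expected 2 columns at line {lineno}")
        a, b = fields[0], fields[1]
        ddi.add((a, b) if a <= b else (b, a))  # homotypic (d, d) kept
    return ddi


def write_ddi(ddi: Iterable[Pair], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for a, b in sorted(ddi):
            fh.write(f"{a}\t{b}\n")


def write_obo(
    terms: Iterable[str],
    parents: Mapping[str, FrozenSet[str]],
    namespace: Mapping[str, str],
    path,
) -> None:
    """Emit a minimal OBO 1.2 file ([Term] stanzas with is_a links)."""
    code_to_ns = {v: k for k, v in _NAMESPACE_CODE.items()}
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("format-version: 1.2\n")
        for term in sorted(terms):
            fh.write(f"\n[Term]\nid: {term}\nname: {term}\n")
            ns = namespace.get(term)
            if ns:
                fh.write(f"namespace: {code_to_ns.get(ns, ns)}\n")
            for parent in sorted(parents.get(term, ())):
                fh.write(f"is_a: {parent}\n")


def read_fusion_hits(path) -> List[Tuple[str, str, int, int, str]]:
    """TSV of (query_protein, target_protein, target_start, target_end, genome)."""
    hits = []
    for lineno, fields in _iter_tsv_rows(path):
        if len(fields) < 5:
            raise ValueError(f"{path}: expected 5 columns at line {lineno}")
        hits.append((fields[0], fields[1], int(fields[2]), int(fields[3]), fields[4]))
    return hits


def write_fusion_hits(hits: Iterable[Tuple[str, str, int, int, str]], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for query, target, start, end, genome in hits:
            fh.write(f"{query}\t{target}\t{start}\t{end}\t{genome}\n")


def read_gene_context(coords_path, links_path):
    """Gene coordinate TSV (genome, gene, contig, start, end, strand) plus
    ortholog-link TSV (genome, query_protein, gene)."""
    from .evidence import GeneContextTable

    genomes: Dict[str, Dict[str, Tuple[str, int, int, str]]] = {}
    for lineno, fields in _iter_tsv_rows(coords_path):
        if len(fields) < 6:
            raise ValueError(f"{coords_path}: expected 6 columns at line {lineno}")
        genome, gene, contig, start, end, strand = fields[:6]
        genomes.setdefault(genome, {})[gene] = (contig, int(start), int(end), strand)
    links: Dict[str, Dict[str, Set[str]]] = {}
    for lineno, fields in _iter_tsv_rows(links_path):
        if len(fields) < 3:
            raise ValueError(f"{links_path}: expected 3 columns at line {lineno}")
        genome, protein, gene = fields[:3]
        links.setdefault(genome, {}).setdefault(protein, set()).add(gene)
    return GeneContextTable(genomes=genomes, links=links)


def write_gene_context(context, coords_path, links_path) -> None:
    with open(coords_path, "w", encoding="utf-8") as fh:
        for genome in sorted(context.genomes):
            for gene in sorted(context.genomes[genome]):
                contig, start, end, strand = context.genomes[genome][gene]
                fh.write(f"{genome}\t{gene}\t{contig}\t{start}\t{end}\t{strand}\n")
    with open(links_path, "w", encoding="utf-8") as fh:
        for genome in sorted(context.links):
            for protein in sorted(context.links[genome]):
                for gene in sorted(context.links[genome][protein]):
                    fh.write(f"{genome}\t{protein}\t{gene}\n")


def read_phylo_profiles(path):
    """TSV: header '#genomes<TAB>g1<TAB>g2...' then (protein, bits) rows."""
    from .evidence import PhyloProfile

    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if not header or not header[0].startswith("#genomes"):
            raise ValueError(f"{path}: missing '#genomes' header")
        genomes = header[1:]
        vectors: Dict[str, np.ndarray] = {}
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path}: expected 2 columns at line {lineno}")
            protein, bits = fields
            if len(bits) != len(genomes) or set(bits) - {"0", "1"}:
                raise ValueError(f"{path}: bad profile at line {lineno}")
            vectors[protein] = np.array([int(c) for c in bits], dtype=int)
    return PhyloProfile(genomes=genomes, vectors=vectors)


def write_phylo_profiles(profiles, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#genomes\t" + "\t".join(profiles.genomes) + "\n")
        for protein in sorted(profiles.vectors):
            bits = "".join(str(int(b)) for b in profiles.vectors[protein])
            fh.write(f"{protein}\t{bits}\n")


def write_layer(layer, path) -> None:
    """One evidence layer as TSV with a self-describing header comment."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"#layer\t{layer.name}\t{int(layer.binary)}\t{int(layer.complete)}\n")
        for pair in sorted(layer.values):
            fh.write(f"{pair[0]}\t{pair[1]}\t{layer.values[pair]:.12g}\n")


def read_layer(path):
    """Read back a layer written by :func:`write_layer`."""
    from .evidence import EvidenceLayer

    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) != 4 or header[0] != "#layer":
            raise ValueError(f"{path}: missing '#layer' header")
        name, binary, complete = header[1], bool(int(header[2])), bool(int(header[3]))
        values: Dict[Pair, float] = {}
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ValueError(f"{path}: expected 3 columns at line {lineno}")
            values[canonical_pair(fields[0], fields[1])] = float(fields[2])
    return EvidenceLayer(name=name, values=values, binary=binary, complete=complete)


# ---------------------------------------------------------------------------
# scored-network round trip


def write_network(network, path, format: str = "tsv") -> None:
    """Write a :class:`~bayespin.bayes.ScoredNetwork` as TSV or SIF.

    The TSV carries one column per evidence layer (empty when the layer did
    not contribute), the functional/total LRs, the posterior odds and the
    confidence tier; reading the TSV back reproduces the network to 12
    significant digits.
    """
    if format not in {"tsv", "sif"}:
        raise ValueError(f"format must be tsv|sif, got {format!r}")
    rows = network.rows
    if format == "sif":
        with open(path, "w", encoding="utf-8") as fh:
            for a, b in sorted(rows):
                fh.write(f"{a}\tpp\t{b}\n")
        return
    evidence_names = sorted({name for score in rows.values() for name in score.evidence_lrs})
    header = (
        ["protein_a", "protein_b"]
        + [f"lr:{name}" for name in evidence_names]
        + ["lr_functional", "lr_total", "posterior_odds", "tier"]
    )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(header) + "\n")
        for pair in sorted(rows):
            score = rows[pair]
            cells = [pair[0], pair[1]]
            for name in evidence_names:
                lr = score.evidence_lrs.get(name)
                cells.append("" if lr is None else f"{lr:.12g}")
            cells.append(f"{score.lr_functional:.12g}")
            cells.append(f"{score.lr_total:.12g}")
            cells.append(f"{score.posterior_odds:.12g}")
            cells.append(score.tier)
            fh.write("\t".join(cells) + "\n")


def read_network(path):
    """Read back a network TSV written by :func:`write_network`."""
    from .bayes import PairScore, ScoredNetwork

    with open(path, "r", encoding="utf-8") as fh:
        header_line = fh.readline().rstrip("\n")
        if not header_line:
            raise ValueError(f"{path}: missing header")
        header = header_line.split("\t")
        ev_cols = [(i, h[3:]) for i, h in enumerate(header) if h.startswith("lr:")]
        col = {h: i for i, h in enumerate(header)}
        rows: Dict[Pair, PairScore] = {}
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(header):
                raise ValueError(f"{path}: malformed row at line {lineno}")
            pair = canonical_pair(fields[0], fields[1])
            evidence_lrs = {
                name: float(fields[i]) for i, name in ev_cols if fields[i] != ""
            }
            tier = fields[col["tier"]]
            if tier not in {"high", "medium", "low"}:
                raise ValueError(f"{path}: bad tier {tier!r} at line {lineno}")
            rows[pair] = PairScore(
                evidence_lrs=evidence_lrs,
                lr_functional=float(fields[col["lr_functional"]]),
                lr_total=float(fields[col["lr_total"]]),
                posterior_odds=float(fields[col["posterior_odds"]]),
                tier=tier,
            )
    return ScoredNetwork(rows=rows)
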