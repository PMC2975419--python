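"""The seven evidence signals, each against its independent oracle."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bayespin.evidence import (
    EvidenceLayer,
    GeneContextTable,
    OrthologMap,
    PhyloProfile,
    coexpression_scores,
    domain_support,
    gene_fusion_pairs,
    gene_neighbor_pairs,
    phylo_profile_scores,
    project_orthologs,
    ssbp_scores,
)
from bayespin.io_formats import AnnotationTable, ExpressionMatrix, OntologyDag


class TestProjectOrthologs:
    def test_one_to_one_transfer(self):
        omap = OrthologMap("scer", {"X": {"A"}, "Y": {"B"}})
        layer = project_orthologs({("X", "Y")}, omap)
        assert layer.flagged() == {("A", "B")}
        assert layer.binary and layer.complete

    def test_shared_ortholog_gives_no_self_pair(self):
        omap = OrthologMap("scer", {"X": {"A"}, "Y": {"A"}})
        assert project_orthologs({("X", "Y")}, omap).flagged() == set()

    def test_one_to_many_cross_product(self):
        omap = OrthologMap("scer", {"X": {"A1", "A2"}, "Y": {"B"}})
        layer = project_orthologs({("X", "Y")}, omap)
        assert layer.flagged() == {("A1", "B"), ("A2", "B")}

    def test_count_matches_cross_product_oracle(self):
        rng = np.random.default_rng(3)
        source = {(f"X{i}", f"X{i + 10}") for i in range(8)}
        mapping = {
            f"X{i}": {f"A{j}" for j in rng.choice(12, size=rng.integers(1, 4), replace=False)}
            for i in range(20)
        }
        layer = project_orthologs(source, OrthologMap("org", mapping))
        expected = set()
        for x, y in source:  # brute-force enumeration
            for a in mapping[x]:
                for b in mapping[y]:
                    if a != b:
                        expected.add(tuple(sorted((a, b))))
        assert layer.flagged() == expected


class TestCoexpression:
    def _matrix(self, **vectors):
        genes = sorted(vectors)
        return ExpressionMatrix(
            genes=genes,
            samples=[f"s{i}" for i in range(len(next(iter(vectors.values()))))],
            values=np.array([vectors[g] for g in genes], dtype=float),
        )

    def test_identical_vectors(self):
        expr = self._matrix(a=[1, 2, 3], b=[1, 2, 3])
        layer = coexpression_scores(expr, [("a", "b")])
        assert layer.values[("a", "b")] == pytest.approx(1.0)

    def test_anticorrelated_vectors(self):
        expr = self._matrix(a=[1, 0, -1], b=[-1, 0, 1])
        layer = coexpression_scores(expr, [("a", "b")])
        assert layer.values[("a", "b")] == pytest.approx(-1.0)

    def test_closed_form_value(self):
        # Pearson r of (1,2,3) vs (1,2,4) computed in closed form: 3/sqrt(2*21/3)
        expr = self._matrix(a=[1, 2, 3], b=[1, 2, 4])
        expected = 3 / np.sqrt(2 * (42 / 9))
        layer = coexpression_scores(expr, [("a", "b")])
        assert layer.values[("a", "b")] == pytest.approx(expected, rel=1e-9)

    def test_too_few_samples_is_error(self):
        expr = self._matrix(a=[1, 2], b=[2, 1])
        with pytest.raises(ValueError):
            coexpression_scores(expr, [("a", "b")])

    def test_zero_variance_excluded_from_coverage(self):
        expr = self._matrix(a=[1, 1, 1], b=[1, 2, 3])
        layer = coexpression_scores(expr, [("a", "b")])
        assert ("a", "b") not in layer.coverage

    @settings(max_examples=50, derandomize=True)
    @given(
        scale=st.floats(min_value=0.1, max_value=50),
        shift=st.floats(min_value=-100, max_value=100),
    )
    def test_affine_invariance(self, scale, shift):
        base = np.array([0.5, 1.7, -2.1, 3.3, 0.2])
        expr = self._matrix(a=base, b=scale * base + shift)
        layer = coexpression_scores(expr, [("a", "b")])
        assert layer.values[("a", "b")] == pytest.approx(1.0, abs=1e-9)


class TestDomainSupport:
    def test_direct_hit(self):
        layer = domain_support({"a": {"D1"}, "b": {"D2"}}, {("D1", "D2")}, [("a", "b")])
        assert layer.values[("a", "b")] == 1.0

    def test_miss(self):
        layer = domain_support({"a": {"D1"}, "b": {"D2"}}, {("D1", "D3")}, [("a", "b")])
        assert layer.values[("a", "b")] == 0.0

    def test_homotypic_domain_pair(self):
        layer = domain_support({"a": {"D1"}, "b": {"D1"}}, {("D1", "D1")}, [("a", "b")])
        assert layer.values[("a", "b")] == 1.0

    def test_domainless_protein_covered_with_zero(self):
        layer = domain_support({"a": {"D1"}}, {("D1", "D1")}, [("a", "b")])
        assert layer.values[("a", "b")] == 0.0
        assert ("a", "b") in layer.coverage


def _random_dag_world(rng, n_terms, n_proteins):
    terms = [f"T{i}" for i in range(n_terms)]
    parents = {}
    for i in range(1, n_terms):
        k = int(rng.integers(0, min(i, 2) + 1))
        if k:
            chosen = rng.choice(i, size=k, replace=False)
            parents[terms[i]] = frozenset(terms[j] for j in chosen)
    dag = OntologyDag(
        terms=frozenset(terms),
        parents=parents,
        namespace={t: "BP" for t in terms},
    )
    rows = []
    proteins = [f"P{i:02d}" for i in range(n_proteins)]
    for p in proteins:
        for t in rng.choice(terms, size=rng.integers(1, 4), replace=False):
            rows.append((p, t, "BP", "IDA"))
    return dag, parents, AnnotationTable.from_rows(rows), proteins


def brute_force_ssbp(annotations, parents, pairs):
    """Oracle: explicit propagation to all ancestors, explicit counting."""
    direct = annotations.protein_terms(aspect="BP")
    propagated = {}
    for protein, terms in direct.items():
        closed = set()
        for t in terms:
            stack = [t]
            while stack:
                cur = stack.pop()
                if cur in closed:
                    continue
                closed.add(cur)
                stack.extend(parents.get(cur, ()))
        propagated[protein] = closed
    sizes = {}
    for terms in propagated.values():
        for t in terms:
            sizes[t] = sizes.get(t, 0) + 1
    out = {}
    for a, b in pairs:
        shared = propagated.get(a, set()) & propagated.get(b, set())
        if shared:
            out[tuple(sorted((a, b)))] = float(min(sizes[t] for t in shared))
    return out


class TestSsbp:
    def test_shared_leaf_term_size(self):
        terms = ["root"] + [f"L{i}" for i in range(3)]
        parents = {f"L{i}": frozenset({"root"}) for i in range(3)}
        dag = OntologyDag(
            terms=frozenset(terms), parents=parents, namespace={t: "BP" for t in terms}
        )
        rows = [(f"P{i}", "L0", "BP", "IDA") for i in range(5)]
        rows += [(f"Q{i}", "L1", "BP", "IDA") for i in range(10)]
        table = AnnotationTable.from_rows(rows)
        layer = ssbp_scores(table, dag, [("P0", "P1")])
        # P0 and P1 share L0 (5 proteins) and root (15); the minimum wins
        assert layer.values[("P0", "P1")] == 5.0

    def test_root_only_share(self):
        terms = ["root", "L0", "L1"]
        parents = {"L0": frozenset({"root"}), "L1": frozenset({"root"})}
        dag = OntologyDag(
            terms=frozenset(terms), parents=parents, namespace={t: "BP" for t in terms}
        )
        table = AnnotationTable.from_rows(
            [("A", "L0", "BP", "IDA"), ("B", "L1", "BP", "IDA")]
        )
        layer = ssbp_scores(table, dag, [("A", "B")])
        assert layer.values[("A", "B")] == 2.0  # root annotates both proteins

    def test_no_shared_term_uncovered(self):
        terms = ["r1", "r2"]
        dag = OntologyDag(
            terms=frozenset(terms), parents={}, namespace={t: "BP" for t in terms}
        )
        table = AnnotationTable.from_rows(
            [("A", "r1", "BP", "IDA"), ("B", "r2", "BP", "IDA")]
        )
        layer = ssbp_scores(table, dag, [("A", "B")])
        assert ("A", "B") not in layer.coverage

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(17)
        for _ in range(15):
            dag, parents, table, proteins = _random_dag_world(
                rng, int(rng.integers(5, 41)), int(rng.integers(5, 31))
            )
            pairs = list(itertools.combinations(proteins, 2))
            layer = ssbp_scores(table, dag, pairs)
            assert layer.values == brute_force_ssbp(table, parents, pairs)


class TestGeneFusion:
    def test_disjoint_intervals_flagged(self):
        hits = [("a", "t", 1, 100, "g"), ("b", "t", 120, 220, "g")]
        layer = gene_fusion_pairs(hits, 0.2, [("a", "b")])
        assert layer.values[("a", "b")] == 1.0

    def test_large_overlap_not_flagged(self):
        # overlap 51 bp on a 101 bp shorter interval: 51/101 > 0.2
        hits = [("a", "t", 1, 100, "g"), ("b", "t", 50, 150, "g")]
        layer = gene_fusion_pairs(hits, 0.2, [("a", "b")])
        assert layer.values[("a", "b")] == 0.0

    def test_different_targets_not_flagged(self):
        hits = [("a", "t1", 1, 100, "g"), ("b", "t2", 1, 100, "g")]
        layer = gene_fusion_pairs(hits, 0.2, [("a", "b")])
        assert layer.values[("a", "b")] == 0.0

    def test_inverted_interval_is_error(self):
        with pytest.raises(ValueError):
            gene_fusion_pairs([("a", "t", 100, 1, "g")], 0.2, None)


class TestPhyloProfile:
    def _profiles(self, **vectors):
        return PhyloProfile(
            genomes=[f"G{i}" for i in range(4)],
            vectors={k: np.array(v) for k, v in vectors.items()},
        )

    def test_identical_profiles(self):
        p = self._profiles(a=[1, 0, 1, 0], b=[1, 0, 1, 0])
        layer = phylo_profile_scores(p, [("a", "b")])
        assert layer.values[("a", "b")] == 1.0

    def test_complementary_profiles(self):
        p = self._profiles(a=[1, 0, 1, 0], b=[0, 1, 0, 1])
        layer = phylo_profile_scores(p, [("a", "b")])
        assert layer.values[("a", "b")] == 0.0

    def test_half_matching(self):
        p = self._profiles(a=[1, 1, 0, 0], b=[1, 0, 1, 0])
        layer = phylo_profile_scores(p, [("a", "b")])
        assert layer.values[("a", "b")] == 0.5

    def test_uninformative_profile_uncovered(self):
        p = self._profiles(a=[1, 1, 1, 1], b=[1, 0, 1, 0])
        layer = phylo_profile_scores(p, [("a", "b")])
        assert ("a", "b") not in layer.coverage

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            PhyloProfile(genomes=["G0", "G1"], vectors={"a": np.array([1, 0, 1])})


class TestGeneNeighbor:
    def _context(self, gap, n_genomes=2):
        genomes, links = {}, {}
        for i in range(n_genomes):
            g = f"ref{i}"
            genomes[g] = {
                "ga": ("c1", 1000, 2000, "+"),
                "gb": ("c1", 2000 + gap + 1, 4000 + gap, "+"),
            }
            links[g] = {"a": {"ga"}, "b": {"gb"}}
        return GeneContextTable(genomes=genomes, links=links)

    def test_adjacent_in_enough_genomes(self):
        layer = gene_neighbor_pairs(self._context(gap=200), 5000, 2, [("a", "b")])
        assert layer.values[("a", "b")] == 1.0

    def test_distance_fail(self):
        layer = gene_neighbor_pairs(self._context(gap=50000), 5000, 2, [("a", "b")])
        assert layer.values[("a", "b")] == 0.0

    def test_genome_count_fail(self):
        layer = gene_neighbor_pairs(
            self._context(gap=200, n_genomes=1), 5000, 2, [("a", "b")]
        )
        assert layer.values[("a", "b")] == 0.0

    def test_different_contigs_never_adjacent(self):
        context = GeneContextTable(
            genomes={"r": {"ga": ("c1", 1, 10, "+"), "gb": ("c2", 11, 20, "+")}},
            links={"r": {"a": {"ga"}, "b": {"gb"}}},
        )
        layer = gene_neighbor_pairs(context, 5000, 1, [("a", "b")])
        assert layer.values[("a", "b")] == 0.0


class TestLayerInvariants:
    def test_binary_layer_rejects_non_flag_values(self):
        with pytest.raises(ValueError):
            EvidenceLayer(name="x", values={("A", "B"): 0.5}, binary=True)

    def test_non_finite_scores_rejected(self):
        with pytest.raises(ValueError):
            EvidenceLayer(name="x", values={("A", "B"): float("nan")})

    def test_complete_layer_implicit_zero(self):
        layer = EvidenceLayer(name="x", values={("A", "B"): 1.0}, binary=True, complete=True)
        assert layer.value(("C", "D")) == 0.0
        assert layer.value(("A", "B")) == 1.0
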