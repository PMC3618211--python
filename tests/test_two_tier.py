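"""Two-tier pipelining, dependency-chain features, reference classifier."""

import io
import itertools
import random

import numpy as np
import pytest

from ppirules.corpus import enumerate_candidates
from ppirules.evaluation import (
    gold_instances,
    join_predictions,
    per_instance_eval,
)
from ppirules.fixtures import SynthConfig, generate_corpus, worked_examples
from ppirules.two_tier import (
    AlwaysNegative,
    DepChain,
    ExternalLabelTier,
    ExtractionInstance,
    FeatureSpec,
    FeatureTier,
    RuleTier,
    ThresholdClassifier,
    chain_bigrams,
    extract_chains,
    featurize,
    pipeline,
    select_top_features,
    tiered_to_predictions,
)


class MappingTier:
    """Test helper: fixed labels keyed by instance."""

    def __init__(self, positives, name="mapping"):
        self.name = name
        self._pos = set(positives)

    def fit(self, instances, labels):
        pass

    def predict(self, instance):
        return instance.instance_key in self._pos


class ExplodingTier:
    name = "exploding"

    def fit(self, instances, labels):
        pass

    def predict(self, instance):
        raise RuntimeError("boom")


@pytest.fixture(scope="module")
def instances(small_corpus_module=None):
    corpus = generate_corpus(
        SynthConfig(seed=31, n_positive_relations=10, n_negative_relations=25)
    )
    return corpus, corpus.extraction_instances()


class TestPipeline:
    def test_always_negative_second_tier_is_identity(self, instances):
        corpus, insts = instances
        rules = RuleTier()
        alone = [rules.predict(i) for i in insts]
        tiered = pipeline(rules, AlwaysNegative(), insts)
        assert [t.label for t in tiered] == alone

    def test_union_of_disjoint_positive_sets(self, instances):
        _, insts = instances
        keys = [i.instance_key for i in insts]
        t1 = MappingTier(keys[:3], "t1")
        t2 = MappingTier(keys[3:7], "t2")
        tiered = pipeline(t1, t2, insts)
        assert sum(t.label for t in tiered) == 7
        assert {t.tier for t in tiered if t.label} == {"t1", "t2"}

    def test_positive_preservation_and_union_semantics(self, instances):
        """Pipeline positives == tier1 positives | tier2 positives on tier1 rejections."""
        _, insts = instances
        rng = random.Random(4)
        t2 = MappingTier(
            {i.instance_key for i in insts if rng.random() < 0.3}, "random"
        )
        rules = RuleTier()
        tiered = pipeline(rules, t2, insts)
        by_key = {t.instance.instance_key: t.label for t in tiered}
        for inst in insts:
            l1 = rules.predict(inst)
            expected = l1 or t2.predict(inst)  # brute-force union oracle
            assert by_key[inst.instance_key] == expected
            if l1:
                assert by_key[inst.instance_key]  # never flipped

    def test_tp_fp_monotone_over_rules_alone(self, instances):
        corpus, insts = instances
        rules = RuleTier()
        gold = gold_instances(corpus.sentences)
        alone = join_predictions(gold, tiered_to_predictions(pipeline(rules, AlwaysNegative(), insts)))
        t2 = MappingTier([i.instance_key for i in insts[::5]], "every5")
        piped = join_predictions(gold, tiered_to_predictions(pipeline(rules, t2, insts)))
        ra, rp = per_instance_eval(alone), per_instance_eval(piped)
        assert rp.counts.tp >= ra.counts.tp
        assert rp.counts.fp >= ra.counts.fp

    def test_order_matters_but_degenerate_orders_agree(self, instances):
        _, insts = instances
        rules = RuleTier()
        other = MappingTier([i.instance_key for i in insts[:2]], "other")
        ab = [t.label for t in pipeline(rules, other, insts)]
        ba = [t.label for t in pipeline(other, rules, insts)]
        assert ab == ba  # labels agree (union); provenance differs
        prov_ab = [t.tier for t in pipeline(rules, other, insts)]
        prov_ba = [t.tier for t in pipeline(other, rules, insts)]
        assert prov_ab != prov_ba

    def test_tier_failure_inherits_tier1_label(self, instances, caplog):
        _, insts = instances
        tiered = pipeline(AlwaysNegative(), ExplodingTier(), insts[:4])
        assert [t.label for t in tiered] == [False] * 4

    def test_external_label_tier_splices_predictions(self, instances):
        corpus, insts = instances
        rules = RuleTier()
        preds = tiered_to_predictions(pipeline(rules, AlwaysNegative(), insts))
        ext = ExternalLabelTier(preds, "replay")
        replay = pipeline(ext, AlwaysNegative(), insts)
        assert [t.label for t in replay] == [rules.predict(i) for i in insts]


class TestChains:
    def _fig1(self):
        case = next(c for c in worked_examples() if c.name == "fig1_rule1")
        pairs = {p.mention_ids: p for p in enumerate_candidates(case.sentence)}
        return case, pairs

    def test_forward_chain_to_subject_has_length_one(self):
        case, pairs = self._fig1()
        fwd, bwd = extract_chains(case.tree, pairs[frozenset(("e0", "e1"))])
        assert fwd.direction == "forward" and len(fwd) == 1
        assert fwd.elements == (("nsubj", "protein0"),)
        assert bwd.elements == (("prep_with", "protein1"),)

    def test_propagated_edges_excluded_from_paths(self):
        case, pairs = self._fig1()
        _, bwd = extract_chains(case.tree, pairs[frozenset(("e0", "e2"))])
        # P2 is reached through the conjunction, not the propagated prep
        assert bwd.elements == (("prep_with", "protein1"), ("conj_and", "protein2"))

    def test_root_protein_has_empty_chain(self):
        from ppirules.fixtures import build_sentence, build_tree

        sent = build_sentence("s", "PROTEIN0/PROPN of/ADP PROTEIN1/PROPN")
        tree = build_tree(
            "s", "PROTEIN0/PROPN of/ADP PROTEIN1/PROPN", [(0, 2, "nmod"), (2, 1, "case")]
        )
        (pair,) = enumerate_candidates(sent)
        fwd, bwd = extract_chains(tree, pair)
        assert fwd.elements == () and fwd.complete
        assert len(bwd) == 1

    def test_path_uniqueness_on_all_fixture_trees(self):
        for case in worked_examples():
            if case.tree is None:
                continue
            for pair in enumerate_candidates(case.sentence):
                a1 = extract_chains(case.tree, pair)
                a2 = extract_chains(case.tree, pair)
                assert a1 == a2
                assert all(c.complete for c in a1)

    @pytest.mark.parametrize(
        "n_elements,n_bigrams", [(0, 0), (1, 0), (2, 1), (3, 2), (5, 4)]
    )
    def test_bigram_count(self, n_elements, n_bigrams):
        chain = DepChain("forward", tuple((f"l{i}", f"w{i}") for i in range(n_elements)))
        assert len(chain_bigrams(chain)) == n_bigrams

    def test_bigrams_are_adjacent_pairs(self):
        chain = DepChain("forward", (("nsubj", "a"), ("prep_of", "b"), ("conj_and", "c")))
        assert chain_bigrams(chain) == [
            ("nsubj/a", "prep_of/b"),
            ("prep_of/b", "conj_and/c"),
        ]
        assert chain_bigrams(chain, mode="label") == [
            ("nsubj", "prep_of"),
            ("prep_of", "conj_and"),
        ]


class TestFeatureSelection:
    def test_contrast_score_arithmetic(self):
        # one bigram: 5 forward, 1 backward occurrences -> forward score 4
        chains = []
        for _ in range(5):
            chains.append(
                (DepChain("forward", (("a", "x"), ("b", "y"))), DepChain("backward", ()))
            )
        chains.append(
            (DepChain("forward", ()), DepChain("backward", (("a", "x"), ("b", "y"))))
        )
        insts = [_chain_instance(f, b) for f, b in chains]
        spec = select_top_features(insts, n=10)
        assert spec.top_forward_bigrams == (("a/x", "b/y"),)
        assert spec.top_backward_bigrams == (("a/x", "b/y"),)

    def test_all_tied_scores_fall_to_deterministic_tiebreak(self):
        insts = []
        for i in range(4):
            elems = ((f"l{i}", "w"), (f"m{i}", "v"))
            insts.append(
                _chain_instance(DepChain("forward", elems), DepChain("backward", elems))
            )
        spec = select_top_features(insts, n=2)
        scored = sorted(
            {bg for i in range(4) for bg in [(f"l{i}/w", f"m{i}/v")]}
        )
        assert spec.top_forward_bigrams == tuple(scored[:2])

    def test_top100_matches_bruteforce_sort_oracle(self):
        rng = np.random.default_rng(13)
        vocab = [(f"lab{i}", f"lem{i}") for i in range(40)]
        insts = []
        for _ in range(200):
            k = int(rng.integers(2, 6))
            felems = tuple(vocab[i] for i in rng.integers(0, 40, size=k))
            belems = tuple(vocab[i] for i in rng.integers(0, 40, size=k))
            insts.append(
                _chain_instance(DepChain("forward", felems), DepChain("backward", belems))
            )
        spec = select_top_features(insts, n=100)
        # brute-force oracle
        from collections import Counter

        fwd, bwd = Counter(), Counter()
        for inst in insts:
            fwd.update(chain_bigrams(inst.chains[0]))
            bwd.update(chain_bigrams(inst.chains[1]))
        expected = sorted(
            fwd.keys() | bwd.keys(),
            key=lambda bg: (-(fwd[bg] - bwd[bg]), -fwd[bg], bg),
        )[:100]
        assert list(spec.top_forward_bigrams) == expected

    def test_permutation_invariance(self):
        rng = random.Random(3)
        insts = []
        for i in range(30):
            elems = tuple((f"l{j}", "w") for j in range(i % 4 + 1))
            insts.append(
                _chain_instance(DepChain("forward", elems), DepChain("backward", ()))
            )
        spec = select_top_features(insts, n=5)
        shuffled = insts[:]
        rng.shuffle(shuffled)
        assert select_top_features(shuffled, n=5) == spec


class _ChainCarrier:
    """Minimal instance carrying precomputed chains (honored by featurize)."""

    def __init__(self, fwd, bwd):
        self.chains = (fwd, bwd)
        self.tree = None
        self.pair = None
        self.sentence = None

    @property
    def instance_key(self):
        return id(self)


def _chain_instance(fwd, bwd):
    return _ChainCarrier(fwd, bwd)


class TestFeaturize:
    def test_single_active_forward_bigram(self):
        spec = FeatureSpec(
            top_forward_bigrams=(("a/x", "b/y"), ("c/z", "d/w")),
            top_backward_bigrams=(("e/v", "f/u"),),
        )
        inst = _chain_instance(
            DepChain("forward", (("a", "x"), ("b", "y"))), DepChain("backward", ())
        )
        vec = featurize(inst, spec)
        assert vec.tolist() == [1.0, 0.0, 0.0]

    def test_offset_distance_of_adjacent_proteins_is_one(self):
        from ppirules.fixtures import build_sentence, build_tree

        sent = build_sentence("s", "PROTEIN0/PROPN PROTEIN1/PROPN bind/VERB")
        tree = build_tree(
            "s", "PROTEIN0/PROPN PROTEIN1/PROPN bind/VERB",
            [(2, 0, "nsubj"), (0, 1, "conj")],
        )
        (pair,) = enumerate_candidates(sent)
        spec = FeatureSpec((), (), use_offset_distance=True)
        assert featurize(ExtractionInstance(sent, pair, tree), spec).tolist() == [1.0]

    def test_dimension_formula_on_corpus(self):
        corpus = generate_corpus(
            SynthConfig(seed=2, n_positive_relations=5, n_negative_relations=5)
        )
        insts = corpus.extraction_instances()
        for use_len, use_off in itertools.product([False, True], repeat=2):
            spec = select_top_features(
                insts, n=10, use_dep_lengths=use_len, use_offset_distance=use_off
            )
            expected = (
                len(spec.top_forward_bigrams)
                + len(spec.top_backward_bigrams)
                + 2 * use_len
                + use_off
            )
            assert spec.dimension == expected
            for inst in insts[:10]:
                assert featurize(inst, spec).shape == (expected,)

    def test_spec_json_roundtrip(self):
        spec = FeatureSpec(
            top_forward_bigrams=(("a/x", "b/y"),),
            top_backward_bigrams=(("c/z", "d/w"),),
            use_dep_lengths=True,
        )
        buf = io.StringIO()
        spec.to_json(buf)
        buf.seek(0)
        assert FeatureSpec.from_json(buf) == spec


class TestThresholdClassifier:
    @pytest.mark.parametrize(
        "X,y",
        [
            ([[1, 1, 0], [1, 0, 0], [0, 0, 0], [1, 1, 1]], [True, False, False, True]),
            ([[0, 0], [0, 1], [1, 1]], [False, False, True]),
            ([[1], [1], [1]], [True, True, True]),
        ],
    )
    def test_fit_matches_exhaustive_search(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=bool)
        clf = ThresholdClassifier()
        clf.fit(X, y)
        # exhaustive oracle over all thresholds
        best_f, best_t = -1.0, None
        for t in range(0, int(X.sum(axis=1).max()) + 2):
            pred = X.sum(axis=1) >= t
            tp = int((pred & y).sum())
            fp = int((pred & ~y).sum())
            fn = int((~pred & y).sum())
            f = 2 * tp / (2 * tp + fp + fn) if tp else 0.0
            if f > best_f:
                best_f, best_t = f, t
        assert clf.threshold == best_t
        for row in X:
            assert clf.predict_vector(row) == (row.sum() >= best_t)

    def test_predict_before_fit_raises(self):
        with pytest.raises(RuntimeError):
            ThresholdClassifier().predict_vector(np.zeros(3))


class TestFeatureTier:
    def test_threshold_tier_predictions_match_fitted_threshold(self):
        corpus = generate_corpus(
            SynthConfig(
                seed=8, n_positive_relations=12, n_negative_relations=12, miss_rate=0.0
            )
        )
        insts = corpus.extraction_instances()
        labels = [any(s.gold_pairs.values()) for s in corpus.sentences if s.is_candidate]
        spec = select_top_features(insts, n=50)
        tier = FeatureTier(spec, ThresholdClassifier(), "ml")
        tier.fit(insts, labels)
        t = tier.model.threshold
        assert t is not None
        for inst in insts[:40]:
            assert tier.predict(inst) == (featurize(inst, spec).sum() >= t)

    def test_sklearn_estimator_satisfies_contract(self):
        from sklearn.tree import DecisionTreeClassifier

        corpus = generate_corpus(
            SynthConfig(seed=9, n_positive_relations=8, n_negative_relations=8)
        )
        insts = corpus.extraction_instances()
        labels = [any(s.gold_pairs.values()) for s in corpus.sentences if s.is_candidate]
        spec = select_top_features(insts, n=30)
        tier = FeatureTier(spec, DecisionTreeClassifier(random_state=0), "dt")
        tier.fit(insts, labels)
        out = pipeline(RuleTier(), tier, insts)
        assert len(out) == len(insts)
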