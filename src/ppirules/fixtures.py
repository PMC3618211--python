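"""Executable worked examples and a seeded synthetic corpus generator.

``worked_examples`` returns hand-built sentence/tree cases, one per
rule behavior (positive patterns, negation vetoes, rejection clauses),
with the expected per-pair outcome.  The dependency trees are
reconstructions of the canonical example phrases ("binding of P0 to
P1", "erythropoietin receptor (EPOR)", ...); where the original figure
sentence is not printed in full, the fixture text is a marked
reconstruction chosen so the documented locality constraints (7-word
window, 3 dependency-bearing words) hold with equality where stated.

``generate_corpus`` emulates the statistical structure of an
exhaustively annotated PPI corpus: distinct relations with controlled
instance multiplicities (so MIpR strata are exact), a configurable mix
of rule-matching positive phrasings, positive phrasings outside the
rule inventory (misses), negated variants and keyword-free distractor
sentences.  All sampling is driven by a mandatory seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from ppirules.corpus import AnnotatedSentence, ProteinMention, mask_proteins
from ppirules.deps import DepEdge, DepTree, Token, collapse_ud
from ppirules.errors import ConfigError
from ppirules.rules import Prediction
from ppirules.two_tier import ExtractionInstance
from ppirules.corpus import enumerate_candidates


# ---------------------------------------------------------------------------
# sentence/tree builders
# ---------------------------------------------------------------------------

def _parse_token_spec(spec: str) -> list[tuple[str, str]]:
    out = []
    for item in spec.split():
        text, _, pos = item.rpartition("/")
        if not text:
            text, pos = item, ""
        out.append((text, pos))
    return out


def build_sentence(
    sentence_id: str,
    token_spec: str,
    *,
    entity_keys: dict[str, str] | None = None,
    gold: dict[frozenset, bool] | None = None,
    raw_names: dict[str, str] | None = None,
) -> AnnotatedSentence:
    """Build a masked sentence from a ``text/POS`` token spec.

    ``PROTEINk`` tokens become mentions with ids ``e<k>``.  When
    ``raw_names`` maps mask labels to surface names, the raw text uses
    those names (and masking is exercised for real); otherwise the raw
    text equals the masked text.
    """
    toks = [t for t, _ in _parse_token_spec(token_spec)]
    masked_text = " ".join(toks)
    labels = [t for t in toks if t.startswith("PROTEIN")]
    if raw_names:
        raw_tokens = [raw_names.get(t, t) for t in toks]
        raw_text = " ".join(raw_tokens)
        spans = []
        pos = 0
        for t in raw_tokens:
            start = raw_text.index(t, pos)
            if t in raw_names.values():
                spans.append((start, start + len(t)))
            pos = start + len(t)
        keys = [
            (entity_keys or {}).get(lbl, "") for lbl in labels
        ]
        ids = [f"e{lbl.removeprefix('PROTEIN')}" for lbl in labels]
        masked, mentions = mask_proteins(raw_text, spans, mention_ids=ids, entity_keys=keys)
        assert masked == masked_text, (masked, masked_text)
    else:
        raw_text = masked_text
        mentions = []
        cursor = 0
        for lbl in labels:
            start = masked_text.index(lbl, cursor)
            k = lbl.removeprefix("PROTEIN")
            mentions.append(
                ProteinMention(
                    mention_id=f"e{k}",
                    char_span=(start, start + len(lbl)),
                    surface=lbl,
                    mask_label=lbl,
                    entity_key=(entity_keys or {}).get(lbl, f"synthkey{k}"),
                )
            )
            cursor = start + len(lbl)
    return AnnotatedSentence(
        sentence_id=sentence_id,
        raw_text=raw_text,
        masked_text=masked_text,
        tokens=toks,
        mentions=mentions,
        gold_pairs=dict(gold) if gold else {},
    )


def build_tree(
    sentence_id: str,
    token_spec: str,
    edges: Sequence[tuple[int, int, str]],
    *,
    lemmas: dict[int, str] | None = None,
    collapse: bool = True,
) -> DepTree:
    """Build a dependency tree from 0-based (head, dependent, label) edges.

    The root is the token with no incoming edge.  UD-style labels are
    collapsed unless ``collapse=False``; collapsed input passes through
    unchanged (idempotence).
    """
    parsed = _parse_token_spec(token_spec)
    tokens = [
        Token(index=i, text=t, lemma=(lemmas or {}).get(i, ""), coarse_pos=pos)
        for i, (t, pos) in enumerate(parsed)
    ]
    dep_edges = [DepEdge(h, d, lbl) for h, d, lbl in edges]
    with_incoming = {e.dependent for e in dep_edges}
    roots = [t.index for t in tokens if t.index not in with_incoming]
    content_roots = [r for r in roots if tokens[r].coarse_pos not in ("PUNCT",)]
    root = content_roots[0] if content_roots else 0
    tree = DepTree(sentence_id=sentence_id, tokens=tokens, edges=dep_edges, root=root)
    return collapse_ud(tree) if collapse else tree


# ---------------------------------------------------------------------------
# worked examples
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FixtureCase:
    """One worked example: sentence, optional tree, expected outcomes.

    ``expected`` maps each candidate mention-id pair to the rule id
    that should label it positive, or None.  ``expected_negated`` lists
    the pairs whose negative label must come from a negation veto.
    """

    name: str
    sentence: AnnotatedSentence
    tree: DepTree | None
    expected: dict
    citation: str
    expected_negated: frozenset = frozenset()


def _case(
    name: str,
    token_spec: str,
    edges: Sequence[tuple[int, int, str]] | None,
    expected: dict[tuple[str, str], int | None],
    citation: str,
    *,
    negated: Iterable[tuple[str, str]] = (),
    lemmas: dict[int, str] | None = None,
) -> FixtureCase:
    exp = {frozenset(k): v for k, v in expected.items()}
    gold = {k: v is not None for k, v in exp.items()}
    sentence = build_sentence(name, token_spec, gold=gold)
    tree = build_tree(name, token_spec, edges, lemmas=lemmas) if edges is not None else None
    return FixtureCase(
        name=name,
        sentence=sentence,
        tree=tree,
        expected=exp,
        citation=citation,
        expected_negated=frozenset(frozenset(p) for p in negated),
    )


def worked_examples() -> list[FixtureCase]:
    """The bundled rule-by-rule worked examples (reconstructed trees)."""
    cases = [
        _case(
            "fig1_rule1",
            "PROTEIN0/PROPN interacts/VERB directly/ADV with/ADP PROTEIN1/PROPN "
            "and/CCONJ PROTEIN2/PROPN",
            [(1, 0, "nsubj"), (1, 2, "advmod"), (1, 4, "obl"), (4, 3, "case"),
             (4, 6, "conj"), (6, 5, "cc")],
            {("e0", "e1"): 1, ("e0", "e2"): 1, ("e1", "e2"): None},
            "subject-verb-prep pattern; conjunction propagation extracts both "
            "pairs (reconstructed figure sentence)",
        ),
        _case(
            "rule1_negated_verb",
            "PROTEIN0/PROPN does/AUX not/PART bind/VERB to/ADP PROTEIN1/PROPN",
            [(3, 0, "nsubj"), (3, 1, "aux"), (3, 2, "advmod"), (3, 5, "obl"),
             (5, 4, "case")],
            {("e0", "e1"): None},
            "negation on the relation verb vetoes the match",
            negated=[("e0", "e1")],
        ),
        _case(
            "rule1_negated_subject",
            "no/DET PROTEIN0/PROPN binds/VERB to/ADP PROTEIN1/PROPN",
            [(2, 1, "nsubj"), (1, 0, "det"), (2, 4, "obl"), (4, 3, "case")],
            {("e0", "e1"): None},
            "negative determiner on the subject vetoes the match",
            negated=[("e0", "e1")],
        ),
        _case(
            "rule2_binding_of_to",
            "binding/NOUN of/ADP PROTEIN0/PROPN to/ADP PROTEIN1/PROPN",
            [(0, 2, "nmod"), (2, 1, "case"), (0, 4, "nmod"), (4, 3, "case")],
            {("e0", "e1"): 2},
            "nominal keyword with prep_of and prep_to arguments",
        ),
        _case(
            "rule2_negated_keyword",
            "no/DET interaction/NOUN of/ADP PROTEIN0/PROPN with/ADP PROTEIN1/PROPN "
            "was/AUX found/VERB",
            [(7, 1, "nsubjpass"), (1, 0, "det"), (1, 3, "nmod"), (3, 2, "case"),
             (1, 5, "nmod"), (5, 4, "case"), (7, 6, "auxpass")],
            {("e0", "e1"): None},
            "negation checked on the relation noun itself",
            negated=[("e0", "e1")],
        ),
        _case(
            "rule2_negated_verb_level",
            "activation/NOUN of/ADP PROTEIN0/PROPN by/ADP PROTEIN1/PROPN was/AUX "
            "not/PART identified/VERB",
            [(7, 0, "nsubjpass"), (0, 2, "nmod"), (2, 1, "case"), (0, 4, "nmod"),
             (4, 3, "case"), (7, 5, "auxpass"), (7, 6, "advmod")],
            {("e0", "e1"): None},
            "negation at verb level vetoes the nominal keyword match",
            negated=[("e0", "e1")],
        ),
        _case(
            "rule3_interaction_between",
            "the/DET interaction/NOUN between/ADP PROTEIN0/PROPN and/CCONJ "
            "PROTEIN1/PROPN",
            [(1, 0, "det"), (1, 3, "nmod"), (3, 2, "case"), (3, 5, "conj"),
             (5, 4, "cc")],
            {("e0", "e1"): 3},
            "keyword reaches both proteins through prep_between + conjunction",
        ),
        _case(
            "rule3_two_keywords",
            "regulation/NOUN of/ADP the/DET interaction/NOUN between/ADP "
            "PROTEIN0/PROPN and/CCONJ PROTEIN1/PROPN",
            [(0, 3, "nmod"), (3, 1, "case"), (3, 2, "det"), (3, 5, "nmod"),
             (5, 4, "case"), (5, 7, "conj"), (7, 6, "cc")],
            {("e0", "e1"): 3},
            "of two keywords only the one with the prep_between path matches "
            "(reconstructed figure sentence)",
        ),
        _case(
            "rule4_conjunction_subject",
            "PROTEIN0/PROPN and/CCONJ PROTEIN1/PROPN interact/VERB",
            [(3, 0, "nsubj"), (0, 2, "conj"), (2, 1, "cc")],
            {("e0", "e1"): 4},
            "protein conjunction as nominal subject of a keyword verb",
        ),
        _case(
            "rule4_form_complex",
            "PROTEIN0/PROPN and/CCONJ PROTEIN1/PROPN form/VERB a/DET complex/NOUN",
            [(3, 0, "nsubj"), (0, 2, "conj"), (2, 1, "cc"), (3, 5, "obj"),
             (5, 4, "det")],
            {("e0", "e1"): 4},
            "'form' exempt from the dobj rejection when its dobj is 'complex'",
        ),
        _case(
            "rule4_dobj_rejection",
            "PROTEIN0/PROPN and/CCONJ PROTEIN1/PROPN activate/VERB PROTEIN2/PROPN",
            [(3, 0, "nsubj"), (0, 2, "conj"), (2, 1, "cc"), (3, 4, "obj")],
            {("e0", "e1"): None, ("e0", "e2"): 1, ("e1", "e2"): 1},
            "conjunction pair rejected because the keyword has a dobj; the "
            "subject-object pairs still match the SVO rule",
        ),
        _case(
            "rule5_dash_complex",
            "the/DET PROTEIN0/PROPN -/PUNCT PROTEIN1/PROPN complex/NOUN was/AUX "
            "purified/VERB",
            None,
            {("e0", "e1"): 5},
            "lexical compound pattern with dash separator",
        ),
        _case(
            "rule5_slash_heterodimer",
            "PROTEIN0/PROPN //SYM PROTEIN1/PROPN heterodimer/NOUN",
            None,
            {("e0", "e1"): 5},
            "lexical compound pattern with slash separator",
        ),
        _case(
            "rule5_noncue_noun",
            "PROTEIN0/PROPN -/PUNCT PROTEIN1/PROPN pathway/NOUN",
            None,
            {("e0", "e1"): None},
            "head noun outside the compound cue list: no match",
        ),
        _case(
            "rule6_receptor_for",
            "PROTEIN0/PROPN is/AUX a/DET receptor/NOUN for/ADP PROTEIN1/PROPN",
            [(3, 0, "nsubj"), (3, 1, "cop"), (3, 2, "det"), (3, 5, "nmod"),
             (5, 4, "case")],
            {("e0", "e1"): 6},
            "predicative binding-role pattern",
        ),
        _case(
            "rule6_negated",
            "PROTEIN0/PROPN is/AUX not/PART a/DET receptor/NOUN for/ADP "
            "PROTEIN1/PROPN",
            [(4, 0, "nsubj"), (4, 1, "cop"), (4, 2, "advmod"), (4, 3, "det"),
             (4, 6, "nmod"), (6, 5, "case")],
            {("e0", "e1"): None},
            "negation on the role noun vetoes the match",
            negated=[("e0", "e1")],
        ),
        _case(
            "rule6_substrate_of",
            "PROTEIN0/PROPN is/AUX a/DET substrate/NOUN of/ADP PROTEIN1/PROPN",
            [(3, 0, "nsubj"), (3, 1, "cop"), (3, 2, "det"), (3, 5, "nmod"),
             (5, 4, "case")],
            {("e0", "e1"): 6},
            "substrate-of variant of the binding-role pattern",
        ),
        _case(
            "rule7_receptor_apposition",
            "PROTEIN0/PROPN receptor/NOUN (/PUNCT PROTEIN1/PROPN )/PUNCT",
            None,
            {("e0", "e1"): 7},
            "parenthetical apposition names the receptor protein",
        ),
        _case(
            "rule7_no_parentheses",
            "PROTEIN0/PROPN receptor/NOUN PROTEIN1/PROPN",
            None,
            {("e0", "e1"): None},
            "without parentheses the apposition pattern must not fire",
        ),
        _case(
            "rule7_ligand",
            "PROTEIN0/PROPN ligand/NOUN (/PUNCT PROTEIN1/PROPN )/PUNCT",
            None,
            {("e0", "e1"): 7},
            "ligand variant of the apposition pattern",
        ),
        _case(
            "rule8_binding_domain",
            "PROTEIN0/PROPN binding/NOUN domain/NOUN on/ADP the/DET human/ADJ "
            "PROTEIN1/PROPN molecule/NOUN",
            None,
            {("e0", "e1"): 8},
            "binding-region pattern with intervening noun-phrase tokens",
        ),
        _case(
            "rule8_binding_site_of",
            "PROTEIN0/PROPN binding/NOUN site/NOUN of/ADP PROTEIN1/PROPN",
            None,
            {("e0", "e1"): 8},
            "binding-site variant",
        ),
        _case(
            "rule8_no_prep",
            "PROTEIN0/PROPN binding/NOUN domain/NOUN structure/NOUN was/AUX "
            "solved/VERB with/ADP PROTEIN1/PROPN",
            None,
            {("e0", "e1"): None},
            "cue bigram without the prepositional link: no match",
        ),
    ]
    return cases


# ---------------------------------------------------------------------------
# synthetic corpus generation
# ---------------------------------------------------------------------------

# template registry: token spec with PROTEIN0/PROTEIN1 placeholders,
# UD edges (or None for tree-free lexical sentences), and the rule
# expected to extract the pair (None for misses/negatives).
_RULE_TEMPLATES: dict[int, tuple[str, list | None]] = {
    1: (
        "PROTEIN0/PROPN activates/VERB PROTEIN1/PROPN",
        [(1, 0, "nsubj"), (1, 2, "obj")],
    ),
    2: (
        "binding/NOUN of/ADP PROTEIN0/PROPN to/ADP PROTEIN1/PROPN",
        [(0, 2, "nmod"), (2, 1, "case"), (0, 4, "nmod"), (4, 3, "case")],
    ),
    3: (
        "the/DET interaction/NOUN between/ADP PROTEIN0/PROPN and/CCONJ PROTEIN1/PROPN",
        [(1, 0, "det"), (1, 3, "nmod"), (3, 2, "case"), (3, 5, "conj"), (5, 4, "cc")],
    ),
    4: (
        "PROTEIN0/PROPN and/CCONJ PROTEIN1/PROPN interact/VERB",
        [(3, 0, "nsubj"), (0, 2, "conj"), (2, 1, "cc")],
    ),
    5: (
        "the/DET PROTEIN0/PROPN -/PUNCT PROTEIN1/PROPN complex/NOUN was/AUX purified/VERB",
        None,
    ),
    6: (
        "PROTEIN0/PROPN is/AUX a/DET receptor/NOUN for/ADP PROTEIN1/PROPN",
        [(3, 0, "nsubj"), (3, 1, "cop"), (3, 2, "det"), (3, 5, "nmod"), (5, 4, "case")],
    ),
    7: ("PROTEIN0/PROPN receptor/NOUN (/PUNCT PROTEIN1/PROPN )/PUNCT", None),
    8: (
        "PROTEIN0/PROPN binding/NOUN domain/NOUN on/ADP the/DET human/ADJ "
        "PROTEIN1/PROPN molecule/NOUN",
        None,
    ),
}

# gold-positive phrasings outside the rule inventory (extraction misses)
_MISS_TEMPLATES: list[tuple[str, list | None]] = [
    (
        "PROTEIN0/PROPN is/AUX required/VERB for/ADP the/DET full/ADJ "
        "activity/NOUN of/ADP PROTEIN1/PROPN",
        [(2, 0, "nsubjpass"), (2, 1, "auxpass"), (2, 6, "nmod"), (6, 3, "case"),
         (6, 5, "amod"), (6, 4, "det"), (6, 8, "nmod"), (8, 7, "case")],
    ),
    (
        "PROTEIN0/PROPN functions/VERB upstream/ADV of/ADP PROTEIN1/PROPN",
        [(1, 0, "nsubj"), (1, 2, "advmod"), (2, 4, "nmod"), (4, 3, "case")],
    ),
]

# gold-negative phrasings with a negated keyword
_NEGATED_TEMPLATES: list[tuple[str, list | None]] = [
    (
        "PROTEIN0/PROPN does/AUX not/PART bind/VERB to/ADP PROTEIN1/PROPN",
        [(3, 0, "nsubj"), (3, 1, "aux"), (3, 2, "advmod"), (3, 5, "obl"), (5, 4, "case")],
    ),
    (
        "no/DET interaction/NOUN of/ADP PROTEIN0/PROPN with/ADP PROTEIN1/PROPN "
        "was/AUX observed/VERB",
        [(7, 1, "nsubjpass"), (1, 0, "det"), (1, 3, "nmod"), (3, 2, "case"),
         (1, 5, "nmod"), (5, 4, "case"), (7, 6, "auxpass")],
    ),
]

# gold-negative keyword-free co-occurrences
_DISTRACTOR_TEMPLATES: list[tuple[str, list | None]] = [
    (
        "PROTEIN0/PROPN was/AUX detected/VERB near/ADP PROTEIN1/PROPN",
        [(2, 0, "nsubjpass"), (2, 1, "auxpass"), (2, 4, "nmod"), (4, 3, "case")],
    ),
    (
        "PROTEIN0/PROPN and/CCONJ PROTEIN1/PROPN were/AUX analyzed/VERB in/ADP "
        "parallel/NOUN",
        [(4, 0, "nsubjpass"), (0, 2, "conj"), (2, 1, "cc"), (4, 3, "auxpass"),
         (4, 6, "nmod"), (6, 5, "case")],
    ),
    (
        "the/DET level/NOUN of/ADP PROTEIN0/PROPN was/AUX measured/VERB "
        "alongside/ADP PROTEIN1/PROPN",
        [(5, 1, "nsubjpass"), (1, 0, "det"), (1, 3, "nmod"), (3, 2, "case"),
         (5, 4, "auxpass"), (5, 7, "nmod"), (7, 6, "case")],
    ),
]


@dataclass(frozen=True)
class SynthConfig:
    """Conditions of a synthetic corpus.

    Defaults emulate an exhaustively annotated benchmark corpus at
    reduced scale: positive relations average ~1.6 positive and ~1.5
    negative instances, negative relations ~1.7 instances; most
    positive instances (``miss_rate``) are phrased outside the rule
    inventory so that a high-precision extractor has low instance
    recall.  Explicit multiplicity lists override the sampled ones so
    MIpR strata can be controlled exactly.
    """

    seed: int
    n_positive_relations: int = 62
    n_negative_relations: int = 231
    positive_multiplicities: tuple | None = None  # ((n_pos, n_neg), ...) per relation
    negative_multiplicities: tuple | None = None  # (n_instances, ...) per relation
    rule_mix: tuple = (1, 2, 3, 4, 5, 6, 7, 8)
    miss_rate: float = 0.6
    negation_rate: float = 0.3
    distractor_rate: float = 0.5

    def __post_init__(self) -> None:
        for nm in ("miss_rate", "negation_rate", "distractor_rate"):
            v = getattr(self, nm)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{nm} must be in [0, 1], got {v}")
        if self.negation_rate + self.distractor_rate > 1.0 + 1e-9:
            raise ConfigError("negation_rate + distractor_rate must be <= 1")
        if not set(self.rule_mix) <= set(_RULE_TEMPLATES):
            raise ConfigError(f"unknown rule ids in rule_mix: {self.rule_mix}")
        if self.positive_multiplicities is not None:
            for np_, nn in self.positive_multiplicities:
                if np_ < 1 or nn < 0:
                    raise ConfigError(
                        "positive relations need >=1 positive instance and >=0 negatives"
                    )
        if self.negative_multiplicities is not None and any(
            n < 1 for n in self.negative_multiplicities
        ):
            raise ConfigError("negative relations need >=1 instance")


@dataclass
class SyntheticCorpus:
    sentences: list[AnnotatedSentence]
    trees: dict[str, DepTree]
    config: SynthConfig

    def extraction_instances(self) -> list[ExtractionInstance]:
        out = []
        for s in self.sentences:
            if not s.is_candidate:
                continue
            for pair in enumerate_candidates(s):
                out.append(ExtractionInstance(s, pair, self.trees.get(s.sentence_id)))
        return out


def _instantiate(
    sid: str,
    template: tuple[str, list | None],
    names: tuple[str, str],
    gold_label: bool,
) -> tuple[AnnotatedSentence, DepTree | None]:
    spec, edges = template
    raw_names = {"PROTEIN0": names[0], "PROTEIN1": names[1]}
    sentence = build_sentence(
        sid,
        spec,
        gold={frozenset(("e0", "e1")): gold_label},
        raw_names=raw_names,
    )
    tree = build_tree(sid, spec, edges) if edges is not None else None
    return sentence, tree


def generate_corpus(config: SynthConfig) -> SyntheticCorpus:
    """Generate a synthetic annotated corpus (reproducible from the seed)."""
    rng = np.random.default_rng(config.seed)
    counter = itertools.count()
    sentences: list[AnnotatedSentence] = []
    trees: dict[str, DepTree] = {}

    def neg_template(rng) -> tuple[str, list | None]:
        u = rng.random()
        if u < config.negation_rate:
            pool = _NEGATED_TEMPLATES
        elif u < config.negation_rate + config.distractor_rate:
            pool = _DISTRACTOR_TEMPLATES
        else:
            pool = _DISTRACTOR_TEMPLATES[-1:]  # plain co-occurrence
        return pool[int(rng.integers(len(pool)))]

    def add(template, names, label) -> None:
        sid = f"syn{next(counter)}"
        sentence, tree = _instantiate(sid, template, names, label)
        sentences.append(sentence)
        if tree is not None:
            trees[sid] = tree

    # positive relations
    if config.positive_multiplicities is not None:
        pos_mult = list(config.positive_multiplicities)
    else:
        pos_mult = [
            (1 + int(rng.poisson(0.6)), int(rng.poisson(1.5)))
            for _ in range(config.n_positive_relations)
        ]
    name_counter = itertools.count()

    def fresh_pair() -> tuple[str, str]:
        a, b = next(name_counter), next(name_counter)
        return (f"SYNPA{a}", f"SYNPB{b}")

    for n_pos, n_neg in pos_mult:
        names = fresh_pair()
        for _ in range(n_pos):
            if rng.random() < config.miss_rate:
                tpl = _MISS_TEMPLATES[int(rng.integers(len(_MISS_TEMPLATES)))]
            else:
                rid = config.rule_mix[int(rng.integers(len(config.rule_mix)))]
                tpl = _RULE_TEMPLATES[rid]
            add(tpl, names, True)
        for _ in range(n_neg):
            add(neg_template(rng), names, False)

    # negative relations
    if config.negative_multiplicities is not None:
        neg_mult = list(config.negative_multiplicities)
    else:
        neg_mult = [1 + int(rng.poisson(0.7)) for _ in range(config.n_negative_relations)]
    for n in neg_mult:
        names = fresh_pair()
        for _ in range(n):
            add(neg_template(rng), names, False)

    return SyntheticCorpus(sentences=sentences, trees=trees, config=config)


def perfect_and_degraded_predictions(
    corpus: SyntheticCorpus,
    *,
    flip_positive_rate: float = 0.0,
    flip_negative_rate: float = 0.0,
    seed: int = 0,
) -> list[Prediction]:
    """Gold labels pushed through a label-flipping channel.

    ``flip_positive_rate`` is the probability a gold-positive instance
    is predicted negative (and vice versa); both 0 yields the perfect
    predictor.
    """
    rng = np.random.default_rng(seed)
    out = []
    for s in corpus.sentences:
        for pair, gold in sorted(s.gold_pairs.items(), key=lambda kv: sorted(kv[0])):
            a, b = sorted(pair)
            label = bool(gold)
            flip = flip_positive_rate if gold else flip_negative_rate
            if flip and rng.random() < flip:
                label = not label
            out.append(
                Prediction(
                    sentence_id=s.sentence_id,
                    mention_a=a,
                    mention_b=b,
                    entity_key_a=s.mention(a).entity_key,
                    entity_key_b=s.mention(b).entity_key,
                    label=label,
                )
            )
    return out
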