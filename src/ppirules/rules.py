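"""The eight-rule high-precision PPI classifier.

Each candidate protein pair in a sentence is tested against eight
lexical/syntactic rules in ascending order; the first matching rule
labels the pair positive, otherwise the pair is negative.  Rules 1-4
and 6 pattern-match the collapsed-Stanford dependency graph, Rules 5,
7 and 8 are pure token-sequence patterns and run even when no parse is
available.  Negation (a ``neg`` edge on the relation word, its subject,
or its governing verb, depending on the rule) vetoes a structural
match; vetoed matches are recorded so callers can audit them.

Rule inventory (P = protein mask, REL = lexicon keyword):

1. ``P_i - REL - P_j``: subject-verb-object/prepositional pattern.
2. ``REL - of - P_i - PREP - P_j``: nominal keyword, e.g.
   "binding of P0 to P1".
3. ``REL - {between, of} - P_i - and - P_j``: keyword over a protein
   conjunction, e.g. "interaction between P0 and P1".
4. ``P_i - and - P_j - REL``: protein conjunction as subject of a
   keyword verb; rejected when the verb has a dobj/prep argument,
   except "form ... complex".
5. ``P_i {-,/} P_j {interaction, complex, heterodimer, product,
   assembly}``: lexical compound pattern.
6. ``P_i VERB {receptor, ligand, substrate, binding protein}
   {for, of} P_j``: predicative binding-role pattern.
7. ``P_i {receptor, ligand, substrate, binding protein} ( P_j )``:
   apposition in parentheses, e.g. "erythropoietin receptor (EPOR)".
8. ``P_i {binding domain, binding site} {in, within, on, of} P_j``:
   binding-region pattern, e.g. "CD30L binding domain on ... CD30".

High precision comes from the keyword lexicon, the negation vetoes, and
two locality constraints applied to the syntactic rules 1-4: the pair
must lie within a seven-word surface window and at most three
dependency-bearing words may occur between the proteins.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from typing import IO, Iterable, Sequence

from ppirules.corpus import AnnotatedSentence, CandidatePair, enumerate_candidates
from ppirules.deps import (
    DepTree,
    dependents,
    governing_verb,
    has_negation,
    intervening_dep_words,
)
from ppirules.errors import ClassificationError, ConfigError
from ppirules.lexicon import KeywordMatch, RelationLexicon, load_default_lexicon, match_keyword

logger = logging.getLogger(__name__)

RULE_IDS = (1, 2, 3, 4, 5, 6, 7, 8)

#: head nouns of the Rule 5 compound pattern
RULE5_NOUNS = frozenset({"interaction", "complex", "heterodimer", "product", "assembly"})
#: binding-role cue nouns of Rules 6 and 7
ROLE_NOUNS = frozenset({"receptor", "ligand", "substrate"})
#: prepositions accepted by Rule 6
RULE6_PREPS = ("prep_for", "prep_of")
#: prepositions accepted by Rule 8
RULE8_PREPS = frozenset({"in", "within", "on", "of"})
#: second-slot prepositions accepted by Rule 2 (precision-first whitelist)
RULE2_PREPS = frozenset({"to", "by", "with", "on", "for"})


@dataclass(frozen=True)
class RuleConfig:
    """Tunable constraints of the rule engine.

    ``window_tokens`` is the maximum surface span (both proteins
    inclusive) for the syntactic rules and Rule 8; ``max_dep_words``
    caps the dependency-bearing words between the proteins for Rules
    1-4.  ``rule2_wildcard_prep`` lifts the second-slot preposition
    whitelist of Rule 2; ``rule6_copula_only`` restricts Rule 6 to
    copular constructions.
    """

    window_tokens: int = 7
    max_dep_words: int = 3
    rule4_form_requires_complex: bool = True
    enabled_rules: tuple = RULE_IDS
    rule2_wildcard_prep: bool = False
    rule6_copula_only: bool = False

    def __post_init__(self) -> None:
        if self.window_tokens < 2:
            raise ConfigError("window_tokens must be >= 2")
        if self.max_dep_words < 0:
            raise ConfigError("max_dep_words must be >= 0")
        bad = set(self.enabled_rules) - set(RULE_IDS)
        if bad:
            raise ConfigError(f"unknown rule ids {sorted(bad)}")


@dataclass
class MatchResult:
    """Outcome of testing one candidate pair.

    ``negated`` means a rule's structural pattern matched but a
    negation cue vetoed it.  ``trace`` lists the satisfied conditions
    in order, for auditability.
    """

    matched: bool
    rule_id: int | None = None
    trigger: KeywordMatch | str | None = None
    negated: bool = False
    trace: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.matched:
            assert self.rule_id is not None and not self.negated


@dataclass(frozen=True)
class Prediction:
    """Per-pair output row (the predictions TSV schema)."""

    sentence_id: str
    mention_a: str
    mention_b: str
    entity_key_a: str
    entity_key_b: str
    label: bool
    rule_id: int | None = None
    trigger_lemma: str | None = None
    negated: bool = False

    @property
    def instance_key(self) -> tuple:
        return (self.sentence_id, frozenset((self.mention_a, self.mention_b)))

    @property
    def relation_key(self) -> tuple:
        return tuple(sorted((self.entity_key_a, self.entity_key_b)))


# ---------------------------------------------------------------------------
# shared helpers
# ---------------------------------------------------------------------------

def _pair_indices(pair: CandidatePair, sentence: AnnotatedSentence) -> tuple[int, int]:
    return (
        sentence.mention_token_index(pair.first),
        sentence.mention_token_index(pair.second),
    )


def _is_verbish(tree: DepTree, idx: int) -> bool:
    pos = tree.tokens[idx].coarse_pos
    return pos in ("VERB", "AUX") or pos == ""


def _is_nounish(tree: DepTree, idx: int) -> bool:
    pos = tree.tokens[idx].coarse_pos
    return pos in ("NOUN", "PROPN") or pos == ""


def _keyword_tokens(tree: DepTree, lexicon: RelationLexicon) -> list[KeywordMatch]:
    out = []
    for t in tree.tokens:
        if t.is_protein:
            continue
        km = match_keyword(t, lexicon)
        if km is not None:
            out.append(km)
    return out


def _locality_ok(
    res_trace: list,
    pair: CandidatePair,
    tree: DepTree,
    ti: int,
    tj: int,
    config: RuleConfig,
    *,
    dep_words: bool = True,
) -> bool:
    if pair.surface_span_tokens > config.window_tokens:
        res_trace.append(
            f"vetoed: span {pair.surface_span_tokens} > window {config.window_tokens}"
        )
        return False
    if dep_words:
        n = intervening_dep_words(tree, ti, tj)
        if n > config.max_dep_words:
            res_trace.append(
                f"vetoed: {n} dependency-bearing words > max {config.max_dep_words}"
            )
            return False
    return True


def _neg_on(tree: DepTree, *nodes: int | None) -> bool:
    return any(n is not None and has_negation(tree, n) for n in nodes)


# ---------------------------------------------------------------------------
# the eight rules
# ---------------------------------------------------------------------------

def rule1(
    pair: CandidatePair,
    sentence: AnnotatedSentence,
    tree: DepTree,
    config: RuleConfig,
    lexicon: RelationLexicon,
) -> MatchResult:
    """``P_i - REL - P_j``: subject + keyword verb + dobj/prep object."""
    ti, tj = _pair_indices(pair, sentence)
    for km in _keyword_tokens(tree, lexicon):
        v = km.token_index
        if not _is_verbish(tree, v):
            continue
        subs = {t.index for t in dependents(tree, v, "nsubj")}
        objs = {t.index for t in dependents(tree, v, "dobj")}
        objs |= {t.index for t in dependents(tree, v, "prep_*")}
        for a, b in ((ti, tj), (tj, ti)):
            if a in subs and b in objs:
                trace = [f"rule1: {km.lemma!r} nsubj={a} obj={b}"]
                if _neg_on(tree, v, a):
                    trace.append("vetoed: negation on verb or subject")
                    return MatchResult(False, negated=True, trigger=km, trace=trace)
                if not _locality_ok(trace, pair, tree, ti, tj, config):
                    return MatchResult(False, trigger=km, trace=trace)
                return MatchResult(True, rule_id=1, trigger=km, trace=trace)
    return MatchResult(False)


def rule2(
    pair: CandidatePair,
    sentence: AnnotatedSentence,
    tree: DepTree,
    config: RuleConfig,
    lexicon: RelationLexicon,
) -> MatchResult:
    """``REL - of - P_i - PREP - P_j``: nominal keyword with two preps."""
    ti, tj = _pair_indices(pair, sentence)
    for km in _keyword_tokens(tree, lexicon):
        n = km.token_index
        if not _is_nounish(tree, n):
            continue
        of_deps = {t.index for t in dependents(tree, n, "prep_of")}
        others = set()
        for e in tree.out_edges(n):
            if not e.label.startswith("prep_") or e.label == "prep_of":
                continue
            prep = e.label[len("prep_") :]
            if config.rule2_wildcard_prep or prep in RULE2_PREPS:
                others.add(e.dependent)
        for a, b in ((ti, tj), (tj, ti)):
            if a in of_deps and b in others:
                trace = [f"rule2: {km.lemma!r} prep_of={a} prep_x={b}"]
                if _neg_on(tree, n, governing_verb(tree, n)):
                    trace.append("vetoed: negation on keyword or governing verb")
                    return MatchResult(False, negated=True, trigger=km, trace=trace)
                if not _locality_ok(trace, pair, tree, ti, tj, config):
                    return MatchResult(False, trigger=km, trace=trace)
                return MatchResult(True, rule_id=2, trigger=km, trace=trace)
    return MatchResult(False)


def rule3(
    pair: CandidatePair,
    sentence: AnnotatedSentence,
    tree: DepTree,
    config: RuleConfig,
    lexicon: RelationLexicon,
) -> MatchResult:
    """``REL - {between, of} - P_i - and - P_j``: keyword over a conjunction."""
    ti, tj = _pair_indices(pair, sentence)
    for km in _keyword_tokens(tree, lexicon):
        n = km.token_index
        reach = {t.index for t in dependents(tree, n, "prep_between")}
        reach |= {t.index for t in dependents(tree, n, "prep_of")}
        conj_ok = False
        if ti in reach and tj in reach:
            conj_ok = True  # both reached via the collapsed/propagated prep
        else:
            for a, b in ((ti, tj), (tj, ti)):
                if a in reach and b in {t.index for t in dependents(tree, a, "conj_and")}:
                    conj_ok = True
                    break
        if not conj_ok:
            continue
        trace = [f"rule3: {km.lemma!r} links {ti} and {tj}"]
        if _neg_on(tree, n, governing_verb(tree, n)):
            trace.append("vetoed: negation on keyword or governing verb")
            return MatchResult(False, negated=True, trigger=km, trace=trace)
        if not _locality_ok(trace, pair, tree, ti, tj, config):
            return MatchResult(False, trigger=km, trace=trace)
        return MatchResult(True, rule_id=3, trigger=km, trace=trace)
    return MatchResult(False)


def rule4(
    pair: CandidatePair,
    sentence: AnnotatedSentence,
    tree: DepTree,
    config: RuleConfig,
    lexicon: RelationLexicon,
) -> MatchResult:
    """``P_i - and - P_j - REL``: protein conjunction as keyword subject."""
    ti, tj = _pair_indices(pair, sentence)
    ti_conj = {t.index for t in dependents(tree, ti, "conj_and")}
    tj_conj = {t.index for t in dependents(tree, tj, "conj_and")}
    if tj not in ti_conj and ti not in tj_conj:
        return MatchResult(False)
    for km in _keyword_tokens(tree, lexicon):
        v = km.token_index
        if not _is_verbish(tree, v):
            continue
        subs = {t.index for t in dependents(tree, v, "nsubj")}
        if not (ti in subs or tj in subs):
            continue
        trace = [f"rule4: conjunction ({ti}, {tj}) nsubj of {km.lemma!r}"]
        offenders = [
            e
            for e in tree.out_edges(v)
            if e.label == "dobj" or e.label.startswith("prep_")
        ]
        if offenders:
            exempt = (
                config.rule4_form_requires_complex
                and km.lemma == "form"
                and all(
                    e.label == "dobj"
                    and tree.tokens[e.dependent].lemma.lower() == "complex"
                    for e in offenders
                )
            )
            if not exempt:
                trace.append("rejected: keyword has dobj/prep_* dependency")
                continue
            trace.append("form/complex exception applies")
        if _neg_on(tree, v, ti, tj):
            trace.append("vetoed: negation on verb or subject")
            return MatchResult(False, negated=True, trigger=km, trace=trace)
        if not _locality_ok(trace, pair, tree, ti, tj, config):
            return MatchResult(False, trigger=km, trace=trace)
        return MatchResult(True, rule_id=4, trigger=km, trace=trace)
    return MatchResult(False)


def rule5(
    pair: CandidatePair,
    sentence: AnnotatedSentence,
    tree: DepTree | None,
    config: RuleConfig,
    lexicon: RelationLexicon,
) -> MatchResult:
    """``P_i {-,/} P_j NOUN``: compound pattern ("P0-P1 complex")."""
    ti, tj = _pair_indices(pair, sentence)
    lo, hi = min(ti, tj), max(ti, tj)
    toks = sentence.tokens
    if hi != lo + 2 or toks[lo + 1] not in ("-", "/"):
        return MatchResult(False)
    if hi + 1 >= len(toks):
        return MatchResult(False)
    head = toks[hi + 1].lower()
    if head.rstrip("s") not in RULE5_NOUNS and head not in RULE5_NOUNS:
        return MatchResult(False)
    trace = [f"rule5: {toks[lo]} {toks[lo + 1]} {toks[hi]} {head}"]
    if tree is not None and _neg_on(tree, hi + 1, governing_verb(tree, hi + 1)):
        trace.append("vetoed: negation on head noun or governing verb")
        return MatchResult(False, negated=True, trigger=head, trace=trace)
    return MatchResult(True, rule_id=5, trigger=head, trace=trace)


def _role_cues(tokens: Sequence[str]) -> list[tuple[int, str]]:
    """(index of cue head token, cue string) for role nouns incl. 'binding protein'."""
    cues = []
    for i, t in enumerate(tokens):
        low = t.lower()
        if low in ROLE_NOUNS:
            cues.append((i, low))
        elif low == "protein" and i > 0 and tokens[i - 1].lower() == "binding":
            cues.append((i, "binding protein"))
    return cues


def rule6(
    pair: CandidatePair,
    sentence: AnnotatedSentence,
    tree: DepTree,
    config: RuleConfig,
    lexicon: RelationLexicon,
) -> MatchResult:
    """``P_i VERB ROLE {for, of} P_j``: predicative binding-role pattern."""
    ti, tj = _pair_indices(pair, sentence)
    for n, cue in _role_cues(sentence.tokens):
        targets: set[int] = set()
        for lbl in RULE6_PREPS:
            targets |= {t.index for t in dependents(tree, n, lbl)}
        subs = {t.index for t in dependents(tree, n, "nsubj")}
        has_cop = bool(dependents(tree, n, "cop"))
        verbs = [
            v.index
            for v in tree.tokens
            if _is_verbish(tree, v.index) and n in {
                d.index
                for lbl in ("dobj", "attr", "xcomp", "acomp")
                for d in dependents(tree, v.index, lbl)
            }
        ]
        for a, b in ((ti, tj), (tj, ti)):
            linked_verb: int | None = None
            if a in subs and (has_cop or not config.rule6_copula_only):
                subject_ok = True
            else:
                subject_ok = False
                if not config.rule6_copula_only:
                    for v in verbs:
                        if a in {t.index for t in dependents(tree, v, "nsubj")}:
                            subject_ok = True
                            linked_verb = v
                            break
            if subject_ok and b in targets:
                trace = [f"rule6: subject {a}, {cue!r}, prep target {b}"]
                if _neg_on(tree, n, linked_verb, a):
                    trace.append("vetoed: negation on cue noun, verb or subject")
                    return MatchResult(False, negated=True, trigger=cue, trace=trace)
                return MatchResult(True, rule_id=6, trigger=cue, trace=trace)
    return MatchResult(False)


def rule7(
    pair: CandidatePair,
    sentence: AnnotatedSentence,
    tree: DepTree | None,
    config: RuleConfig,
    lexicon: RelationLexicon,
) -> MatchResult:
    """``P_i ROLE ( P_j )``: parenthetical apposition ("EPO receptor (EPOR)")."""
    ti, tj = _pair_indices(pair, sentence)
    lo, hi = min(ti, tj), max(ti, tj)
    toks = sentence.tokens
    for cue_end, cue in _role_cues(toks):
        cue_start = cue_end - (1 if cue == "binding protein" else 0)
        if cue_start != lo + 1:
            continue
        if (
            cue_end + 3 < len(toks)
            and toks[cue_end + 1] == "("
            and hi == cue_end + 2
            and toks[cue_end + 3] == ")"
        ):
            return MatchResult(
                True,
                rule_id=7,
                trigger=cue,
                trace=[f"rule7: {toks[lo]} {cue} ( {toks[hi]} )"],
            )
    return MatchResult(False)


def rule8(
    pair: CandidatePair,
    sentence: AnnotatedSentence,
    tree: DepTree | None,
    config: RuleConfig,
    lexicon: RelationLexicon,
) -> MatchResult:
    """``P_i {binding domain, binding site} {in, within, on, of} P_j``."""
    ti, tj = _pair_indices(pair, sentence)
    lo, hi = min(ti, tj), max(ti, tj)
    toks = sentence.tokens
    if lo + 3 >= len(toks):
        return MatchResult(False)
    if toks[lo + 1].lower() != "binding" or toks[lo + 2].lower() not in ("domain", "site"):
        return MatchResult(False)
    if toks[lo + 3].lower() not in RULE8_PREPS:
        return MatchResult(False)
    if hi <= lo + 3 or pair.surface_span_tokens > config.window_tokens:
        return MatchResult(False)
    cue = f"binding {toks[lo + 2].lower()}"
    return MatchResult(
        True,
        rule_id=8,
        trigger=cue,
        trace=[f"rule8: {toks[lo]} {cue} {toks[lo + 3]} ... {toks[hi]}"],
    )


_RULES = {1: rule1, 2: rule2, 3: rule3, 4: rule4, 5: rule5, 6: rule6, 7: rule7, 8: rule8}
_LEXICAL_RULES = frozenset({5, 7, 8})

_default_lexicon: RelationLexicon | None = None


def _lexicon(lexicon: RelationLexicon | None) -> RelationLexicon:
    global _default_lexicon
    if lexicon is not None:
        return lexicon
    if _default_lexicon is None:
        _default_lexicon = load_default_lexicon()
    return _default_lexicon


# ---------------------------------------------------------------------------
# the classifier
# ---------------------------------------------------------------------------

def classify_pair(
    pair: CandidatePair,
    sentence: AnnotatedSentence,
    tree: DepTree | None,
    config: RuleConfig | None = None,
    lexicon: RelationLexicon | None = None,
    *,
    rule_order: Sequence[int] | None = None,
) -> MatchResult:
    """Apply the rules in ascending id order; first match wins.

    Without a dependency tree only the lexical rules (5, 7, 8) run; a
    candidate that no rule matches is negative, which is also the
    fallback for unclassifiable instances.  Pairs of co-referent
    mentions (same entity key) are never positive.
    """
    config = config or RuleConfig()
    lexicon = _lexicon(lexicon)
    if pair.is_self_relation:
        return MatchResult(False, trace=["self-relation pair: never positive"])
    order = rule_order if rule_order is not None else sorted(config.enabled_rules)
    negated = False
    traces: list = []
    for rid in order:
        if rid not in config.enabled_rules:
            continue
        if tree is None and rid not in _LEXICAL_RULES:
            continue
        res = _RULES[rid](pair, sentence, tree, config, lexicon)
        if res.matched:
            return res
        if res.trace:
            traces.extend(res.trace)
        negated = negated or res.negated
    return MatchResult(False, negated=negated, trace=traces)


def classify_sentence(
    sentence: AnnotatedSentence,
    tree: DepTree | None,
    config: RuleConfig | None = None,
    lexicon: RelationLexicon | None = None,
) -> list[Prediction]:
    """Classify every candidate pair of one sentence."""
    preds = []
    if not sentence.is_candidate:
        return preds
    if tree is None:
        logger.info(
            "sentence %s: no dependency tree; only lexical rules applied",
            sentence.sentence_id,
        )
    for pair in enumerate_candidates(sentence):
        res = classify_pair(pair, sentence, tree, config, lexicon)
        trig = res.trigger.lemma if isinstance(res.trigger, KeywordMatch) else res.trigger
        preds.append(
            Prediction(
                sentence_id=sentence.sentence_id,
                mention_a=pair.first.mention_id,
                mention_b=pair.second.mention_id,
                entity_key_a=pair.first.entity_key,
                entity_key_b=pair.second.entity_key,
                label=res.matched,
                rule_id=res.rule_id,
                trigger_lemma=trig,
                negated=res.negated,
            )
        )
    return preds


def classify_corpus(
    sentences: Iterable[AnnotatedSentence],
    trees: dict[str, DepTree],
    config: RuleConfig | None = None,
    lexicon: RelationLexicon | None = None,
) -> list[Prediction]:
    out = []
    for s in sentences:
        out.extend(classify_sentence(s, trees.get(s.sentence_id), config, lexicon))
    return out


# ---------------------------------------------------------------------------
# predictions TSV
# ---------------------------------------------------------------------------

_TSV_COLUMNS = (
    "sentence_id",
    "mention_a",
    "mention_b",
    "entity_key_a",
    "entity_key_b",
    "label",
    "rule_id",
    "trigger_lemma",
    "negated",
)


def write_predictions(predictions: Iterable[Prediction], stream: IO) -> None:
    writer = csv.writer(stream, delimiter="\t", lineterminator="\n")
    writer.writerow(_TSV_COLUMNS)
    for p in predictions:
        writer.writerow(
            [
                p.sentence_id,
                p.mention_a,
                p.mention_b,
                p.entity_key_a,
                p.entity_key_b,
                "positive" if p.label else "negative",
                p.rule_id if p.rule_id is not None else "",
                p.trigger_lemma or "",
                int(p.negated),
            ]
        )


def read_predictions(stream: IO) -> list[Prediction]:
    reader = csv.reader(stream, delimiter="\t")
    header = next(reader, None)
    if header is None or tuple(header) != _TSV_COLUMNS:
        raise ClassificationError("predictions TSV header mismatch")
    out = []
    for row in reader:
        if not row:
            continue
        out.append(
            Prediction(
                sentence_id=row[0],
                mention_a=row[1],
                mention_b=row[2],
                entity_key_a=row[3],
                entity_key_b=row[4],
                label=row[5] == "positive",
                rule_id=int(row[6]) if row[6] else None,
                trigger_lemma=row[7] or None,
                negated=bool(int(row[8])) if row[8] else False,
            )
        )
    return out
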