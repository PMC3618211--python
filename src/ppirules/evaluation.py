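"""Per-instance and per-relation precision/recall/F evaluation.

An *instance* is one candidate protein pair in one sentence; a
*relation* is the corpus-wide distinct protein pair (by normalized
entity keys), aggregating all its instances.  Conventional per-instance
scoring counts correctly predicted instances.  Per-relation scoring
counts correctly predicted distinct pairs, under the simple aggregation
strategy that a single predicted-positive instance makes the relation
predicted positive (and a single gold-positive instance makes it gold
positive).

Precision = TP/(TP+FP), Recall = TP/(TP+FN) and
F = 2*P*R/(P+R), with the 0/0 convention that a metric is 0 when its
denominator is 0.  Corpora can be stratified by MIpR -- the minimum
number of instances per relation -- optionally requiring gold-positive
relations to also have at least k gold-positive instances.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from ppirules.corpus import AnnotatedSentence
from ppirules.errors import CorpusIntegrityError
from ppirules.rules import Prediction


def relation_key(entity_key_a: str, entity_key_b: str) -> tuple:
    """Canonical (lexicographically sorted) identity of a protein pair."""
    return tuple(sorted((entity_key_a, entity_key_b)))


@dataclass(frozen=True)
class LabeledInstance:
    """A gold-labeled instance joined with its predicted label."""

    sentence_id: str
    mention_pair: frozenset
    relation: tuple
    gold: bool
    pred: bool = False


@dataclass(frozen=True)
class EvalCounts:
    tp: int
    fp: int
    fn: int
    level: str = "instance"

    def __post_init__(self) -> None:
        assert self.tp >= 0 and self.fp >= 0 and self.fn >= 0


@dataclass(frozen=True)
class EvalResult:
    counts: EvalCounts
    precision: float
    recall: float
    f_score: float

    @classmethod
    def from_counts(cls, counts: EvalCounts) -> "EvalResult":
        p = precision(counts.tp, counts.fp)
        r = recall(counts.tp, counts.fn)
        return cls(counts, p, r, f_score(p, r))


def precision(tp: int, fp: int) -> float:
    return tp / (tp + fp) if tp + fp else 0.0


def recall(tp: int, fn: int) -> float:
    return tp / (tp + fn) if tp + fn else 0.0


def f_score(p: float, r: float) -> float:
    return 2 * p * r / (p + r) if p + r else 0.0


@dataclass(frozen=True)
class MIpRFilter:
    """Stratification by minimum instances per relation.

    Keeps a relation (and all its instances) iff it has at least ``k``
    instances; with ``require_k_positive_instances`` a gold-positive
    relation must additionally have at least ``k`` gold-positive
    instances.  ``k=1`` is the identity filter.
    """

    k: int = 1
    require_k_positive_instances: bool = True

    def __post_init__(self) -> None:
        assert self.k >= 1


# ---------------------------------------------------------------------------
# joining gold and predictions
# ---------------------------------------------------------------------------

def gold_instances(sentences: Iterable[AnnotatedSentence]) -> list[LabeledInstance]:
    """All gold-labeled candidate-pair instances of a corpus (pred=False)."""
    out = []
    for s in sentences:
        for pair, label in sorted(s.gold_pairs.items(), key=lambda kv: sorted(kv[0])):
            a, b = sorted(pair)
            rel = relation_key(s.mention(a).entity_key, s.mention(b).entity_key)
            out.append(
                LabeledInstance(
                    sentence_id=s.sentence_id,
                    mention_pair=frozenset(pair),
                    relation=rel,
                    gold=bool(label),
                )
            )
    return out


def join_predictions(
    gold: Sequence[LabeledInstance], predictions: Iterable[Prediction]
) -> list[LabeledInstance]:
    """Attach predicted labels to gold instances.

    A prediction without a gold counterpart is an input-mismatch error;
    a gold instance without a prediction counts as predicted negative.
    """
    by_key = {(g.sentence_id, g.mention_pair): i for i, g in enumerate(gold)}
    pred_labels: dict[int, bool] = {}
    for p in predictions:
        key = p.instance_key
        if key not in by_key:
            raise CorpusIntegrityError(
                f"prediction for unknown instance {key!r} (no gold counterpart)"
            )
        idx = by_key[key]
        pred_labels[idx] = pred_labels.get(idx, False) or p.label
    return [
        LabeledInstance(
            g.sentence_id, g.mention_pair, g.relation, g.gold, pred_labels.get(i, False)
        )
        for i, g in enumerate(gold)
    ]


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def per_instance_eval(instances: Sequence[LabeledInstance]) -> EvalResult:
    """Conventional instance-level precision/recall/F."""
    tp = sum(1 for i in instances if i.pred and i.gold)
    fp = sum(1 for i in instances if i.pred and not i.gold)
    fn = sum(1 for i in instances if not i.pred and i.gold)
    return EvalResult.from_counts(EvalCounts(tp, fp, fn, level="instance"))


def aggregate_relations(
    instances: Sequence[LabeledInstance],
) -> dict[tuple, tuple[bool, bool]]:
    """Relation-level (gold, predicted) labels.

    One gold-positive instance makes the relation gold positive; one
    predicted-positive instance makes it predicted positive.  Invariant
    to instance order and mention-pair orientation by construction.
    """
    agg: dict[tuple, tuple[bool, bool]] = {}
    for inst in instances:
        g, p = agg.get(inst.relation, (False, False))
        agg[inst.relation] = (g or inst.gold, p or inst.pred)
    return agg


def per_relation_eval(instances: Sequence[LabeledInstance]) -> EvalResult:
    """Relation-level precision/recall/F over distinct protein pairs."""
    agg = aggregate_relations(instances)
    tp = sum(1 for g, p in agg.values() if p and g)
    fp = sum(1 for g, p in agg.values() if p and not g)
    fn = sum(1 for g, p in agg.values() if not p and g)
    return EvalResult.from_counts(EvalCounts(tp, fp, fn, level="relation"))


def filter_mipr(
    instances: Sequence[LabeledInstance], flt: MIpRFilter
) -> list[LabeledInstance]:
    """Keep only relations passing the MIpR stratum.

    Negative relations are filtered on total instance count alone;
    gold-positive relations additionally require ``k`` gold-positive
    instances when the filter demands it.
    """
    totals: dict[tuple, int] = {}
    positives: dict[tuple, int] = {}
    for inst in instances:
        totals[inst.relation] = totals.get(inst.relation, 0) + 1
        if inst.gold:
            positives[inst.relation] = positives.get(inst.relation, 0) + 1
    keep = set()
    for rel, n in totals.items():
        if n < flt.k:
            continue
        npos = positives.get(rel, 0)
        if npos > 0 and flt.require_k_positive_instances and npos < flt.k:
            continue
        keep.add(rel)
    return [i for i in instances if i.relation in keep]


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def evaluate_all(
    instances: Sequence[LabeledInstance],
) -> dict[str, EvalResult]:
    return {
        "relation": per_relation_eval(instances),
        "instance": per_instance_eval(instances),
    }


def pooled_report(
    results: dict[tuple[str, int], dict[str, EvalResult]]
) -> str:
    """Fixed-width comparison table over (system, MIpR) strata.

    ``results`` maps (system name, k) to the dict produced by
    :func:`evaluate_all`.  Empty strata render as dashes.  Metrics are
    printed to 3 decimals (round-half-even).
    """
    rows = []
    for (system, k), res in sorted(results.items(), key=lambda kv: (kv[0][1], kv[0][0])):
        row: dict[str, object] = {"MIpR": k, "system": system}
        for level_name, short in (("relation", "rel"), ("instance", "inst")):
            r = res.get(level_name)
            if r is None or (r.counts.tp + r.counts.fp + r.counts.fn) == 0:
                row.update({f"{short}_{c}": "-" for c in ("TP", "FP", "P", "R", "F")})
            else:
                row.update(
                    {
                        f"{short}_TP": r.counts.tp,
                        f"{short}_FP": r.counts.fp,
                        f"{short}_P": f"{r.precision:.3f}",
                        f"{short}_R": f"{r.recall:.3f}",
                        f"{short}_F": f"{r.f_score:.3f}",
                    }
                )
        rows.append(row)
    df = pd.DataFrame(rows)
    return df.to_string(index=False)


def result_to_dict(result: EvalResult) -> dict:
    return {
        "level": result.counts.level,
        "tp": result.counts.tp,
        "fp": result.counts.fp,
        "fn": result.counts.fn,
        "precision": round(result.precision, 6),
        "recall": round(result.recall, 6),
        "f_score": round(result.f_score, 6),
    }
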