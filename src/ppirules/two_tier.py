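"""Two-tier classifier pipelining and dependency-chain features.

A two-tier extractor runs a first classifier over all instances and
re-screens only the instances the first tier rejected with a second
classifier; positives of either tier are final positives.  Pipelining
therefore never flips a tier-1 positive to negative, and the positive
set is the union of tier-1 positives and tier-2 positives among tier-1
negatives.  Either tier can be the rule engine, a fitted model, a file
of precomputed labels from an external system, or any object satisfying
the classifier contract.

For machine-learned tiers the module implements dependency-chain
features: the *forward* chain is the path from the tree root to the
first protein and the *backward* chain the path to the second protein;
(label, lemma) bigrams along each chain are the base features, with the
top-n bigrams per direction selected by the difference between their
forward- and backward-chain occurrence counts.  Optional extras are the
two chain lengths and the surface token distance between the proteins.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass
from typing import IO, Iterable, Protocol, Sequence, runtime_checkable

import numpy as np

from ppirules.corpus import AnnotatedSentence, CandidatePair
from ppirules.deps import DepTree
from ppirules.lexicon import RelationLexicon
from ppirules.rules import Prediction, RuleConfig, classify_pair

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# instances and the classifier contract
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExtractionInstance:
    """One candidate pair with everything a tier may need."""

    sentence: AnnotatedSentence
    pair: CandidatePair
    tree: DepTree | None = None

    @property
    def instance_key(self) -> tuple:
        return (self.sentence.sentence_id, self.pair.mention_ids)


@runtime_checkable
class ClassifierContract(Protocol):
    """Anything with a name, fit() and a deterministic predict()."""

    name: str

    def fit(self, instances: Sequence[ExtractionInstance], labels: Sequence[bool]) -> None:
        ...

    def predict(self, instance: ExtractionInstance) -> bool:
        ...


class RuleTier:
    """The rule engine as a tier (ignores fit)."""

    def __init__(
        self,
        config: RuleConfig | None = None,
        lexicon: RelationLexicon | None = None,
        name: str = "rules",
    ) -> None:
        self.name = name
        self.config = config
        self.lexicon = lexicon

    def fit(self, instances, labels) -> None:  # rule-based: nothing to fit
        return None

    def predict(self, instance: ExtractionInstance) -> bool:
        return classify_pair(
            instance.pair, instance.sentence, instance.tree, self.config, self.lexicon
        ).matched


class AlwaysNegative:
    """Degenerate tier; pipelining with it reduces to the other tier."""

    name = "always-negative"

    def fit(self, instances, labels) -> None:
        return None

    def predict(self, instance: ExtractionInstance) -> bool:
        return False


class ExternalLabelTier:
    """Precomputed labels (e.g. another system's predictions TSV).

    Splices third-party outputs into a tier without reimplementing the
    system.  Instances absent from the label table are negative.
    """

    def __init__(self, predictions: Iterable[Prediction], name: str = "external") -> None:
        self.name = name
        self._labels = {p.instance_key: p.label for p in predictions}

    def fit(self, instances, labels) -> None:
        return None

    def predict(self, instance: ExtractionInstance) -> bool:
        return self._labels.get(instance.instance_key, False)


@dataclass(frozen=True)
class TieredPrediction:
    instance: ExtractionInstance
    label: bool
    tier: str  # name of the tier that produced the final label


def pipeline(
    tier1: ClassifierContract,
    tier2: ClassifierContract,
    instances: Sequence[ExtractionInstance],
) -> list[TieredPrediction]:
    """Run tier1 over all instances, tier2 over tier1's rejections.

    Every instance is labeled exactly once; provenance records which
    tier produced the final label.  If tier2 fails on an instance the
    instance inherits the tier-1 label (logged).
    """
    out = []
    for inst in instances:
        label1 = tier1.predict(inst)
        if label1:
            out.append(TieredPrediction(inst, True, tier1.name))
            continue
        try:
            label2 = tier2.predict(inst)
        except Exception:  # tier failure: inherit tier-1 label
            logger.warning(
                "tier %r failed on instance %r; keeping tier-1 label",
                tier2.name,
                inst.instance_key,
                exc_info=True,
            )
            label2 = label1
        out.append(TieredPrediction(inst, label2, tier2.name if label2 else tier1.name))
    return out


def tiered_to_predictions(tiered: Iterable[TieredPrediction]) -> list[Prediction]:
    return [
        Prediction(
            sentence_id=t.instance.sentence.sentence_id,
            mention_a=t.instance.pair.first.mention_id,
            mention_b=t.instance.pair.second.mention_id,
            entity_key_a=t.instance.pair.first.entity_key,
            entity_key_b=t.instance.pair.second.entity_key,
            label=t.label,
            trigger_lemma=None,
        )
        for t in tiered
    ]


# ---------------------------------------------------------------------------
# dependency chains
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DepChain:
    """Root-to-protein path; elements are (dependency label, token lemma).

    ``complete`` is False when the protein token is disconnected from
    the root over non-propagated edges.
    """

    direction: str  # "forward" (first protein) or "backward" (second)
    elements: tuple
    complete: bool = True

    def __len__(self) -> int:
        return len(self.elements)


def _root_path(tree: DepTree, target: int) -> tuple[list[tuple[str, str]], bool]:
    parents = {
        e.dependent: (e.head, e.label) for e in tree.edges if not e.propagated
    }
    steps: list[tuple[str, str]] = []
    cur = target
    seen = set()
    while cur != tree.root:
        if cur in seen or cur not in parents:
            return [], False
        seen.add(cur)
        head, label = parents[cur]
        steps.append((label, tree.tokens[cur].lemma))
        cur = head
    steps.reverse()
    return steps, True


def extract_chains(tree: DepTree, pair: CandidatePair) -> tuple[DepChain, DepChain]:
    """Forward (root -> first protein) and backward (root -> second) chains."""
    fwd_steps, fwd_ok = _root_path(tree, tree.protein_index(pair.first.mask_label))
    bwd_steps, bwd_ok = _root_path(tree, tree.protein_index(pair.second.mask_label))
    if not fwd_ok or not bwd_ok:
        logger.warning(
            "tree %s: disconnected protein token; empty chain emitted", tree.sentence_id
        )
    return (
        DepChain("forward", tuple(fwd_steps), fwd_ok),
        DepChain("backward", tuple(bwd_steps), bwd_ok),
    )


def render_element(element: tuple[str, str], mode: str = "both") -> str:
    label, lemma = element
    if mode == "label":
        return label
    if mode == "lemma":
        return lemma
    return f"{label}/{lemma}"


def chain_bigrams(chain: DepChain, mode: str = "both") -> list[tuple[str, str]]:
    """Adjacent-element pairs of a chain; fewer than 2 elements -> []."""
    rendered = [render_element(e, mode) for e in chain.elements]
    return list(zip(rendered, rendered[1:]))


# ---------------------------------------------------------------------------
# feature selection and featurization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureSpec:
    """Frozen feature layout for a fitted two-tier ML tier.

    Bigram slots come first (forward then backward, each in selection
    order), then optionally the two dependency lengths, then the
    surface offset distance.
    """

    top_forward_bigrams: tuple
    top_backward_bigrams: tuple
    use_dep_lengths: bool = False
    use_offset_distance: bool = False
    element_mode: str = "both"

    @property
    def dimension(self) -> int:
        return (
            len(self.top_forward_bigrams)
            + len(self.top_backward_bigrams)
            + 2 * self.use_dep_lengths
            + self.use_offset_distance
        )

    def to_json(self, stream: IO) -> None:
        json.dump(
            {
                "top_forward_bigrams": [list(b) for b in self.top_forward_bigrams],
                "top_backward_bigrams": [list(b) for b in self.top_backward_bigrams],
                "use_dep_lengths": self.use_dep_lengths,
                "use_offset_distance": self.use_offset_distance,
                "element_mode": self.element_mode,
            },
            stream,
            indent=1,
        )

    @classmethod
    def from_json(cls, stream: IO) -> "FeatureSpec":
        d = json.load(stream)
        return cls(
            top_forward_bigrams=tuple(tuple(b) for b in d["top_forward_bigrams"]),
            top_backward_bigrams=tuple(tuple(b) for b in d["top_backward_bigrams"]),
            use_dep_lengths=d["use_dep_lengths"],
            use_offset_distance=d["use_offset_distance"],
            element_mode=d.get("element_mode", "both"),
        )


def _chain_pair(inst: ExtractionInstance) -> tuple[DepChain, DepChain]:
    pre = getattr(inst, "chains", None)  # precomputed-chain carriers welcome
    if pre is not None:
        return pre
    if inst.tree is None:
        return DepChain("forward", (), False), DepChain("backward", (), False)
    return extract_chains(inst.tree, inst.pair)


def select_top_features(
    instances: Sequence[ExtractionInstance],
    n: int = 100,
    *,
    use_dep_lengths: bool = False,
    use_offset_distance: bool = False,
    element_mode: str = "both",
) -> FeatureSpec:
    """Pick the top-n bigrams per direction by cross-direction contrast.

    A forward bigram's score is (its count over all forward chains)
    minus (its count over all backward chains); backward scores are the
    symmetric difference.  Ties break on the higher same-direction raw
    count, then on the lexicographic bigram string, so selection is
    deterministic and invariant to instance order.
    """
    fwd = Counter()
    bwd = Counter()
    for inst in instances:
        f, b = _chain_pair(inst)
        fwd.update(chain_bigrams(f, element_mode))
        bwd.update(chain_bigrams(b, element_mode))

    def top(own: Counter, other: Counter) -> tuple:
        scored = sorted(
            own.keys() | other.keys(),
            key=lambda bg: (-(own[bg] - other[bg]), -own[bg], bg),
        )
        return tuple(scored[:n])

    return FeatureSpec(
        top_forward_bigrams=top(fwd, bwd),
        top_backward_bigrams=top(bwd, fwd),
        use_dep_lengths=use_dep_lengths,
        use_offset_distance=use_offset_distance,
        element_mode=element_mode,
    )


def featurize(instance: ExtractionInstance, spec: FeatureSpec) -> np.ndarray:
    """Fixed-dimension feature vector for one instance.

    Binary presence indicators for the selected bigrams, then (if
    enabled) the forward/backward chain lengths in edges and the token
    offset distance (adjacent proteins -> 1).
    """
    f, b = _chain_pair(instance)
    fset = set(chain_bigrams(f, spec.element_mode))
    bset = set(chain_bigrams(b, spec.element_mode))
    vec = np.zeros(spec.dimension, dtype=float)
    i = 0
    for bg in spec.top_forward_bigrams:
        vec[i] = 1.0 if bg in fset else 0.0
        i += 1
    for bg in spec.top_backward_bigrams:
        vec[i] = 1.0 if bg in bset else 0.0
        i += 1
    if spec.use_dep_lengths:
        vec[i] = len(f)
        vec[i + 1] = len(b)
        i += 2
    if spec.use_offset_distance:
        ti = instance.sentence.mention_token_index(instance.pair.first)
        tj = instance.sentence.mention_token_index(instance.pair.second)
        vec[i] = tj - ti
    return vec


# ---------------------------------------------------------------------------
# reference classifier (pluggable-tier stand-in)
# ---------------------------------------------------------------------------

class ThresholdClassifier:
    """Deterministic reference classifier over binary feature counts.

    Predicts positive when the number of active bigram features is at
    least a threshold; fitting exhaustively searches the threshold that
    maximizes training F (ties -> the smallest threshold).  It exists
    as a transparent, fully deterministic plug-in tier; any external
    estimator obeying the contract (e.g. a scikit-learn model wrapped
    in :class:`FeatureTier`) can replace it.
    """

    def __init__(self) -> None:
        self.name = "threshold"
        self.threshold: int | None = None

    @staticmethod
    def _counts(X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float).sum(axis=1)

    def fit(self, X: np.ndarray, y: Sequence[bool]) -> None:
        counts = self._counts(X)
        y = np.asarray(y, dtype=bool)
        best = (-1.0, 0)
        for t in range(0, int(counts.max(initial=0)) + 2):
            pred = counts >= t
            tp = int(np.sum(pred & y))
            fp = int(np.sum(pred & ~y))
            fn = int(np.sum(~pred & y))
            p = tp / (tp + fp) if tp + fp else 0.0
            r = tp / (tp + fn) if tp + fn else 0.0
            f = 2 * p * r / (p + r) if p + r else 0.0
            if f > best[0]:
                best = (f, t)
        self.threshold = best[1]

    def predict_vector(self, x: np.ndarray) -> bool:
        if self.threshold is None:
            raise RuntimeError("ThresholdClassifier.predict before fit")
        return bool(np.asarray(x, dtype=float).sum() >= self.threshold)


class FeatureTier:
    """Adapter: featurizes instances and delegates to a vector classifier.

    The vector classifier needs ``fit(X, y)`` plus either
    ``predict_vector(x)`` (ThresholdClassifier) or sklearn-style
    ``predict(X)``.  Stochastic models must be seeded by the caller;
    everything shipped here is deterministic.
    """

    def __init__(self, spec: FeatureSpec, model, name: str | None = None) -> None:
        self.spec = spec
        self.model = model
        self.name = name or getattr(model, "name", type(model).__name__)

    def fit(self, instances: Sequence[ExtractionInstance], labels: Sequence[bool]) -> None:
        X = np.vstack([featurize(i, self.spec) for i in instances])
        self.model.fit(X, np.asarray(labels, dtype=bool))

    def predict(self, instance: ExtractionInstance) -> bool:
        x = featurize(instance, self.spec)
        if hasattr(self.model, "predict_vector"):
            return bool(self.model.predict_vector(x))
        return bool(self.model.predict(x.reshape(1, -1))[0])
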