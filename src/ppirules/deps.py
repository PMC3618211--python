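"""Dependency-graph model in the collapsed-Stanford label dialect.

The extraction rules are written against collapsed dependency labels:
prepositions folded into the edge label (``prep_of``, ``prep_between``),
coordination folded into ``conj_and`` with argument propagation to the
conjuncts, and negation surfacing as a ``neg`` edge.  Universal
Dependencies input (``nmod``/``obl`` + ``case``, ``conj`` + ``cc``,
``advmod`` "not", ``det`` "no") is converted by :func:`collapse_ud`;
trees already in the collapsed dialect pass through unchanged, so the
conversion is idempotent.

Parses are ingested from CoNLL-U.  The package never calls a parser:
fixture and synthetic trees ship pre-built.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import IO, Iterable, Sequence

from ppirules.errors import AlignmentError
from ppirules.corpus import AnnotatedSentence

MASK_RE = re.compile(r"PROTEIN\d+$")

#: labels that never make a token "dependency-bearing"
FUNCTION_LABELS = frozenset({"case", "cc", "punct", "det", "mark", "aux", "auxpass", "cop"})
#: parts of speech excluded from the dependency-bearing word count
FUNCTION_POS = frozenset({"ADP", "CCONJ", "PUNCT", "DET", "AUX", "PART"})

_NEG_ADVERBS = frozenset({"not", "n't", "never"})


@dataclass(frozen=True)
class Token:
    index: int
    text: str
    lemma: str = ""
    coarse_pos: str = ""
    is_protein: bool = False
    mask_label: str | None = None

    def __post_init__(self):
        if not self.lemma:
            object.__setattr__(self, "lemma", self.text.lower())
        if MASK_RE.match(self.text):
            object.__setattr__(self, "is_protein", True)
            object.__setattr__(self, "mask_label", self.text)


@dataclass(frozen=True)
class DepEdge:
    head: int
    dependent: int
    label: str
    propagated: bool = False


@dataclass
class DepTree:
    """Rooted labeled dependency graph over the tokens of one sentence.

    The non-propagated edges form a tree; conjunction propagation adds
    extra flagged edges on top of it.
    """

    sentence_id: str
    tokens: list[Token]
    edges: list[DepEdge]
    root: int
    _by_head: dict | None = field(default=None, repr=False, compare=False)

    def token(self, index: int) -> Token:
        return self.tokens[index]

    def _index(self) -> dict:
        if self._by_head is None:
            by_head: dict[int, list[DepEdge]] = {}
            for e in self.edges:
                by_head.setdefault(e.head, []).append(e)
            self._by_head = by_head
        return self._by_head

    def out_edges(self, node: int) -> list[DepEdge]:
        return self._index().get(node, [])

    def head_of(self, node: int) -> int | None:
        """Non-propagated head of a token, or None for the root."""
        for e in self.edges:
            if e.dependent == node and not e.propagated:
                return e.head
        return None

    def protein_index(self, mask_label: str) -> int:
        for t in self.tokens:
            if t.mask_label == mask_label:
                return t.index
        raise AlignmentError(
            f"protein token {mask_label!r} not in tree {self.sentence_id!r}"
        )


# ---------------------------------------------------------------------------
# graph queries used by the rules
# ---------------------------------------------------------------------------

def dependents(tree: DepTree, node: int, label_pattern: str) -> list[Token]:
    """Dependents of ``node`` whose edge label matches ``label_pattern``.

    The pattern is either an exact label or a prefix wildcard such as
    ``"prep_*"``.  Propagated edges are included; results come back in
    token order.
    """
    if label_pattern.endswith("*"):
        prefix = label_pattern[:-1]
        hit = lambda lbl: lbl.startswith(prefix)  # noqa: E731
    else:
        hit = lambda lbl: lbl == label_pattern  # noqa: E731
    idx = sorted({e.dependent for e in tree.out_edges(node) if hit(e.label)})
    return [tree.tokens[i] for i in idx]


def has_negation(tree: DepTree, node: int) -> bool:
    """True iff ``node`` has a ``neg``-labeled dependent."""
    return any(e.label == "neg" for e in tree.out_edges(node))


def governing_verb(tree: DepTree, node: int) -> int | None:
    """Nearest ancestor of ``node`` (along non-propagated edges) that is a verb."""
    seen = set()
    cur = tree.head_of(node)
    while cur is not None and cur not in seen:
        seen.add(cur)
        if tree.tokens[cur].coarse_pos in ("VERB", "AUX"):
            return cur
        cur = tree.head_of(cur)
    return None


def intervening_dep_words(tree: DepTree, i: int, j: int) -> int:
    """Number of dependency-bearing words strictly between two tokens.

    A token counts when it participates in at least one edge whose label
    is outside the function-word set (case markers absorbed by
    collapsing, cc, punct, det, mark, ...) and its part of speech is not
    adposition/conjunction/punctuation/determiner.  Prepositions and
    coordinators therefore never count, matching the convention that in
    a pattern like "interacts ... with ... and ..." only content words
    between the proteins are limited.
    """
    lo, hi = min(i, j), max(i, j)
    count = 0
    for t in tree.tokens[lo + 1 : hi]:
        if t.coarse_pos in FUNCTION_POS:
            continue
        bearing = any(
            e.label not in FUNCTION_LABELS
            for e in tree.edges
            if e.head == t.index or e.dependent == t.index
        )
        if bearing:
            count += 1
    return count


# ---------------------------------------------------------------------------
# UD -> collapsed-Stanford conversion
# ---------------------------------------------------------------------------

def collapse_ud(tree: DepTree) -> DepTree:
    """Convert UD-style labels to the collapsed-Stanford dialect.

    * ``nmod:X`` / ``obl:X`` (or bare ``nmod``/``obl`` whose dependent
      has a ``case`` child) become ``prep_X``;
    * ``conj:and`` (or ``conj`` with a ``cc`` child) becomes
      ``conj_and`` and the conjunct receives propagated copies of the
      first conjunct's incoming ``nsubj``/``dobj``/``prep_*`` edges;
    * ``advmod`` on "not"/"never" and ``det`` on "no" become ``neg``;
    * ``obj`` is normalized to ``dobj``; everything else passes through.

    Idempotent: a tree already in the collapsed dialect is returned
    unchanged (up to the propagation closure).
    """
    by_head: dict[int, list[DepEdge]] = {}
    for e in tree.edges:
        by_head.setdefault(e.head, []).append(e)

    def case_marker(node: int) -> str | None:
        for e in by_head.get(node, []):
            if e.label == "case":
                return tree.tokens[e.dependent].lemma.lower()
        return None

    def coordinator(node: int) -> str | None:
        for e in by_head.get(node, []):
            if e.label == "cc":
                return tree.tokens[e.dependent].lemma.lower()
        return None

    new_edges: list[DepEdge] = []
    for e in tree.edges:
        label = e.label
        dep_tok = tree.tokens[e.dependent]
        if label.startswith(("nmod:", "obl:")):
            label = "prep_" + label.split(":", 1)[1]
        elif label in ("nmod", "obl"):
            marker = case_marker(e.dependent)
            if marker:
                label = f"prep_{marker}"
        elif label.startswith("conj:"):
            label = "conj_" + label.split(":", 1)[1]
        elif label == "conj":
            coord = coordinator(e.dependent)
            label = f"conj_{coord}" if coord else "conj"
        elif label == "advmod" and dep_tok.lemma.lower() in _NEG_ADVERBS:
            label = "neg"
        elif label == "det" and dep_tok.lemma.lower() == "no":
            label = "neg"
        elif label == "obj":
            label = "dobj"
        new_edges.append(replace(e, label=label))

    # conjunction propagation: the second conjunct inherits the first
    # conjunct's incoming argument edges (flagged, so queries can treat
    # them identically while the tree property is preserved).
    existing = {(e.head, e.dependent, e.label) for e in new_edges}
    propagated: list[DepEdge] = []
    for conj in [e for e in new_edges if e.label.startswith("conj_")]:
        for incoming in new_edges:
            if incoming.dependent != conj.head or incoming.propagated:
                continue
            if incoming.label in ("nsubj", "dobj") or incoming.label.startswith("prep_"):
                key = (incoming.head, conj.dependent, incoming.label)
                if key not in existing:
                    existing.add(key)
                    propagated.append(
                        DepEdge(incoming.head, conj.dependent, incoming.label, propagated=True)
                    )
    return DepTree(
        sentence_id=tree.sentence_id,
        tokens=list(tree.tokens),
        edges=new_edges + propagated,
        root=tree.root,
    )


# ---------------------------------------------------------------------------
# CoNLL-U ingestion
# ---------------------------------------------------------------------------

def read_conllu(
    stream: IO | Iterable[str],
    *,
    sentences: Sequence[AnnotatedSentence] | None = None,
) -> list[DepTree]:
    """Read 10-column CoNLL-U into dependency trees.

    Multiword-token ranges and empty nodes are skipped; the enhanced
    dependency column is ignored (collapsing is done by
    :func:`collapse_ud`).  Sentence ids come from ``# sent_id =``
    comments.  When masked ``sentences`` are supplied, token counts are
    checked against them and a mismatch raises :class:`AlignmentError`.
    """
    by_id = {s.sentence_id: s for s in sentences} if sentences else {}
    trees: list[DepTree] = []
    sent_id: str | None = None
    rows: list[tuple[int, str, str, str, int, str]] = []

    def flush() -> None:
        nonlocal sent_id, rows
        if not rows:
            sent_id = None
            return
        sid = sent_id if sent_id is not None else f"conllu{len(trees)}"
        tokens = []
        edges = []
        root = 0
        remap = {cid: i for i, (cid, *_rest) in enumerate(rows)}
        for i, (cid, form, lemma, upos, head, deprel) in enumerate(rows):
            tokens.append(Token(index=i, text=form, lemma=lemma, coarse_pos=upos))
            if head == 0:
                root = i
            else:
                if head not in remap:
                    raise AlignmentError(
                        f"sentence {sid!r}: head {head} refers to a missing token"
                    )
                edges.append(DepEdge(remap[head], i, deprel))
        if sid in by_id:
            expected = by_id[sid].tokens
            got = [t.text for t in tokens]
            if expected != got:
                raise AlignmentError(
                    f"sentence {sid!r}: CoNLL-U tokens {got!r} do not match "
                    f"masked tokens {expected!r}"
                )
        trees.append(DepTree(sentence_id=sid, tokens=tokens, edges=edges, root=root))
        sent_id = None
        rows = []

    for raw in stream:
        line = raw.rstrip("\n")
        if not line.strip():
            flush()
            continue
        if line.startswith("#"):
            m = re.match(r"#\s*sent_id\s*=\s*(\S+)", line)
            if m:
                sent_id = m.group(1)
            continue
        cols = line.split("\t")
        if len(cols) < 8:
            raise AlignmentError(f"bad CoNLL-U line (need >=8 columns): {line!r}")
        cid = cols[0]
        if "-" in cid or "." in cid:  # multiword range or empty node
            continue
        form, lemma, upos = cols[1], cols[2], cols[3]
        if lemma == "_":
            lemma = form.lower()
        head = int(cols[6])
        deprel = cols[7]
        rows.append((int(cid), form, lemma, upos, head, deprel))
    flush()
    return trees


def write_conllu(trees: Iterable[DepTree], stream: IO) -> None:
    """Serialize trees to 10-column CoNLL-U (propagated edges omitted)."""
    for tree in trees:
        stream.write(f"# sent_id = {tree.sentence_id}\n")
        heads = {e.dependent: (e.head, e.label) for e in tree.edges if not e.propagated}
        for t in tree.tokens:
            if t.index == tree.root:
                head, label = 0, "root"
            else:
                h, label = heads.get(t.index, (tree.root, "dep"))
                head = h + 1
            stream.write(
                "\t".join(
                    [
                        str(t.index + 1),
                        t.text,
                        t.lemma or "_",
                        t.coarse_pos or "_",
                        "_",
                        "_",
                        str(head),
                        label,
                        "_",
                        "_",
                    ]
                )
                + "\n"
            )
        stream.write("\n")
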