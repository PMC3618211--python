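"""Corpus reading and sentence normalization for PPI extraction.

Sentences are normalized the way high-precision PPI extractors prepare
text for parsing: protein mentions are masked with single placeholder
tokens (``PROTEIN0``, ``PROTEIN1``, ...), parenthetical remarks that
contain no protein are removed, multi-clause sentences are split, and
only sentences/clauses with at least two proteins become extraction
candidates.

Two input dialects are supported: a unified PPI-XML format
(corpus/document/sentence with character-offset entities and pairwise
interaction labels) and plain text plus standoff TSV spans.  Normalized
sentences round-trip through a JSONL representation consumed by the
downstream modules.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field, replace
from typing import IO, Iterable, Sequence

from lxml import etree

from ppirules.errors import CorpusIntegrityError, CorpusParseError, NormalizationError

logger = logging.getLogger(__name__)

MASK_RE = re.compile(r"PROTEIN\d+$")
# one token per protein mask, word, or single punctuation mark
_TOKEN_RE = re.compile(r"PROTEIN\d+|\w+|[^\w\s]")

#: sentence-medial coordinators at which clause splitting is attempted
_CLAUSE_CONJ = {"and", "but", "or", "while", "whereas"}


def normalize_entity_key(surface: str) -> str:
    """Case-folded surface with whitespace/hyphen variation collapsed."""
    return re.sub(r"[\s\-]+", "", surface).casefold()


def tokenize(text: str) -> list[str]:
    return _TOKEN_RE.findall(text)


@dataclass(frozen=True)
class ProteinMention:
    """A protein name occurrence inside one sentence.

    ``char_span`` is a 0-based half-open interval.  After masking it
    refers to the masked text and covers exactly the ``mask_label``
    token.  ``entity_key`` is the normalized identity used to group
    instances of the same relation corpus-wide.
    """

    mention_id: str
    char_span: tuple[int, int]
    surface: str
    mask_label: str | None = None
    entity_key: str = ""

    def __post_init__(self) -> None:
        if not self.entity_key:
            object.__setattr__(self, "entity_key", normalize_entity_key(self.surface))


@dataclass
class AnnotatedSentence:
    """A masked, tokenized sentence with mentions and gold pair labels.

    ``gold_pairs`` maps unordered mention-id pairs (frozensets of size 2)
    to a boolean interaction label.  ``is_candidate`` is False when the
    sentence has fewer than two protein mentions and is therefore never
    shown to the rule engine.
    """

    sentence_id: str
    raw_text: str
    masked_text: str
    tokens: list[str]
    mentions: list[ProteinMention]
    gold_pairs: dict[frozenset, bool] = field(default_factory=dict)

    @property
    def is_candidate(self) -> bool:
        return len(self.mentions) >= 2

    def mention(self, mention_id: str) -> ProteinMention:
        for m in self.mentions:
            if m.mention_id == mention_id:
                return m
        raise KeyError(mention_id)

    def mention_token_index(self, mention: ProteinMention) -> int:
        """Index of the mask token that realizes ``mention``."""
        try:
            return self.tokens.index(mention.mask_label)
        except ValueError:
            raise CorpusIntegrityError(
                f"mask token {mention.mask_label!r} missing from sentence "
                f"{self.sentence_id!r}"
            ) from None


@dataclass(frozen=True)
class CandidatePair:
    """An unordered candidate protein pair, stored in surface order."""

    first: ProteinMention
    second: ProteinMention
    surface_span_tokens: int

    @property
    def is_self_relation(self) -> bool:
        return self.first.entity_key == self.second.entity_key

    @property
    def mention_ids(self) -> frozenset:
        return frozenset((self.first.mention_id, self.second.mention_id))


# ---------------------------------------------------------------------------
# masking
# ---------------------------------------------------------------------------

def mask_proteins(
    raw_text: str,
    spans: Sequence[tuple[int, int]],
    *,
    mention_ids: Sequence[str] | None = None,
    entity_keys: Sequence[str] | None = None,
) -> tuple[str, list[ProteinMention]]:
    """Replace each protein span with a ``PROTEINk`` placeholder.

    Labels are assigned in order of first appearance (span start).
    Identical surface names at different positions receive distinct
    labels.  Mention character offsets are recomputed on the masked
    text.  Overlapping spans raise :class:`NormalizationError`.
    """
    order = sorted(range(len(spans)), key=lambda i: spans[i])
    for a, b in zip(order, order[1:]):
        if spans[a][1] > spans[b][0]:
            raise NormalizationError(
                f"overlapping protein spans {spans[a]} and {spans[b]}"
            )
    for start, end in spans:
        if not (0 <= start < end <= len(raw_text)):
            raise NormalizationError(f"span ({start}, {end}) outside text")

    out: list[str] = []
    mentions: list[ProteinMention] = []
    cursor = 0
    masked_len = 0
    for k, i in enumerate(order):
        start, end = spans[i]
        label = f"PROTEIN{k}"
        out.append(raw_text[cursor:start])
        masked_len += start - cursor
        surface = raw_text[start:end]
        mid = mention_ids[i] if mention_ids is not None else f"m{i}"
        key = entity_keys[i] if entity_keys is not None else ""
        mentions.append(
            ProteinMention(
                mention_id=mid,
                char_span=(masked_len, masked_len + len(label)),
                surface=surface,
                mask_label=label,
                entity_key=key,
            )
        )
        out.append(label)
        masked_len += len(label)
        cursor = end
    out.append(raw_text[cursor:])
    # restore original span order of the input for positional stability
    mentions.sort(key=lambda m: m.char_span)
    return "".join(out), mentions


def unmask(masked_text: str, mentions: Iterable[ProteinMention]) -> str:
    """Inverse of :func:`mask_proteins` using the stored surfaces."""
    text = masked_text
    for m in sorted(mentions, key=lambda m: m.char_span, reverse=True):
        a, b = m.char_span
        text = text[:a] + m.surface + text[b:]
    return text


def _relocate_mentions(
    new_text: str, mentions: Iterable[ProteinMention]
) -> list[ProteinMention]:
    """Recompute mention char spans after a text edit (mask labels are unique)."""
    out = []
    for m in mentions:
        pos = re.search(rf"\b{m.mask_label}\b", new_text)
        if pos is None:
            raise NormalizationError(
                f"mask token {m.mask_label!r} lost during normalization"
            )
        out.append(replace(m, char_span=(pos.start(), pos.end())))
    return out


# ---------------------------------------------------------------------------
# parenthetical stripping
# ---------------------------------------------------------------------------

def strip_parentheticals(masked_text: str) -> str:
    """Delete maximal ``(...)`` regions that contain no protein mask.

    Regions with a protein anywhere inside (including nested) are kept
    verbatim.  Unmatched parentheses are treated as literal characters.
    """
    opens: list[int] = []
    # spans of top-level balanced groups
    groups: list[tuple[int, int]] = []
    for i, ch in enumerate(masked_text):
        if ch == "(":
            opens.append(i)
        elif ch == ")" and opens:
            start = opens.pop()
            if not opens:
                groups.append((start, i + 1))
    out = masked_text
    for start, end in reversed(groups):
        if "PROTEIN" in masked_text[start:end]:
            continue
        left = out[:start].rstrip()
        right = out[end:]
        if right and not right.startswith((" ", ".", ",", ";", ")")):
            right = " " + right
        out = left + right
    return re.sub(r"  +", " ", out).strip()


def strip_sentence_parentheticals(sentence: AnnotatedSentence) -> AnnotatedSentence:
    """Apply :func:`strip_parentheticals` and recompute mention offsets."""
    new_text = strip_parentheticals(sentence.masked_text)
    if new_text == sentence.masked_text:
        return sentence
    return AnnotatedSentence(
        sentence_id=sentence.sentence_id,
        raw_text=sentence.raw_text,
        masked_text=new_text,
        tokens=tokenize(new_text),
        mentions=_relocate_mentions(new_text, sentence.mentions),
        gold_pairs=dict(sentence.gold_pairs),
    )


# ---------------------------------------------------------------------------
# clause splitting
# ---------------------------------------------------------------------------

@dataclass
class ClauseSplit:
    clauses: list[AnnotatedSentence]
    straddling_pairs: list[frozenset]


def split_clauses(sentence: AnnotatedSentence, *, enabled: bool = True) -> ClauseSplit:
    """Split a multi-clause sentence into separate clause sentences.

    Conservative, parse-free heuristic: split at sentence-medial
    semicolons, and at a comma followed by a coordinating conjunction
    when both resulting sides contain at least two protein masks.  The
    clause token sequences cover the sentence tokens exactly once;
    mentions and gold pairs are reassigned to the clause containing
    them, and gold pairs straddling a boundary are dropped and reported.
    """
    tokens = sentence.tokens
    if not enabled or len(sentence.mentions) == 0:
        return ClauseSplit([sentence], [])

    def n_proteins(seg: Sequence[str]) -> int:
        return sum(1 for t in seg if MASK_RE.match(t))

    boundaries: list[int] = []  # clause starts after these token indices
    for i, tok in enumerate(tokens[:-1]):
        if i == 0:
            continue
        if tok == ";":
            boundaries.append(i)
        elif (
            tok == ","
            and i + 1 < len(tokens)
            and tokens[i + 1].lower() in _CLAUSE_CONJ
            and n_proteins(tokens[: i + 1]) >= 2
            and n_proteins(tokens[i + 1 :]) >= 2
        ):
            boundaries.append(i)
    if not boundaries:
        return ClauseSplit([sentence], [])

    segments: list[list[str]] = []
    start = 0
    for b in boundaries:
        segments.append(tokens[start : b + 1])  # separator stays with left clause
        start = b + 1
    segments.append(tokens[start:])

    clauses: list[AnnotatedSentence] = []
    mention_clause: dict[str, int] = {}
    for ci, seg in enumerate(segments):
        text = " ".join(seg)
        mentions = []
        for m in sentence.mentions:
            if m.mask_label in seg:
                mention_clause[m.mention_id] = ci
                mentions.append(m)
        mentions = _relocate_mentions(text, mentions) if mentions else []
        clauses.append(
            AnnotatedSentence(
                sentence_id=f"{sentence.sentence_id}.c{ci}",
                raw_text=sentence.raw_text,
                masked_text=text,
                tokens=list(seg),
                mentions=mentions,
                gold_pairs={},
            )
        )
    straddlers: list[frozenset] = []
    for pair, label in sentence.gold_pairs.items():
        a, b = tuple(pair)
        if mention_clause.get(a) == mention_clause.get(b) and a in mention_clause:
            clauses[mention_clause[a]].gold_pairs[pair] = label
        else:
            straddlers.append(pair)
    if straddlers:
        logger.warning(
            "sentence %s: %d gold pair(s) straddle a clause boundary and are dropped",
            sentence.sentence_id,
            len(straddlers),
        )
    return ClauseSplit(clauses, straddlers)


# ---------------------------------------------------------------------------
# candidate enumeration
# ---------------------------------------------------------------------------

def enumerate_candidates(sentence: AnnotatedSentence) -> list[CandidatePair]:
    """All unordered mention pairs of a sentence, in surface order.

    Returns exactly n(n-1)/2 pairs for n mentions.  The seven-word
    window is *not* applied here; it is a per-rule constraint.  Pairs of
    co-referent mentions (same entity key) are emitted and flagged via
    :attr:`CandidatePair.is_self_relation`.
    """
    ms = sorted(sentence.mentions, key=sentence.mention_token_index)
    pairs = []
    for i in range(len(ms)):
        for j in range(i + 1, len(ms)):
            ti = sentence.mention_token_index(ms[i])
            tj = sentence.mention_token_index(ms[j])
            pairs.append(CandidatePair(ms[i], ms[j], surface_span_tokens=tj - ti + 1))
    return pairs


# ---------------------------------------------------------------------------
# PPI-XML dialect
# ---------------------------------------------------------------------------

def read_ppi_corpus(
    stream: IO | str,
    *,
    exhaustive_pairs: bool = True,
) -> list[AnnotatedSentence]:
    """Read a unified PPI-XML corpus into masked annotated sentences.

    The dialect nests corpus/document/sentence; each sentence carries
    ``<entity id charOffset="a-b" text>`` children (inclusive character
    ranges, converted to half-open) and ``<pair e1 e2 interaction>`` or
    ``<interaction e1 e2>`` elements.  With ``exhaustive_pairs`` (the
    convention of exhaustively annotated corpora such as AIMed) entity
    pairs without a pair element are materialized as gold negatives.
    """
    try:
        tree = etree.parse(stream)
    except etree.XMLSyntaxError as exc:
        raise CorpusParseError(
            f"malformed corpus XML at line {exc.lineno}, column {exc.offset}: {exc.msg}"
        ) from exc

    sentences: list[AnnotatedSentence] = []
    for sent_el in tree.iter("sentence"):
        sid = sent_el.get("id") or f"s{len(sentences)}"
        text = sent_el.get("text") or (sent_el.text or "")
        spans: list[tuple[int, int]] = []
        ids: list[str] = []
        keys: list[str] = []
        for ent in sent_el.findall("entity"):
            off = ent.get("charOffset", "")
            try:
                parts = [p.split("-") for p in off.split(",")]
                start = min(int(p[0]) for p in parts)
                end = max(int(p[1]) for p in parts) + 1  # inclusive -> half-open
            except (ValueError, IndexError):
                raise CorpusParseError(
                    f"sentence {sid!r}: bad charOffset {off!r}"
                ) from None
            if end > len(text):
                raise CorpusParseError(
                    f"sentence {sid!r}: entity offset {off!r} outside sentence text"
                )
            spans.append((start, end))
            ids.append(ent.get("id") or f"{sid}.e{len(ids)}")
            keys.append(ent.get("normalized") or "")
        # overlapping spans: keep the longest, drop contained ones
        keep = _drop_overlaps(sid, spans)
        spans = [spans[i] for i in keep]
        ids = [ids[i] for i in keep]
        keys = [keys[i] for i in keep]

        masked, mentions = mask_proteins(text, spans, mention_ids=ids, entity_keys=keys)
        sent = AnnotatedSentence(
            sentence_id=sid,
            raw_text=text,
            masked_text=masked,
            tokens=tokenize(masked),
            mentions=mentions,
            gold_pairs={},
        )
        known = {m.mention_id for m in mentions}
        for pel in list(sent_el.findall("pair")) + list(sent_el.findall("interaction")):
            e1, e2 = pel.get("e1"), pel.get("e2")
            for ref in (e1, e2):
                if ref not in known:
                    raise CorpusIntegrityError(
                        f"sentence {sid!r}: pair references unknown entity {ref!r}"
                    )
            if e1 == e2:
                raise CorpusIntegrityError(
                    f"sentence {sid!r}: pair references the same entity twice"
                )
            flag = pel.get("interaction", "True")
            sent.gold_pairs[frozenset((e1, e2))] = flag.lower() in ("true", "1", "yes")
        if exhaustive_pairs:
            for cand in enumerate_candidates(sent):
                sent.gold_pairs.setdefault(cand.mention_ids, False)
        if not sent.is_candidate:
            logger.info("sentence %s has <2 proteins; flagged non-candidate", sid)
        sentences.append(sent)
    return sentences


def _drop_overlaps(sid: str, spans: list[tuple[int, int]]) -> list[int]:
    keep = []
    for i, (a, b) in enumerate(spans):
        contained = any(
            j != i and spans[j][0] <= a and b <= spans[j][1] and (spans[j] != (a, b) or j < i)
            for j in range(len(spans))
        )
        if contained:
            logger.warning("sentence %s: dropping entity span (%d, %d) contained in a longer one", sid, a, b)
        else:
            keep.append(i)
    return keep


def write_ppi_corpus(sentences: Iterable[AnnotatedSentence], stream: IO) -> None:
    """Write sentences back to the PPI-XML dialect (round-trip partner)."""
    corpus = etree.Element("corpus", source="ppirules")
    doc = etree.SubElement(corpus, "document", id="d0")
    for s in sentences:
        sent_el = etree.SubElement(doc, "sentence", id=s.sentence_id, text=s.raw_text)
        # export offsets on the raw text by unmasking span bookkeeping
        raw_spans = _raw_spans(s)
        for m, (a, b) in zip(sorted(s.mentions, key=lambda m: m.char_span), raw_spans):
            etree.SubElement(
                sent_el,
                "entity",
                id=m.mention_id,
                charOffset=f"{a}-{b - 1}",
                text=m.surface,
                type="protein",
            )
        for pair, label in sorted(s.gold_pairs.items(), key=lambda kv: sorted(kv[0])):
            e1, e2 = sorted(pair)
            etree.SubElement(
                sent_el, "pair", e1=e1, e2=e2, interaction="True" if label else "False"
            )
    data = etree.tostring(corpus, pretty_print=True, xml_declaration=True, encoding="UTF-8")
    try:
        stream.write(data)
    except TypeError:
        stream.write(data.decode("utf-8"))


def _raw_spans(s: AnnotatedSentence) -> list[tuple[int, int]]:
    """Character spans of the mentions on the raw (unmasked) text."""
    spans = []
    shift = 0
    for m in sorted(s.mentions, key=lambda m: m.char_span):
        a, _ = m.char_span
        start = a + shift
        spans.append((start, start + len(m.surface)))
        shift += len(m.surface) - len(m.mask_label or "")
    return spans


# ---------------------------------------------------------------------------
# standoff TSV dialect
# ---------------------------------------------------------------------------

def read_standoff(
    text_stream: IO, spans_stream: IO, *, exhaustive_pairs: bool = False
) -> list[AnnotatedSentence]:
    """Plain-text sentences (``id<TAB>text``) plus standoff TSV spans.

    The spans file has columns sentence_id, start, end (half-open),
    surface.  Gold labels are not part of this dialect.
    """
    texts: dict[str, str] = {}
    for line in text_stream:
        line = line.rstrip("\n")
        if not line:
            continue
        sid, _, text = line.partition("\t")
        texts[sid] = text
    spans: dict[str, list[tuple[int, int, str]]] = {sid: [] for sid in texts}
    for line in spans_stream:
        line = line.rstrip("\n")
        if not line:
            continue
        sid, start, end, surface = line.split("\t")[:4]
        if sid not in texts:
            raise CorpusIntegrityError(f"standoff span references unknown sentence {sid!r}")
        spans[sid].append((int(start), int(end), surface))
    out = []
    for sid, text in texts.items():
        ss = sorted(spans[sid])
        for start, end, surface in ss:
            if text[start:end] != surface:
                raise CorpusParseError(
                    f"sentence {sid!r}: span ({start}, {end}) does not match surface {surface!r}"
                )
        masked, mentions = mask_proteins(text, [(a, b) for a, b, _ in ss])
        sent = AnnotatedSentence(sid, text, masked, tokenize(masked), mentions)
        if exhaustive_pairs:
            for cand in enumerate_candidates(sent):
                sent.gold_pairs.setdefault(cand.mention_ids, False)
        out.append(sent)
    return out


# ---------------------------------------------------------------------------
# JSONL interchange
# ---------------------------------------------------------------------------

def to_jsonl(sentences: Iterable[AnnotatedSentence], stream: IO) -> None:
    for s in sentences:
        rec = {
            "sentence_id": s.sentence_id,
            "raw_text": s.raw_text,
            "masked_text": s.masked_text,
            "tokens": s.tokens,
            "mentions": [
                {
                    "mention_id": m.mention_id,
                    "char_span": list(m.char_span),
                    "surface": m.surface,
                    "mask_label": m.mask_label,
                    "entity_key": m.entity_key,
                }
                for m in s.mentions
            ],
            "gold_pairs": [
                {"pair": sorted(p), "label": bool(v)} for p, v in sorted(
                    s.gold_pairs.items(), key=lambda kv: sorted(kv[0])
                )
            ],
        }
        stream.write(json.dumps(rec) + "\n")


def from_jsonl(stream: IO) -> list[AnnotatedSentence]:
    out = []
    for line in stream:
        if not line.strip():
            continue
        rec = json.loads(line)
        out.append(
            AnnotatedSentence(
                sentence_id=rec["sentence_id"],
                raw_text=rec["raw_text"],
                masked_text=rec["masked_text"],
                tokens=list(rec["tokens"]),
                mentions=[
                    ProteinMention(
                        mention_id=m["mention_id"],
                        char_span=tuple(m["char_span"]),
                        surface=m["surface"],
                        mask_label=m["mask_label"],
                        entity_key=m["entity_key"],
                    )
                    for m in rec["mentions"]
                ],
                gold_pairs={
                    frozenset(p["pair"]): bool(p["label"]) for p in rec["gold_pairs"]
                },
            )
        )
    return out
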