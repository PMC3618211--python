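"""The interaction-keyword lexicon and its morphological matcher.

67 relation lemmas, partitioned into five interaction categories
(Activation, Deactivation, Creating bond, Breaking bond, Signaling),
signal that a sentence asserts an interaction.  Rules refer to a token
as a relation word (REL) when :func:`match_keyword` maps it onto one of
the lemmas.  Matching covers inflected verbal forms ("interacts",
"bound") and the productive nominalizations ("binding", "interaction",
"activation") through a deterministic suffix-stripping normalizer plus
a hand-curated exception table; the category is recorded for reporting
but never used by the rules themselves.

The lexicon is data, not code: a TSV file (``lemma<TAB>category``)
packaged with the module and replaceable by the user.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import IO

DEFAULT_LEXICON_RESOURCE = "relation_keywords.tsv"

# note: "bound" is a lemma of its own in the table (distinct from "bind"),
# so the past tense "bound" resolves to it rather than to "bind".
_EXCEPTIONS: dict[str, str] = {
    "bound": "bound",
    "induction": "induce",
    "reduction": "reduce",
    "cleavage": "cleave",
    "recognition": "recognize",
    "interference": "interfere",
    "catalysis": "catalyze",
    "catalyses": "catalyze",
    "response": "response",
    "responses": "response",
}

_SUFFIXES = (
    "ations",
    "ation",
    "ating",
    "ated",
    "ates",
    "ings",
    "ions",
    "ion",
    "ate",
    "ing",
    "ies",
    "ied",
    "ed",
    "es",
    "s",
)

_VOWELS = set("aeiou")


def normalize_form(word: str) -> str:
    """Deterministic stem used on both lexicon lemmas and input tokens.

    Strips one inflectional/derivational suffix, drops a trailing "e",
    and undoubles a final doubled consonant, so that e.g. "activate",
    "activates", "activated", "activating" and "activation" all reduce
    to the same normal form.
    """
    w = word.lower()
    for suf in _SUFFIXES:
        if suf == "s" and w.endswith("ss"):
            continue
        if w.endswith(suf) and len(w) - len(suf) >= 3:
            w = w[: -len(suf)]
            break
    if w.endswith("e"):
        w = w[:-1]
    if len(w) >= 4 and w[-1] == w[-2] and w[-1] not in _VOWELS:
        w = w[:-1]
    return w


@dataclass(frozen=True)
class KeywordMatch:
    token_index: int
    lemma: str
    category: str


@dataclass
class RelationLexicon:
    """Relation lemmas with categories plus the derived-form index."""

    entries: dict[str, str]
    exceptions: dict[str, str] = field(default_factory=lambda: dict(_EXCEPTIONS))
    _stem_map: dict[str, str] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        stem_map: dict[str, str] = {}
        for lemma in self.entries:
            stem = normalize_form(lemma)
            # first lemma wins on (unexpected) stem collisions
            stem_map.setdefault(stem, lemma)
        object.__setattr__(self, "_stem_map", stem_map)

    def __len__(self) -> int:
        return len(self.entries)

    def lookup(self, word: str, lemma: str | None = None) -> str | None:
        """Base lemma for a surface word (and optional parser lemma), or None."""
        for cand in filter(None, (lemma, word)):
            low = cand.lower()
            if low in self.entries:
                return low
            if low in self.exceptions:
                exc = self.exceptions[low]
                return exc if exc in self.entries else None
            hit = self._stem_map.get(normalize_form(low))
            if hit is not None:
                return hit
        return None

    def category_of(self, lemma: str) -> str:
        return self.entries[lemma]

    @property
    def categories(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for cat in self.entries.values():
            counts[cat] = counts.get(cat, 0) + 1
        return counts


def load_lexicon(stream: IO | Path) -> RelationLexicon:
    """Load a ``lemma<TAB>category`` TSV lexicon."""
    if isinstance(stream, (str, Path)):
        with open(stream, encoding="utf-8") as fh:
            return load_lexicon(fh)
    entries: dict[str, str] = {}
    for line in stream:
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        lemma, _, category = line.partition("\t")
        entries[lemma.strip().lower()] = category.strip()
    return RelationLexicon(entries)


def load_default_lexicon() -> RelationLexicon:
    """The packaged 67-keyword interaction lexicon."""
    ref = resources.files("ppirules.data").joinpath(DEFAULT_LEXICON_RESOURCE)
    with ref.open("r", encoding="utf-8") as fh:
        return load_lexicon(fh)


def default_lexicon_sha256() -> str:
    ref = resources.files("ppirules.data").joinpath(DEFAULT_LEXICON_RESOURCE)
    return hashlib.sha256(ref.read_bytes()).hexdigest()


def match_keyword(token, lexicon: RelationLexicon) -> KeywordMatch | None:
    """Match a token (``deps.Token`` or str) against the lexicon.

    Case-insensitive; tries the parser lemma, then the exception table,
    then the shared suffix-stripping normal form.  Returns the base
    lemma and its category, or None.
    """
    if isinstance(token, str):
        text, lemma, index = token, None, -1
    else:
        text, lemma, index = token.text, token.lemma, token.index
    base = lexicon.lookup(text, lemma)
    if base is None:
        return None
    return KeywordMatch(token_index=index, lemma=base, category=lexicon.entries[base])
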