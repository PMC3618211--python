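"""Corpus reading, protein masking, parenthetical stripping, clause splitting."""

import io
import itertools

import pytest
from hypothesis import given, settings, strategies as st

from ppirules.corpus import (
    AnnotatedSentence,
    enumerate_candidates,
    from_jsonl,
    mask_proteins,
    read_ppi_corpus,
    read_standoff,
    split_clauses,
    strip_parentheticals,
    strip_sentence_parentheticals,
    to_jsonl,
    tokenize,
    unmask,
    write_ppi_corpus,
)
from ppirules.errors import CorpusIntegrityError, CorpusParseError, NormalizationError
from ppirules.fixtures import SynthConfig, build_sentence, generate_corpus


class TestMasking:
    def test_two_protein_sentence(self):
        text = "IL-6 binds gp130"
        masked, mentions = mask_proteins(text, [(0, 4), (11, 16)])
        assert masked == "PROTEIN0 binds PROTEIN1"
        assert [m.surface for m in mentions] == ["IL-6", "gp130"]
        assert [m.mask_label for m in mentions] == ["PROTEIN0", "PROTEIN1"]

    def test_receptor_apposition(self):
        text = "erythropoietin receptor (EPOR)"
        masked, _ = mask_proteins(text, [(0, 14), (25, 29)])
        assert masked == "PROTEIN0 receptor (PROTEIN1)"

    def test_identical_surfaces_get_distinct_labels(self):
        text = "p53 activates p53"
        masked, mentions = mask_proteins(text, [(0, 3), (14, 17)])
        assert masked == "PROTEIN0 activates PROTEIN1"
        assert mentions[0].entity_key == mentions[1].entity_key == "p53"

    def test_labels_follow_order_of_appearance(self):
        text = "abc def ghi"
        masked, mentions = mask_proteins(text, [(8, 11), (0, 3)])
        assert masked == "PROTEIN0 def PROTEIN1"
        assert mentions[0].surface == "abc"

    def test_offsets_recomputed_on_masked_text(self):
        masked, mentions = mask_proteins("IL-6 binds gp130", [(0, 4), (11, 16)])
        for m in mentions:
            a, b = m.char_span
            assert masked[a:b] == m.mask_label

    def test_overlap_rejected(self):
        with pytest.raises(NormalizationError):
            mask_proteins("abcdef", [(0, 4), (2, 6)])

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.data())
    def test_unmask_inverts_mask(self, data):
        words = data.draw(
            st.lists(st.text(alphabet="abcdexyz", min_size=1, max_size=6), min_size=2, max_size=8)
        )
        text = " ".join(words)
        n = data.draw(st.integers(0, min(3, len(words))))
        idx = data.draw(
            st.lists(st.integers(0, len(words) - 1), min_size=n, max_size=n, unique=True)
        )
        spans = []
        pos = 0
        for i, w in enumerate(words):
            if i in idx:
                spans.append((pos, pos + len(w)))
            pos += len(w) + 1
        masked, mentions = mask_proteins(text, spans)
        assert unmask(masked, mentions) == text
        assert sum(1 for t in tokenize(masked) if t.startswith("PROTEIN")) == len(spans)


class TestStripParentheticals:
    def test_removes_proteinless_remark(self):
        assert (
            strip_parentheticals("PROTEIN0 (p53) binds PROTEIN1")
            == "PROTEIN0 binds PROTEIN1"
        )

    def test_keeps_parenthetical_protein(self):
        s = "PROTEIN0 receptor (PROTEIN1)"
        assert strip_parentheticals(s) == s

    @pytest.mark.parametrize(
        "text,expected",
        [
            # the four nesting/protein combinations, checked by hand
            ("a (b (c) d) e", "a e"),
            ("a (b (PROTEIN0) d) e", "a (b (PROTEIN0) d) e"),
            ("a (PROTEIN0 (c) d) e", "a (PROTEIN0 (c) d) e"),
            ("(x) a (PROTEIN0) b (y)", "a (PROTEIN0) b"),
        ],
    )
    def test_nesting_cases(self, text, expected):
        assert strip_parentheticals(text) == expected

    def test_unbalanced_left_literal(self):
        assert strip_parentheticals("a ( b PROTEIN0") == "a ( b PROTEIN0"

    def test_unbalanced_right_literal(self):
        assert strip_parentheticals("a ) b PROTEIN0") == "a ) b PROTEIN0"

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        st.lists(
            st.sampled_from(["PROTEIN0", "PROTEIN1", "word", "(", ")", "x"]),
            min_size=1,
            max_size=12,
        )
    )
    def test_never_deletes_a_protein_token(self, toks):
        text = " ".join(toks)
        out = strip_parentheticals(text)
        for label in ("PROTEIN0", "PROTEIN1"):
            assert out.count(label) == text.count(label)

    def test_sentence_level_offsets_recomputed(self):
        masked, mentions = mask_proteins(
            "TP53 (a tumor suppressor) binds MDM2", [(0, 4), (32, 36)]
        )
        sent = AnnotatedSentence("s0", "raw", masked, tokenize(masked), mentions)
        stripped = strip_sentence_parentheticals(sent)
        assert stripped.masked_text == "PROTEIN0 binds PROTEIN1"
        for m in stripped.mentions:
            a, b = m.char_span
            assert stripped.masked_text[a:b] == m.mask_label


class TestSplitClauses:
    def test_single_clause_identity(self):
        sent = build_sentence("s", "PROTEIN0/PROPN binds/VERB PROTEIN1/PROPN")
        res = split_clauses(sent)
        assert len(res.clauses) == 1 and res.clauses[0] is sent
        assert res.straddling_pairs == []

    def test_coordinated_clauses_split(self):
        sent = build_sentence(
            "s",
            "PROTEIN0/PROPN binds/VERB PROTEIN1/PROPN ,/PUNCT and/CCONJ "
            "PROTEIN2/PROPN inhibits/VERB PROTEIN3/PROPN",
            gold={
                frozenset(("e0", "e1")): True,
                frozenset(("e2", "e3")): True,
                frozenset(("e1", "e2")): False,
            },
        )
        res = split_clauses(sent)
        assert len(res.clauses) == 2
        assert [len(c.mentions) for c in res.clauses] == [2, 2]
        # token conservation: concatenation covers the sentence exactly once
        assert list(
            itertools.chain.from_iterable(c.tokens for c in res.clauses)
        ) == sent.tokens
        # pairs reassigned to their clause; the straddler is dropped and reported
        assert frozenset(("e0", "e1")) in res.clauses[0].gold_pairs
        assert frozenset(("e2", "e3")) in res.clauses[1].gold_pairs
        assert res.straddling_pairs == [frozenset(("e1", "e2"))]

    def test_semicolon_split(self):
        sent = build_sentence(
            "s",
            "PROTEIN0/PROPN binds/VERB PROTEIN1/PROPN ;/PUNCT PROTEIN2/PROPN "
            "is/AUX unrelated/ADJ",
        )
        res = split_clauses(sent)
        assert len(res.clauses) == 2
        # the one-protein clause is no longer an extraction candidate
        assert not res.clauses[1].is_candidate

    def test_no_split_without_second_protein_pair(self):
        sent = build_sentence(
            "s",
            "PROTEIN0/PROPN binds/VERB PROTEIN1/PROPN ,/PUNCT and/CCONJ "
            "degradation/NOUN follows/VERB",
        )
        assert len(split_clauses(sent).clauses) == 1

    def test_disabled(self):
        sent = build_sentence(
            "s",
            "PROTEIN0/PROPN binds/VERB PROTEIN1/PROPN ;/PUNCT PROTEIN2/PROPN "
            "binds/VERB PROTEIN3/PROPN",
        )
        assert len(split_clauses(sent, enabled=False).clauses) == 1


class TestEnumerateCandidates:
    @pytest.mark.parametrize("n", [2, 3, 5])
    def test_pair_count_is_n_choose_2(self, n):
        spec = " ".join(f"PROTEIN{i}/PROPN" for i in range(n))
        sent = build_sentence("s", spec)
        pairs = enumerate_candidates(sent)
        assert len(pairs) == n * (n - 1) // 2
        # brute-force oracle over index pairs, including span counts
        expected = {
            (f"e{i}", f"e{j}", j - i + 1)
            for i in range(n)
            for j in range(i + 1, n)
        }
        got = {
            (p.first.mention_id, p.second.mention_id, p.surface_span_tokens)
            for p in pairs
        }
        assert got == expected

    def test_self_relation_flagged(self):
        sent = build_sentence(
            "s",
            "PROTEIN0/PROPN binds/VERB PROTEIN1/PROPN",
            entity_keys={"PROTEIN0": "same", "PROTEIN1": "same"},
        )
        (pair,) = enumerate_candidates(sent)
        assert pair.is_self_relation


MINIMAL_XML = b"""<?xml version="1.0"?>
<corpus source="t">
 <document id="d1">
  <sentence id="d1.s0" text="IL-6 binds gp130 strongly.">
   <entity id="d1.s0.e0" charOffset="0-3" text="IL-6"/>
   <entity id="d1.s0.e1" charOffset="11-15" text="gp130"/>
   <pair e1="d1.s0.e0" e2="d1.s0.e1" interaction="True"/>
  </sentence>
  <sentence id="d1.s1" text="Only TP53 appears here.">
   <entity id="d1.s1.e0" charOffset="5-8" text="TP53"/>
  </sentence>
 </document>
</corpus>
"""


class TestPPIXML:
    def test_minimal_document(self):
        sents = read_ppi_corpus(io.BytesIO(MINIMAL_XML))
        assert len(sents) == 2
        s0 = sents[0]
        assert s0.masked_text.startswith("PROTEIN0 binds PROTEIN1")
        assert s0.gold_pairs[frozenset(("d1.s0.e0", "d1.s0.e1"))] is True

    def test_single_entity_sentence_flagged_non_candidate(self):
        sents = read_ppi_corpus(io.BytesIO(MINIMAL_XML))
        assert not sents[1].is_candidate
        assert len(sents[1].mentions) == 1

    def test_exhaustive_flag_materializes_negatives(self):
        xml = MINIMAL_XML.replace(
            b'<pair e1="d1.s0.e0" e2="d1.s0.e1" interaction="True"/>', b""
        )
        with_neg = read_ppi_corpus(io.BytesIO(xml), exhaustive_pairs=True)
        assert with_neg[0].gold_pairs == {frozenset(("d1.s0.e0", "d1.s0.e1")): False}
        without = read_ppi_corpus(io.BytesIO(xml), exhaustive_pairs=False)
        assert without[0].gold_pairs == {}

    def test_malformed_xml_names_position(self):
        with pytest.raises(CorpusParseError, match=r"line \d+"):
            read_ppi_corpus(io.BytesIO(b"<corpus><sentence></corpus>"))

    def test_unknown_entity_reference(self):
        xml = MINIMAL_XML.replace(b'e2="d1.s0.e1"', b'e2="nope"')
        with pytest.raises(CorpusIntegrityError, match="nope"):
            read_ppi_corpus(io.BytesIO(xml))

    def test_roundtrip_preserves_spans_and_labels(self):
        corpus = generate_corpus(
            SynthConfig(seed=11, n_positive_relations=4, n_negative_relations=6)
        )
        subset = corpus.sentences[:10]
        buf = io.StringIO()
        write_ppi_corpus(subset, buf)
        buf2 = io.BytesIO(buf.getvalue().encode())
        back = read_ppi_corpus(buf2)
        assert len(back) == len(subset)
        for a, b in zip(subset, back):
            assert a.raw_text == b.raw_text
            assert a.masked_text == b.masked_text
            assert {m.mask_label: m.surface for m in a.mentions} == {
                m.mask_label: m.surface for m in b.mentions
            }
            a_pairs = {
                frozenset(a.mention(x).mask_label for x in p): v
                for p, v in a.gold_pairs.items()
            }
            b_pairs = {
                frozenset(b.mention(x).mask_label for x in p): v
                for p, v in b.gold_pairs.items()
            }
            assert a_pairs == b_pairs


class TestStandoff:
    def test_roundtrip(self):
        text = io.StringIO("s0\tIL-6 binds gp130\n")
        spans = io.StringIO("s0\t0\t4\tIL-6\ns0\t11\t16\tgp130\n")
        (sent,) = read_standoff(text, spans)
        assert sent.masked_text == "PROTEIN0 binds PROTEIN1"

    def test_surface_mismatch(self):
        text = io.StringIO("s0\tIL-6 binds gp130\n")
        spans = io.StringIO("s0\t0\t4\tWRONG\n")
        with pytest.raises(CorpusParseError):
            read_standoff(text, spans)


def test_jsonl_roundtrip(small_corpus):
    buf = io.StringIO()
    to_jsonl(small_corpus.sentences, buf)
    buf.seek(0)
    back = from_jsonl(buf)
    assert back == small_corpus.sentences
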