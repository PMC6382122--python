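import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from temporient import (TemporalLexicon, build_feature_bundle,
                        detect_temporal_keywords, tag_pos, tokenize)
from temporient.features import TokenAnnotation
from temporient.io import EmbeddingTable


class TestTokenize:
    @pytest.mark.parametrize("text,expected", [
        ("Let me change lanes and turn left legally",
         ["let", "me", "change", "lanes", "and", "turn", "left", "legally"]),
        ("", []),
        ("check http://x.co #U17WC @bob!",
         ["check", "<url>", "u17wc", "<user>", "!"]),
        ("Today I have a meeting at night.",
         ["today", "i", "have", "a", "meeting", "at", "night", "."]),
        ("don't stop", ["don't", "stop"]),
    ])
    def test_examples(self, text, expected):
        assert tokenize(text) == expected

    @given(st.text(max_size=80))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_rejoin_stability(self, text):
        tokens = tokenize(text)
        assert tokenize(" ".join(tokens)) == tokens


class TestTagPos:
    def test_irregular_past_tense(self):
        anns = tag_pos(tokenize("he lost all the hopes"))
        by_token = {a.token: a for a in anns}
        assert by_token["lost"].fine_verb_tag == "VBD"
        assert by_token["hopes"].coarse_pos != "verb"

    def test_all_punctuation_has_no_verbs(self):
        anns = tag_pos(["!", "?", "...", ","])
        assert all(a.coarse_pos == "punct" for a in anns)
        assert all(a.fine_verb_tag is None for a in anns)

    def test_conjunction_rule_guards_fine_tagger(self):
        # a tagger claiming a fine verb tag on a non-verb token: the coarse
        # call wins and the fine tag is discarded
        def inconsistent_tagger(tokens):
            return ["noun"] * len(tokens), ["VBD"] * len(tokens)

        anns = tag_pos(["conference"], tagger=inconsistent_tagger)
        assert anns[0].coarse_pos == "noun"
        assert anns[0].fine_verb_tag is None

    @pytest.mark.parametrize("text,token,tag", [
        ("we planned it", "planned", "VBD"),
        ("cup starts in 3 days", "starts", "VBZ"),
        ("she is working late", "working", "VBG"),
        ("has started already", "started", "VBN"),  # perfect, not VBD
        ("they will go", "go", "VB"),
    ])
    def test_suffix_and_context_rules(self, text, token, tag):
        anns = tag_pos(tokenize(text))
        by_token = {a.token: a for a in anns}
        assert by_token[token].fine_verb_tag == tag

    def test_annotation_invariant(self):
        with pytest.raises(ValueError):
            TokenAnnotation(token="x", index=0, coarse_pos="noun",
                            fine_verb_tag="VBD")


class TestTemporalKeywords:
    def test_plan_flagged_future(self, lexicon):
        anns = detect_temporal_keywords(
            tag_pos(tokenize("i have a nice plan for the spring festival")),
            lexicon)
        flagged = {a.token: a.temporal_sense for a in anns
                   if a.is_temporal_keyword}
        assert flagged["plan"] == "future"

    def test_empty_lexicon_flags_nothing(self):
        anns = detect_temporal_keywords(
            tag_pos(tokenize("tomorrow and yesterday")),
            TemporalLexicon(entries={}))
        assert not any(a.is_temporal_keyword for a in anns)

    def test_longest_match_wins(self):
        lex = TemporalLexicon(entries={"spring": "neutral",
                                       "spring festival": "future"})
        anns = detect_temporal_keywords(
            tag_pos(tokenize("at the spring festival tonight")), lex)
        senses = {a.token: a.temporal_sense for a in anns
                  if a.is_temporal_keyword}
        assert senses == {"spring": "future", "festival": "future"}

    def test_multiword_phrase_marks_all_tokens(self, lexicon):
        anns = detect_temporal_keywords(
            tag_pos(tokenize("we met last week")), lexicon)
        flagged = [a.token for a in anns if a.is_temporal_keyword]
        assert flagged == ["last", "week"]

    def test_idempotent(self, lexicon):
        anns = tag_pos(tokenize("plans for tomorrow and yesterday"))
        once = detect_temporal_keywords(anns, lexicon)
        twice = detect_temporal_keywords(once, lexicon)
        assert once == twice


class TestFeatureBundle:
    @staticmethod
    def _embeddings(d=4):
        table = EmbeddingTable(dimension=d)
        for i, w in enumerate(["ran", "jumped", "tomorrow", "dog"]):
            vec = np.zeros(d)
            vec[i % d] = i + 1.0
            table.add(w, vec)
        return table

    def _annotations(self):
        # 2 verbs, 1 temporal keyword, 1 plain noun
        return [
            TokenAnnotation("ran", 0, "verb", "VBD"),
            TokenAnnotation("jumped", 1, "verb", "VBD"),
            TokenAnnotation("tomorrow", 2, "adv", None, True, "future"),
            TokenAnnotation("dog", 3, "noun"),
        ]

    def test_shapes_with_padding(self):
        fb = build_feature_bundle(self._annotations(), self._embeddings(),
                                  max_seq_len=10, cnn_windows=(5, 6, 7))
        assert fb.X.shape == (4, 2)
        assert fb.Y.shape == (4, 1)
        assert fb.E.shape == (4, 7)  # padded to max window
        assert fb.n_content == 3
        assert fb.word_matrix.shape == (4, 10)
        # columns of X/Y are the token embeddings, in order of occurrence
        emb = self._embeddings()
        assert np.array_equal(fb.X[:, 0], emb.get("ran"))
        assert np.array_equal(fb.X[:, 1], emb.get("jumped"))
        assert np.array_equal(fb.Y[:, 0], emb.get("tomorrow"))
        assert np.array_equal(fb.E[:, :3], np.concatenate([fb.X, fb.Y], 1))
        assert np.array_equal(fb.E[:, 3:], np.zeros((4, 4)))

    def test_no_verbs_no_keywords_is_pure_padding(self):
        anns = [TokenAnnotation("dog", 0, "noun")]
        fb = build_feature_bundle(anns, self._embeddings(), 10, (5, 6, 7))
        assert fb.X.shape == (4, 0) and fb.Y.shape == (4, 0)
        assert np.array_equal(fb.E, np.zeros((4, 7)))
        assert fb.n_content == 0

    def test_oov_words_are_zero(self):
        anns = [TokenAnnotation("ghost", 0, "verb", "VBP"),
                TokenAnnotation("spirit", 1, "noun")]
        fb = build_feature_bundle(anns, self._embeddings(), 5, (2,))
        assert np.array_equal(fb.word_matrix, np.zeros((4, 5)))
        assert np.array_equal(fb.X, np.zeros((4, 1)))

    def test_truncation_to_max_seq_len(self):
        anns = [TokenAnnotation("dog", i, "noun") for i in range(8)]
        fb = build_feature_bundle(anns, self._embeddings(), 5, (2,))
        assert fb.word_matrix.shape == (4, 5)

    def test_column_counts_match_annotations(self, lexicon, toy_embeddings):
        from temporient import annotate
        text = "we celebrated yesterday and will plan tomorrow"
        anns = annotate(text, lexicon)
        fb = build_feature_bundle(anns, toy_embeddings, 20, (5, 6, 7))
        n_verbs = sum(a.coarse_pos == "verb" for a in anns)
        n_kw = sum(a.is_temporal_keyword for a in anns)
        assert fb.X.shape[1] == n_verbs
        assert fb.Y.shape[1] == n_kw
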