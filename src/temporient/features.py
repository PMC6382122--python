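"""Tokenization, part-of-speech tagging and word-level feature construction.

The feature channel follows the published design: for each text, the tokens
tagged as verbs form an embedding matrix X (d x k) and the tokens matched by a
temporal keyword lexicon form a matrix Y (d x l); their column-wise
concatenation E = [X | Y] feeds a small convolutional branch alongside the
recurrent sentence encoder.

Tagging is pluggable.  The packaged :class:`RuleBasedTagger` combines
closed-class function-word lists with suffix rules and an irregular-verb
table; it exists so the pipeline runs with no external models, and any
callable with the same signature (token list -> coarse tags, fine verb tags)
can replace it.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from . import lexicons as lx
from .io import EmbeddingTable, TemporalLexicon

# Coarse tagset of the packaged tagger (documented in the README).
COARSE_TAGS = ("verb", "noun", "pron", "det", "adp", "conj", "adj", "adv",
               "num", "punct", "intj", "other")
FINE_VERB_TAGS = ("VB", "VBD", "VBG", "VBN", "VBP", "VBZ")

_TOKEN_RE = re.compile(
    r"<url>|<user>"            # sentinels survive re-tokenization
    r"|https?://\S+|www\.\S+"  # URLs
    r"|@\w+"                   # mentions
    r"|#[a-z0-9_]+"            # hashtags (same alphabet as words)
    r"|[a-z0-9_]+(?:'[a-z0-9_]+)*"  # words, incl. internal apostrophes
    r"|\S"                     # anything else: one char of punctuation
)


def tokenize(text: str) -> list[str]:
    """Lowercase and split a text into tokens.

    URLs become ``<url>``, @mentions become ``<user>``, the ``#`` is stripped
    from hashtag tokens, and punctuation is split off as separate tokens.
    """
    tokens: list[str] = []
    for match in _TOKEN_RE.finditer(text.lower()):
        tok = match.group()
        if tok in ("<url>", "<user>"):
            tokens.append(tok)
        elif tok.startswith(("http://", "https://", "www.")):
            tokens.append("<url>")
        elif tok.startswith("@") and len(tok) > 1:
            tokens.append("<user>")
        elif tok.startswith("#") and len(tok) > 1:
            tokens.append(tok[1:])
        else:
            tokens.append(tok)
    return tokens


@dataclass
class TokenAnnotation:
    token: str
    index: int
    coarse_pos: str
    fine_verb_tag: str | None = None
    is_temporal_keyword: bool = False
    temporal_sense: str | None = None

    def __post_init__(self) -> None:
        if self.fine_verb_tag is not None and self.coarse_pos != "verb":
            raise ValueError("fine verb tag on a non-verb token")
        if self.is_temporal_keyword and self.temporal_sense is None:
            raise ValueError("temporal keyword without a sense")


# ---------------------------------------------------------------------------
# Packaged rule-based tagger
# ---------------------------------------------------------------------------
_DET_LIKE = lx.DETERMINERS | {"my", "your", "his", "her", "its", "our",
                              "their", "whose"}


def _strip_ed(token: str) -> list[str]:
    stems = []
    if token.endswith("ed"):
        base = token[:-2]
        stems += [base, base + "e"]
        if len(base) >= 2 and base[-1] == base[-2]:
            stems.append(base[:-1])          # planned -> plan
        if base.endswith("i"):
            stems.append(base[:-1] + "y")    # tried -> try
    return stems


def _strip_ing(token: str) -> list[str]:
    base = token[:-3]
    stems = [base, base + "e"]
    if len(base) >= 2 and base[-1] == base[-2]:
        stems.append(base[:-1])              # running -> run
    return stems


def _strip_s(token: str) -> list[str]:
    stems = [token[:-1]]
    if token.endswith("es"):
        stems.append(token[:-2])
    if token.endswith("ies"):
        stems.append(token[:-3] + "y")
    return stems


class RuleBasedTagger:
    """Deterministic fallback tagger: function-word lists + suffix rules.

    Returns equal-length lists of coarse tags (see ``COARSE_TAGS``) and fine
    verb subtags (Penn-style VB/VBD/VBG/VBN/VBP/VBZ, or ``None``).  Modals
    are tagged as verbs with no fine subtag.  A one-token left context
    disambiguates the common noun/verb clashes (a token after a determiner
    is never a verb; an -ed form after a have/be auxiliary is a participle).
    """

    def __call__(self, tokens: list[str]
                 ) -> tuple[list[str], list[str | None]]:
        coarse: list[str] = []
        fine: list[str | None] = []
        for i, tok in enumerate(tokens):
            prev = tokens[i - 1] if i > 0 else ""
            c, f = self._tag_one(tok, prev)
            coarse.append(c)
            fine.append(f)
        return coarse, fine

    def _tag_one(self, tok: str, prev: str
                 ) -> tuple[str, str | None]:
        if not any(ch.isalnum() for ch in tok):
            return "punct", None
        if tok.replace(".", "", 1).replace(",", "").isdigit():
            return "num", None
        if tok in ("<url>", "<user>"):
            return "other", None
        after_aux = prev in lx.AUX_HAVE or prev in lx.AUX_BE
        if tok in lx.MODALS:
            return "verb", None
        if tok in lx.AUX_BE or tok in lx.AUX_HAVE or tok in lx.AUX_DO:
            return "verb", _AUX_FINE.get(tok, "VBP")
        if tok in lx.IRREGULAR_VBN:
            return "verb", "VBN"
        if tok in lx.IRREGULAR_VBD:
            return "verb", "VBN" if after_aux else "VBD"
        if tok in lx.IRREGULAR_VBZ and prev not in _DET_LIKE:
            return "verb", "VBZ"
        if tok in lx.PRONOUNS:
            return "pron", None
        if tok in lx.DETERMINERS:
            return "det", None
        if tok in lx.PREPOSITIONS:
            return "adp", None
        if tok in lx.CONJUNCTIONS:
            return "conj", None
        if tok in lx.COMMON_ADVERBS:
            return "adv", None
        if tok in lx.INTERJECTIONS:
            return "intj", None
        if tok.endswith("ed") and len(tok) > 3 and prev not in _DET_LIKE:
            if any(s in lx.VERB_STEMS for s in _strip_ed(tok)) or after_aux:
                return "verb", "VBN" if after_aux else "VBD"
        if tok.endswith("ing") and len(tok) > 4:
            if (any(s in lx.VERB_STEMS for s in _strip_ing(tok))
                    or prev in lx.AUX_BE):
                return "verb", "VBG"
        if (tok.endswith("s") and not tok.endswith("ss") and len(tok) > 2
                and prev not in _DET_LIKE
                and any(s in lx.VERB_STEMS for s in _strip_s(tok))):
            return "verb", "VBZ"
        if tok in lx.VERB_STEMS and prev not in _DET_LIKE:
            if prev == "to" or prev in lx.MODALS or prev in lx.AUX_DO:
                return "verb", "VB"
            return "verb", "VBP"
        return "noun", None


_AUX_FINE = {
    "am": "VBP", "is": "VBZ", "isnt": "VBZ", "isn't": "VBZ",
    "are": "VBP", "arent": "VBP", "aren't": "VBP",
    "was": "VBD", "wasnt": "VBD", "wasn't": "VBD",
    "were": "VBD", "werent": "VBD", "weren't": "VBD",
    "be": "VB", "been": "VBN", "being": "VBG",
    "have": "VBP", "havent": "VBP", "haven't": "VBP",
    "has": "VBZ", "hasnt": "VBZ", "hasn't": "VBZ",
    "had": "VBD", "hadnt": "VBD", "hadn't": "VBD", "having": "VBG",
    "do": "VBP", "dont": "VBP", "don't": "VBP",
    "does": "VBZ", "doesnt": "VBZ", "doesn't": "VBZ",
    "did": "VBD", "didnt": "VBD", "didn't": "VBD",
}

DEFAULT_TAGGER = RuleBasedTagger()


def tag_pos(tokens: list[str], tagger=None) -> list[TokenAnnotation]:
    """Annotate tokens with coarse PoS and fine verb subtags.

    A token counts as a verb only when the coarse tagger says so; the fine
    verb subtag is kept only for those tokens (guard against fine-tagger
    false positives).
    """
    tagger = tagger if tagger is not None else DEFAULT_TAGGER
    coarse, fine = tagger(tokens)
    if len(coarse) != len(tokens) or len(fine) != len(tokens):
        raise ValueError("tagger output length does not match token count")
    annotations = []
    for i, tok in enumerate(tokens):
        is_verb = coarse[i] == "verb"
        annotations.append(TokenAnnotation(
            token=tok, index=i, coarse_pos=coarse[i],
            fine_verb_tag=fine[i] if is_verb else None))
    return annotations


def detect_temporal_keywords(annotations: list[TokenAnnotation],
                             lexicon: TemporalLexicon
                             ) -> list[TokenAnnotation]:
    """Flag tokens covered by lexicon entries (longest match wins).

    Matching is case-insensitive on token boundaries; a multiword phrase
    marks all of its tokens with the phrase's sense.  Idempotent — flags are
    recomputed from scratch each call.
    """
    max_len = lexicon.max_phrase_len()
    tokens = [a.token.lower() for a in annotations]
    senses: list[str | None] = [None] * len(tokens)
    i = 0
    while i < len(tokens):
        matched = 0
        sense = None
        for n in range(min(max_len, len(tokens) - i), 0, -1):
            phrase = " ".join(tokens[i:i + n])
            if phrase in lexicon.entries:
                matched, sense = n, lexicon.entries[phrase]
                break
        if matched:
            for j in range(i, i + matched):
                senses[j] = sense
            i += matched
        else:
            i += 1
    out = []
    for a, sense in zip(annotations, senses):
        out.append(TokenAnnotation(
            token=a.token, index=a.index, coarse_pos=a.coarse_pos,
            fine_verb_tag=a.fine_verb_tag,
            is_temporal_keyword=sense is not None, temporal_sense=sense))
    return out


def annotate(text: str, lexicon: TemporalLexicon,
             tagger=None) -> list[TokenAnnotation]:
    """tokenize -> tag_pos -> detect_temporal_keywords in one call."""
    return detect_temporal_keywords(tag_pos(tokenize(text), tagger), lexicon)


# ---------------------------------------------------------------------------
# Feature bundle
# ---------------------------------------------------------------------------
@dataclass
class FeatureBundle:
    """Embedding matrices for one text.

    ``word_matrix`` is d x N (N = max_seq_len, zero-padded/truncated);
    ``X`` is d x k over the verb tokens, ``Y`` is d x l over the temporal
    keyword tokens, and ``E = [X | Y]`` zero-padded along the token axis to
    at least the largest convolution window.  ``n_content`` records k + l so
    pooling can ignore pure-padding windows.
    """

    word_matrix: np.ndarray
    X: np.ndarray
    Y: np.ndarray
    E: np.ndarray
    n_content: int


def default_temporal_lexicon() -> TemporalLexicon:
    """The packaged temporal keyword lexicon (replaceable stand-in)."""
    return TemporalLexicon(entries=dict(lx.DEFAULT_TEMPORAL_LEXICON))


def build_feature_bundle(annotations: list[TokenAnnotation],
                         embeddings: EmbeddingTable,
                         max_seq_len: int = 50,
                         cnn_windows: tuple[int, ...] = (5, 6, 7)
                         ) -> FeatureBundle:
    """Assemble word, verb (X) and temporal-keyword (Y) embedding matrices.

    Out-of-vocabulary words map to the zero vector.  A word that is both a
    verb and a temporal keyword contributes a column to both X and Y.
    """
    d = embeddings.dimension
    word_matrix = np.zeros((d, max_seq_len))
    for a in annotations[:max_seq_len]:
        word_matrix[:, a.index] = embeddings.get(a.token)

    verb_cols = [embeddings.get(a.token) for a in annotations
                 if a.coarse_pos == "verb"]
    kw_cols = [embeddings.get(a.token) for a in annotations
               if a.is_temporal_keyword]
    X = (np.column_stack(verb_cols) if verb_cols
         else np.zeros((d, 0)))
    Y = (np.column_stack(kw_cols) if kw_cols
         else np.zeros((d, 0)))
    n_content = X.shape[1] + Y.shape[1]
    min_len = max(cnn_windows)
    width = max(n_content, min_len)
    E = np.zeros((d, width))
    if n_content:
        E[:, :n_content] = np.concatenate([X, Y], axis=1)
    return FeatureBundle(word_matrix=word_matrix, X=X, Y=Y, E=E,
                         n_content=n_content)
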