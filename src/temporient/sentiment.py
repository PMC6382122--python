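"""Pluggable sentiment valence: positive / negative / neutral.

The published pipeline used a pre-trained SemEval-2013 tweet sentiment model;
here sentiment is an interface (any callable text -> class) with a packaged
lexicon-based default: sum token polarities, flipping the sign when a negator
occurs within the three preceding tokens.
"""

from __future__ import annotations

from .features import tokenize
from .io import SENTIMENT_CLASSES
from .lexicons import NEGATORS, SENTIMENT_POLARITY

_NEGATION_WINDOW = 3


def default_sentiment(text: str,
                      polarity: dict[str, int] | None = None) -> str:
    """Lexicon score with negation flip; ties (score 0) are neutral."""
    polarity = polarity if polarity is not None else SENTIMENT_POLARITY
    tokens = tokenize(text)
    score = 0
    for i, tok in enumerate(tokens):
        pol = polarity.get(tok)
        if pol is None:
            continue
        window = tokens[max(0, i - _NEGATION_WINDOW):i]
        if any(t in NEGATORS for t in window):
            pol = -pol
        score += pol
    if score > 0:
        return "positive"
    if score < 0:
        return "negative"
    return "neutral"


class LexiconSentimentClassifier:
    """Estimator-style wrapper around :func:`default_sentiment`.

    Rule-based, so ``fit`` is a no-op kept for pipeline compatibility.
    """

    classes_ = SENTIMENT_CLASSES

    def __init__(self, polarity: dict[str, int] | None = None):
        self.polarity = polarity

    def fit(self, X=None, y=None):
        return self

    def predict(self, X) -> list[str]:
        return [self(t if isinstance(t, str) else t.text) for t in X]

    def __call__(self, text: str) -> str:
        return default_sentiment(text, self.polarity)
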