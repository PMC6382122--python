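"""User-level time-perspective profiles.

Unidimensional TP: the proportion of a user's tweets classified into each
temporal class,

    orientation_t(user) = |tweets_t(user)| / |tweets_all(user)|.

Bidimensional TP crosses temporal orientation with sentiment valence: within
each temporal class t having at least one tweet,

    orientation_{s,t}(user) = |tweets_{s,t}(user)| / |tweets_t(user)|.

A temporal class with zero tweets has *undefined* (None) bidimensional
entries, never 0/0 rendered as zero; downstream correlations drop undefined
pairs pairwise.
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass, field

from .io import SENTIMENT_CLASSES, TEMPORAL_CLASSES, Tweet
from .sentiment import default_sentiment


@dataclass
class UserTPProfile:
    """Unidimensional and bidimensional TP proportions for one user."""

    user_id: str
    n_tweets: int
    counts: dict[str, int]
    uni: dict[str, float]
    bi: dict[tuple[str, str], float | None]

    def __post_init__(self) -> None:
        if self.n_tweets >= 1:
            total = sum(self.uni[t] for t in TEMPORAL_CLASSES)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"user {self.user_id}: uni proportions sum to {total}")
        for t in TEMPORAL_CLASSES:
            defined = [self.bi[(t, s)] for s in SENTIMENT_CLASSES
                       if self.bi[(t, s)] is not None]
            if self.counts.get(t, 0) >= 1:
                if len(defined) != len(SENTIMENT_CLASSES):
                    raise ValueError(
                        f"user {self.user_id}: class {t} has tweets but "
                        f"undefined bi entries")
                if abs(sum(defined) - 1.0) > 1e-9:
                    raise ValueError(
                        f"user {self.user_id}: bi proportions for {t} sum "
                        f"to {sum(defined)}")
            elif defined:
                raise ValueError(
                    f"user {self.user_id}: class {t} empty but bi defined")

    @property
    def defined(self) -> bool:
        return self.n_tweets >= 1


def _labels_for(user_tweets: list[Tweet], model, labels) -> list[str]:
    if labels == "gold":
        missing = [t.tweet_id for t in user_tweets if t.gold_label is None]
        if missing:
            raise ValueError(f"tweets without gold labels: {missing[:5]}")
        return [t.gold_label for t in user_tweets]
    if model is None:
        raise ValueError("a fitted model is required unless labels='gold'")
    return list(model.predict([t.text for t in user_tweets]))


def unidimensional_profile(user_tweets: list[Tweet], model=None,
                           labels: str = "model") -> dict[str, float]:
    """Per-class tweet proportions for one user; needs >= 1 tweet."""
    if not user_tweets:
        raise ValueError("unidimensional profile of zero tweets is undefined")
    pred = _labels_for(user_tweets, model, labels)
    n = len(pred)
    return {t: pred.count(t) / n for t in TEMPORAL_CLASSES}


def bidimensional_profile(user_tweets: list[Tweet], model=None,
                          sentiment_fn=None, labels: str = "model"
                          ) -> dict[tuple[str, str], float | None]:
    """Sentiment proportions conditional on each non-empty temporal class."""
    if not user_tweets:
        raise ValueError("bidimensional profile of zero tweets is undefined")
    sentiment_fn = sentiment_fn if sentiment_fn is not None else default_sentiment
    pred = _labels_for(user_tweets, model, labels)
    if labels == "gold":
        sent = [t.gold_sentiment if t.gold_sentiment is not None
                else sentiment_fn(t.text) for t in user_tweets]
    else:
        sent = [sentiment_fn(t.text) for t in user_tweets]
    bi: dict[tuple[str, str], float | None] = {}
    for t in TEMPORAL_CLASSES:
        idx = [i for i, lab in enumerate(pred) if lab == t]
        if not idx:
            for s in SENTIMENT_CLASSES:
                bi[(t, s)] = None
            continue
        for s in SENTIMENT_CLASSES:
            bi[(t, s)] = sum(1 for i in idx if sent[i] == s) / len(idx)
    return bi


def profile_user(user_id: str, user_tweets: list[Tweet], model=None,
                 sentiment_fn=None, labels: str = "model") -> UserTPProfile:
    pred = _labels_for(user_tweets, model, labels)
    counts = {t: pred.count(t) for t in TEMPORAL_CLASSES}
    uni = {t: counts[t] / len(pred) for t in TEMPORAL_CLASSES}
    # reuse the predicted labels rather than predicting twice
    sentiment_fn = sentiment_fn if sentiment_fn is not None else default_sentiment
    if labels == "gold":
        sent = [t.gold_sentiment if t.gold_sentiment is not None
                else sentiment_fn(t.text) for t in user_tweets]
    else:
        sent = [sentiment_fn(t.text) for t in user_tweets]
    bi: dict[tuple[str, str], float | None] = {}
    for t in TEMPORAL_CLASSES:
        idx = [i for i, lab in enumerate(pred) if lab == t]
        for s in SENTIMENT_CLASSES:
            bi[(t, s)] = (sum(1 for i in idx if sent[i] == s) / len(idx)
                          if idx else None)
    return UserTPProfile(user_id=user_id, n_tweets=len(user_tweets),
                         counts=counts, uni=uni, bi=bi)


def profile_users(tweets: list[Tweet], model=None, sentiment_fn=None,
                  labels: str = "model") -> list[UserTPProfile]:
    """Group tweets by user_id (first-seen order) and profile each user.

    Users with zero tweets cannot occur by construction; callers joining
    against attribute tables drop users absent here.
    """
    by_user: "OrderedDict[str, list[Tweet]]" = OrderedDict()
    for tw in tweets:
        by_user.setdefault(tw.user_id, []).append(tw)
    return [profile_user(uid, tws, model, sentiment_fn, labels)
            for uid, tws in by_user.items()]
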