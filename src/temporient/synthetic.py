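"""Synthetic data: cue-planted tweets, toy embeddings, and user cohorts.

The generator emulates the structure of the study corpus with zero
downloads: every tweet carries gold temporal and sentiment labels; class
identity is signaled (with probability ``cue_strength``) by a cue token from
disjoint per-class vocabularies that include a tense-marked verb (past: a
VBD form; present: VBZ/VBG forms; future: the modal "will" or a temporal
keyword), plus a class-consistent hashtag so the weak-labeling pipeline can
run end to end.  The default class mixture (0.32/0.22/0.46) and per-class
sentiment mixtures follow the population means reported for the large
Twitter cohort the method was applied to.

User cohorts draw each user's latent TP mixture from a Dirichlet centered
on the class mixture, then generate attributes as linear functions of a
chosen realized TP dimension plus Gaussian noise calibrated analytically so
the population correlation equals the requested rho.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import (EmbeddingTable, TEMPORAL_CLASSES, SENTIMENT_CLASSES, Tweet)

# Disjoint per-class cue vocabularies.  Present/future cues deliberately
# avoid simple-past (VBD) forms so the two-pass tense filter keeps them;
# "starts"/"days" make present-tense future reference ("starts in 3 days")
# part of the planted signal, mirroring the tense-vs-time mismatch the
# classifier exists to resolve.
PAST_CUES = ("finished", "visited", "missed", "celebrated", "yesterday",
             "ago", "memories")
PRESENT_CUES = ("happening", "working", "playing", "goes", "today", "now",
                "currently")
FUTURE_CUES = ("will", "tomorrow", "soon", "upcoming", "plan", "starts",
               "days")
CUES = {"past": PAST_CUES, "present": PRESENT_CUES, "future": FUTURE_CUES}

# Every tweet carries one tenseless base verb so pass 1 (verb filter) is
# satisfied even at cue_strength 0.
BASE_VERBS = ("enjoy", "like", "see", "want", "need")

FILLER_WORDS = ("coffee", "music", "city", "friends", "sunshine", "river",
                "garden", "football", "pizza", "photo", "street", "cloud",
                "window", "travel", "book", "beach", "mountain", "dinner",
                "train", "market", "colors", "weather", "crowd", "silence",
                "bridge", "festival", "lights", "corner", "journey", "story")

POSITIVE_CUES = ("love", "happy", "awesome")
NEGATIVE_CUES = ("hate", "sad", "terrible")
SENTIMENT_CUES = {"positive": POSITIVE_CUES, "negative": NEGATIVE_CUES,
                  "neutral": ()}

HASHTAGS = {"past": ("throwback", "memorylane"),
            "present": ("happeningnow", "liveupdate"),
            "future": ("u17wc", "comingsoon")}

# Population means reported for the large observed cohort; used here as the
# generator's target mixtures.
DEFAULT_CLASS_MIXTURE = (0.32, 0.22, 0.46)
DEFAULT_SENTIMENT_MIXTURES = {
    "past": (0.35, 0.21, 0.44),
    "present": (0.36, 0.15, 0.49),
    "future": (0.38, 0.11, 0.51),
}


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic corpus / cohort generator."""

    n_users: int = 100
    n_tweets_per_user: int = 30
    class_mixture: tuple[float, float, float] = DEFAULT_CLASS_MIXTURE
    sentiment_mixtures: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_SENTIMENT_MIXTURES))
    cue_strength: float = 1.0
    attribute_correlations: dict[str, tuple[str, float]] = field(
        default_factory=lambda: {"age": ("past", 0.47)})
    embedding_dim: int = 16
    dirichlet_concentration: float = 10.0
    seed: int = 42

    def __post_init__(self) -> None:
        if abs(sum(self.class_mixture) - 1.0) > 1e-9:
            raise ValueError("class mixture must sum to 1")
        for cls, mix in self.sentiment_mixtures.items():
            if abs(sum(mix) - 1.0) > 1e-9:
                raise ValueError(f"sentiment mixture for {cls} must sum to 1")
        if not 0.0 <= self.cue_strength <= 1.0:
            raise ValueError("cue_strength must be in [0, 1]")
        for attr, (dim, rho) in self.attribute_correlations.items():
            if dim not in TEMPORAL_CLASSES:
                raise ValueError(f"{attr}: unknown TP dimension {dim!r}")
            if not -1.0 < rho < 1.0:
                raise ValueError(f"{attr}: |rho| must be < 1")
        if self.embedding_dim < 2:
            raise ValueError("embedding_dim must be >= 2")

    def to_dict(self) -> dict:
        return {"n_users": self.n_users,
                "n_tweets_per_user": self.n_tweets_per_user,
                "class_mixture": list(self.class_mixture),
                "sentiment_mixtures": {k: list(v) for k, v in
                                       self.sentiment_mixtures.items()},
                "cue_strength": self.cue_strength,
                "attribute_correlations": {k: [d, r] for k, (d, r) in
                                           self.attribute_correlations.items()},
                "embedding_dim": self.embedding_dim,
                "dirichlet_concentration": self.dirichlet_concentration,
                "seed": self.seed}


def null_spec(seed: int = 42, **overrides) -> SyntheticSpec:
    """A no-class-signal spec for chance-level controls.

    Cue strength 0 alone does not remove all class signal: an imbalanced
    class mixture and class-dependent sentiment mixtures still let a
    classifier beat 1/3.  The null condition therefore also uses a uniform
    class mixture and class-independent sentiment.
    """
    uniform = (1.0 / 3.0, 1.0 / 3.0, 1.0 / 3.0)
    kwargs = dict(cue_strength=0.0, class_mixture=uniform,
                  sentiment_mixtures={c: uniform for c in TEMPORAL_CLASSES},
                  seed=seed)
    kwargs.update(overrides)
    return SyntheticSpec(**kwargs)


def synthetic_vocabulary() -> list[str]:
    """Every word the generator can emit (cues, fillers, verbs, hashtags)."""
    vocab: list[str] = []
    for words in (PAST_CUES, PRESENT_CUES, FUTURE_CUES, BASE_VERBS,
                  FILLER_WORDS, POSITIVE_CUES, NEGATIVE_CUES):
        vocab.extend(words)
    for tags in HASHTAGS.values():
        vocab.extend(tags)
    seen = set()
    out = []
    for w in vocab:
        if w not in seen:
            seen.add(w)
            out.append(w)
    return out


def synthetic_hashtag_map() -> dict[str, str]:
    return {tag: cls for cls, tags in HASHTAGS.items() for tag in tags}


def _make_text(cls: str, sentiment: str, cue: bool,
               rng: np.random.Generator) -> str:
    n_filler = int(rng.integers(4, 8))
    tokens = list(rng.choice(FILLER_WORDS, size=n_filler, replace=False))
    tokens.insert(int(rng.integers(0, len(tokens) + 1)),
                  str(rng.choice(BASE_VERBS)))
    if cue:
        tokens.insert(int(rng.integers(0, len(tokens) + 1)),
                      str(rng.choice(CUES[cls])))
    s_cues = SENTIMENT_CUES[sentiment]
    if s_cues:
        tokens.insert(int(rng.integers(0, len(tokens) + 1)),
                      str(rng.choice(s_cues)))
    return " ".join(tokens)


def _one_tweet(tweet_id: str, user_id: str, cls: str,
               spec: SyntheticSpec, rng: np.random.Generator) -> Tweet:
    sentiment = SENTIMENT_CLASSES[
        rng.choice(3, p=np.asarray(spec.sentiment_mixtures[cls]))]
    cue = bool(rng.random() < spec.cue_strength)
    text = _make_text(cls, sentiment, cue, rng)
    hashtag = str(rng.choice(HASHTAGS[cls]))
    return Tweet(tweet_id=tweet_id, user_id=user_id, text=text,
                 hashtags=[hashtag], gold_label=cls,
                 gold_sentiment=sentiment)


def generate_tweets(n: int, spec: SyntheticSpec | None = None,
                    rng: np.random.Generator | None = None,
                    user_id: str = "u0") -> list[Tweet]:
    """Generate ``n`` labeled tweets from the spec's class mixture."""
    spec = spec if spec is not None else SyntheticSpec()
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    mixture = np.asarray(spec.class_mixture)
    classes = rng.choice(3, size=n, p=mixture)
    return [_one_tweet(f"t{i:06d}", user_id, TEMPORAL_CLASSES[classes[i]],
                       spec, rng) for i in range(n)]


def generate_embeddings(vocab: list[str] | None = None, d: int = 16,
                        seed: int | np.random.Generator = 0
                        ) -> EmbeddingTable:
    """Unit-norm random vectors covering the synthetic vocabulary."""
    if d < 2:
        raise ValueError("embedding dimension must be >= 2")
    vocab = vocab if vocab is not None else synthetic_vocabulary()
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    table = EmbeddingTable(dimension=d)
    for word in vocab:
        vec = rng.standard_normal(d)
        table.add(word, vec / np.linalg.norm(vec))
    return table


def generate_user_cohort(spec: SyntheticSpec | None = None,
                         rng: np.random.Generator | None = None
                         ) -> tuple[list[Tweet], pd.DataFrame]:
    """Users with heterogeneous TP mixtures and correlated attributes.

    Each user's TP mixture is Dirichlet(concentration * class_mixture); the
    named attribute equals rho * z + sqrt(1 - rho^2) * noise where z is the
    user's standardized realized TP proportion, so the population
    correlation is exactly rho (up to sampling noise).  Attributes named
    "age" are mapped affinely to a plausible year scale; affine maps leave
    correlations unchanged.
    """
    spec = spec if spec is not None else SyntheticSpec()
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    alpha = spec.dirichlet_concentration * np.asarray(spec.class_mixture)
    tweets: list[Tweet] = []
    realized = {t: np.zeros(spec.n_users) for t in TEMPORAL_CLASSES}
    counter = 0
    for u in range(spec.n_users):
        uid = f"user{u:05d}"
        mix = rng.dirichlet(alpha)
        classes = rng.choice(3, size=spec.n_tweets_per_user, p=mix)
        for c in classes:
            cls = TEMPORAL_CLASSES[c]
            tweets.append(_one_tweet(f"t{counter:07d}", uid, cls, spec, rng))
            counter += 1
        for t_i, t in enumerate(TEMPORAL_CLASSES):
            realized[t][u] = np.mean(classes == t_i)

    attrs: dict[str, np.ndarray] = {
        "user_id": np.array([f"user{u:05d}" for u in range(spec.n_users)])}
    for attr, (dim, rho) in spec.attribute_correlations.items():
        vals = realized[dim]
        sd = vals.std(ddof=0)
        if sd == 0:
            raise ValueError(f"TP dimension {dim!r} is constant across the "
                             f"cohort; cannot plant a correlation")
        z = (vals - vals.mean()) / sd
        noise = rng.standard_normal(spec.n_users)
        raw = rho * z + np.sqrt(1.0 - rho ** 2) * noise
        if attr == "age":
            raw = 35.0 + 12.0 * raw
        attrs[attr] = raw
    return tweets, pd.DataFrame(attrs)
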