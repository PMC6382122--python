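"""Readers and writers for the on-disk formats.

Tweets travel as JSONL (one object per line), embeddings as GloVe-style
whitespace-separated text, the temporal lexicon as a two-column TSV,
hashtag->class maps, user profiles, attributes and correlation reports as CSV.
Readers are tolerant of content-level noise (emoji, mixed scripts) and strict
about structural violations.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .lexicons import TEMPORAL_SENSES

logger = logging.getLogger(__name__)

TEMPORAL_CLASSES = ("past", "present", "future")
SENTIMENT_CLASSES = ("positive", "negative", "neutral")
GOLD_LABELS = TEMPORAL_CLASSES + ("other",)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------
@dataclass
class Tweet:
    """A single short text with metadata and optional gold labels."""

    tweet_id: str
    user_id: str
    text: str
    hashtags: list[str] = field(default_factory=list)
    timestamp: str | None = None
    gold_label: str | None = None
    gold_sentiment: str | None = None

    def __post_init__(self) -> None:
        if not self.text or not self.text.strip():
            raise ValueError(f"tweet {self.tweet_id!r}: empty text")
        self.hashtags = [h.lstrip("#").lower() for h in self.hashtags]
        if any(not h or "#" in h for h in self.hashtags):
            raise ValueError(f"tweet {self.tweet_id!r}: malformed hashtag")
        if self.gold_label is not None and self.gold_label not in GOLD_LABELS:
            raise ValueError(
                f"tweet {self.tweet_id!r}: gold_label {self.gold_label!r} "
                f"not in {GOLD_LABELS}")
        if (self.gold_sentiment is not None
                and self.gold_sentiment not in SENTIMENT_CLASSES):
            raise ValueError(
                f"tweet {self.tweet_id!r}: gold_sentiment "
                f"{self.gold_sentiment!r} not in {SENTIMENT_CLASSES}")

    def to_json(self) -> dict:
        d = {"tweet_id": self.tweet_id, "user_id": self.user_id,
             "text": self.text, "hashtags": list(self.hashtags)}
        for key in ("timestamp", "gold_label", "gold_sentiment"):
            val = getattr(self, key)
            if val is not None:
                d[key] = val
        return d


@dataclass
class EmbeddingTable:
    """Case-folded word -> dense vector lookup of fixed dimension.

    Unknown words resolve to the all-zero vector (deterministic OOV policy).
    """

    dimension: int
    _table: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.dimension < 1:
            raise ValueError("embedding dimension must be positive")

    def __len__(self) -> int:
        return len(self._table)

    def __contains__(self, word: str) -> bool:
        return word.lower() in self._table

    def add(self, word: str, vector: np.ndarray) -> None:
        vector = np.asarray(vector, dtype=np.float64)
        if vector.shape != (self.dimension,):
            raise ValueError(
                f"vector for {word!r} has length {vector.size}, "
                f"expected {self.dimension}")
        self._table.setdefault(word.lower(), vector)

    def get(self, word: str) -> np.ndarray:
        """Vector for ``word`` (case-folded); all-zero vector if unknown."""
        vec = self._table.get(word.lower())
        if vec is None:
            return np.zeros(self.dimension)
        return vec

    def words(self) -> list[str]:
        return list(self._table)


@dataclass
class TemporalLexicon:
    """Map from lowercase word/phrase to a time-sense tag."""

    entries: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, sense in self.entries.items():
            if not key or key != key.lower():
                raise ValueError(f"lexicon key {key!r} must be non-empty lowercase")
            if sense not in TEMPORAL_SENSES:
                raise ValueError(
                    f"lexicon entry {key!r}: unknown sense tag {sense!r}")

    def __len__(self) -> int:
        return len(self.entries)

    def max_phrase_len(self) -> int:
        if not self.entries:
            return 0
        return max(len(k.split()) for k in self.entries)


# ---------------------------------------------------------------------------
# Tweets (JSONL)
# ---------------------------------------------------------------------------
_TWEET_FIELDS = {"tweet_id", "user_id", "text", "hashtags", "timestamp",
                 "gold_label", "gold_sentiment"}


def read_tweets_jsonl(path: str | Path, *, with_stats: bool = False):
    """Read tweets from a JSONL file, skipping malformed lines with a warning.

    Returns the list of tweets, or ``(tweets, n_skipped)`` when
    ``with_stats`` is true.  Raises ``OSError`` if the file is unreadable.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"tweet file not found: {path}")
    tweets: list[Tweet] = []
    skipped = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
                kwargs = {k: v for k, v in obj.items() if k in _TWEET_FIELDS}
                tweets.append(Tweet(**kwargs))
            except (json.JSONDecodeError, TypeError, ValueError) as exc:
                skipped += 1
                logger.warning("%s:%d skipped malformed line (%s)",
                               path, lineno, exc)
    logger.info("read %d tweets from %s (%d lines skipped)",
                len(tweets), path, skipped)
    if with_stats:
        return tweets, skipped
    return tweets


def write_tweets_jsonl(tweets: Iterable[Tweet], path: str | Path,
                       extra: Sequence[dict] | None = None) -> None:
    """Write tweets as JSONL; ``extra`` merges per-tweet fields (predictions)."""
    tweets = list(tweets)
    if extra is not None and len(extra) != len(tweets):
        raise ValueError("extra must align with tweets")
    with open(path, "w", encoding="utf-8") as fh:
        for i, tw in enumerate(tweets):
            obj = tw.to_json()
            if extra is not None:
                obj.update(extra[i])
            fh.write(json.dumps(obj, ensure_ascii=False) + "\n")


# ---------------------------------------------------------------------------
# Embeddings (GloVe-style text)
# ---------------------------------------------------------------------------
def read_embeddings(path: str | Path,
                    expected_d: int | None = None) -> EmbeddingTable:
    """Read a GloVe-style text embedding file.

    Each line is ``word v1 v2 ... vd``.  The dimension is inferred from the
    first line (or enforced when ``expected_d`` is given); a line with the
    wrong arity is a fatal error naming the line number.  Duplicate words
    keep their first occurrence; lookups are case-folded.
    """
    path = Path(path)
    table: EmbeddingTable | None = None
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.rstrip("\n").split()
            if not parts:
                continue
            word, values = parts[0], parts[1:]
            if table is None:
                d = expected_d if expected_d is not None else len(values)
                if d < 1:
                    raise ValueError(f"{path}:{lineno}: no vector components")
                table = EmbeddingTable(dimension=d)
            if len(values) != table.dimension:
                raise ValueError(
                    f"{path}:{lineno}: expected {table.dimension} components, "
                    f"got {len(values)}")
            try:
                vec = np.array([float(v) for v in values])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            table.add(word, vec)
    if table is None:
        if expected_d is None:
            raise ValueError(f"{path}: empty embedding file")
        table = EmbeddingTable(dimension=expected_d)
    logger.info("read %d embeddings (d=%d) from %s",
                len(table), table.dimension, path)
    return table


def write_embeddings(table: EmbeddingTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for word in table.words():
            vec = table.get(word)
            fh.write(word + " " + " ".join(f"{v:.8g}" for v in vec) + "\n")


# ---------------------------------------------------------------------------
# Temporal lexicon (TSV)
# ---------------------------------------------------------------------------
def read_lexicon_tsv(path: str | Path) -> TemporalLexicon:
    """Read ``word<TAB>sense`` lines; unknown sense tags are fatal."""
    entries: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 'word<TAB>sense'")
            word, sense = parts[0].strip().lower(), parts[1].strip().lower()
            if sense not in TEMPORAL_SENSES:
                raise ValueError(
                    f"{path}:{lineno}: unknown sense tag {sense!r} "
                    f"for {word!r}")
            entries.setdefault(word, sense)
    return TemporalLexicon(entries=entries)


def write_lexicon_tsv(lexicon: TemporalLexicon, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for word, sense in lexicon.entries.items():
            fh.write(f"{word}\t{sense}\n")


# ---------------------------------------------------------------------------
# Hashtag -> class map (CSV)
# ---------------------------------------------------------------------------
def read_hashtag_map_csv(path: str | Path) -> dict[str, str]:
    """Two-column CSV ``hashtag,class`` -> dict; classes validated."""
    df = pd.read_csv(path, dtype=str)
    cols = [c.lower() for c in df.columns]
    if cols[:2] != ["hashtag", "class"]:
        raise ValueError(f"{path}: expected columns 'hashtag,class'")
    entries: dict[str, str] = {}
    for tag, cls in zip(df.iloc[:, 0], df.iloc[:, 1]):
        tag = str(tag).lstrip("#").lower()
        cls = str(cls).lower()
        if cls not in TEMPORAL_CLASSES:
            raise ValueError(f"{path}: unknown class {cls!r} for #{tag}")
        entries[tag] = cls
    return entries


def write_hashtag_map_csv(entries: dict[str, str], path: str | Path) -> None:
    pd.DataFrame({"hashtag": list(entries), "class": list(entries.values())}
                 ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Profiles (CSV)
# ---------------------------------------------------------------------------
PROFILE_COLUMNS = (
    ["user_id", "n_tweets", "n_past", "n_present", "n_future",
     "uni_past", "uni_present", "uni_future"]
    + [f"bi_{t}_{s}" for t in TEMPORAL_CLASSES for s in SENTIMENT_CLASSES]
)


def profiles_to_frame(profiles) -> pd.DataFrame:
    """Flatten :class:`~temporient.profiling.UserTPProfile` objects to a table.

    Undefined bidimensional entries become NaN (empty cells on disk).
    """
    rows = []
    for p in profiles:
        row: dict = {"user_id": p.user_id, "n_tweets": p.n_tweets}
        for t in TEMPORAL_CLASSES:
            row[f"n_{t}"] = p.counts[t]
            row[f"uni_{t}"] = p.uni[t]
        for t in TEMPORAL_CLASSES:
            for s in SENTIMENT_CLASSES:
                val = p.bi[(t, s)]
                row[f"bi_{t}_{s}"] = math.nan if val is None else val
        rows.append(row)
    return pd.DataFrame(rows, columns=PROFILE_COLUMNS)


def write_profiles_csv(profiles, path: str | Path) -> None:
    profiles_to_frame(profiles).to_csv(path, index=False,
                                       float_format="%.12g")


def read_profiles_csv(path: str | Path) -> list:
    """Read a profile CSV back into :class:`UserTPProfile` objects."""
    from .profiling import UserTPProfile  # local import avoids a cycle

    df = pd.read_csv(path, dtype={"user_id": str})
    missing = set(PROFILE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing profile columns {sorted(missing)}")
    profiles = []
    for _, row in df.iterrows():
        counts = {t: int(row[f"n_{t}"]) for t in TEMPORAL_CLASSES}
        uni = {t: float(row[f"uni_{t}"]) for t in TEMPORAL_CLASSES}
        bi = {}
        for t in TEMPORAL_CLASSES:
            for s in SENTIMENT_CLASSES:
                val = row[f"bi_{t}_{s}"]
                bi[(t, s)] = None if pd.isna(val) else float(val)
        profiles.append(UserTPProfile(
            user_id=str(row["user_id"]), n_tweets=int(row["n_tweets"]),
            counts=counts, uni=uni, bi=bi))
    return profiles


# ---------------------------------------------------------------------------
# Attributes and correlation reports (CSV)
# ---------------------------------------------------------------------------
def read_attributes_csv(path: str | Path) -> pd.DataFrame:
    """User attribute table; must carry a ``user_id`` column."""
    df = pd.read_csv(path, dtype={"user_id": str})
    if "user_id" not in df.columns:
        raise ValueError(f"{path}: attribute table needs a 'user_id' column")
    return df


def write_correlation_csv(results, path: str | Path) -> None:
    rows = [{"tp_dimension": r.tp_dimension, "attribute": r.attribute,
             "n": r.n, "r": r.r, "z": r.z, "p_raw": r.p_raw,
             "p_bonferroni": r.p_bonferroni, "significant": r.significant,
             "degenerate": r.degenerate}
            for r in results]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.12g")
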