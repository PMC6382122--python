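"""Weak hashtag labeling and two-pass filtering of the training corpus.

A tweet inherits a temporal class when one of its hashtags is in the
hashtag->class map (tweets whose hashtags point at more than one class are
ambiguous and dropped).  Two filtering passes then clean the pool: pass 1
keeps only tweets containing a verb (every meaningful sentence has one);
pass 2 removes present- and future-labeled tweets containing a simple-past
verb (VBD), since those texts are most likely recollections despite the
topical hashtag.  Past-labeled tweets are never removed by pass 2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .features import DEFAULT_TAGGER, tag_pos, tokenize
from .io import TEMPORAL_CLASSES, Tweet

logger = logging.getLogger(__name__)

Record = tuple[Tweet, str]  # (tweet, weak label)


@dataclass
class WeaklyLabeledCorpus:
    records: list[Record]
    provenance: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def class_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in TEMPORAL_CLASSES}
        for _, label in self.records:
            counts[label] += 1
        return counts

    def texts_and_labels(self) -> tuple[list[str], list[str]]:
        return ([t.text for t, _ in self.records],
                [lab for _, lab in self.records])


def weak_label(tweets: list[Tweet], hashtag_map: dict[str, str]
               ) -> list[Record]:
    """Label tweets from their hashtags; ambiguous or unmapped ones drop."""
    if not hashtag_map:
        raise ValueError("hashtag map is empty")
    records: list[Record] = []
    for tw in tweets:
        classes = {hashtag_map[h] for h in tw.hashtags if h in hashtag_map}
        if len(classes) == 1:
            records.append((tw, classes.pop()))
    logger.info("weak labeling: %d tweets in, %d labeled",
                len(tweets), len(records))
    return records


def _has_verb(text: str, tagger) -> bool:
    return any(a.coarse_pos == "verb" for a in tag_pos(tokenize(text), tagger))


def _has_vbd(text: str, tagger) -> bool:
    return any(a.fine_verb_tag == "VBD"
               for a in tag_pos(tokenize(text), tagger))


def pass1_verb_filter(records: list[Record], tagger=None) -> list[Record]:
    """Keep records whose text contains at least one verb (order-stable)."""
    tagger = tagger if tagger is not None else DEFAULT_TAGGER
    kept = [r for r in records if _has_verb(r[0].text, tagger)]
    logger.info("pass 1 (verb filter): %d in, %d kept", len(records), len(kept))
    return kept


def pass2_tense_filter(records: list[Record], tagger=None) -> list[Record]:
    """Drop present/future records containing a simple-past (VBD) verb.

    Past-labeled records are never removed.
    """
    tagger = tagger if tagger is not None else DEFAULT_TAGGER
    kept = [r for r in records
            if r[1] == "past" or not _has_vbd(r[0].text, tagger)]
    logger.info("pass 2 (tense filter): %d in, %d kept",
                len(records), len(kept))
    return kept


def balance_and_sample(records: list[Record], per_class_n: int,
                       seed: int | np.random.Generator = 0
                       ) -> WeaklyLabeledCorpus:
    """Downsample without replacement to exactly ``per_class_n`` per class.

    Sampling is uniform and seeded; survivors keep their input order.
    """
    if per_class_n < 0:
        raise ValueError("per_class_n must be non-negative")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    by_class: dict[str, list[int]] = {c: [] for c in TEMPORAL_CLASSES}
    for i, (_, label) in enumerate(records):
        by_class[label].append(i)
    short = {c: len(ix) for c, ix in by_class.items() if len(ix) < per_class_n}
    if short:
        raise ValueError(
            f"per_class_n={per_class_n} exceeds class counts "
            f"{ {c: len(ix) for c, ix in by_class.items()} }")
    keep: set[int] = set()
    for c in TEMPORAL_CLASSES:
        chosen = rng.choice(len(by_class[c]), size=per_class_n, replace=False)
        keep.update(by_class[c][j] for j in chosen)
    sampled = [records[i] for i in sorted(keep)]
    corpus = WeaklyLabeledCorpus(records=sampled)
    corpus.provenance["after_balancing"] = len(sampled)
    for c, n in corpus.class_counts().items():
        corpus.provenance[f"after_balancing_{c}"] = n
    return corpus


def build_corpus(tweets: list[Tweet], hashtag_map: dict[str, str],
                 tagger=None, per_class_n: int | None = None,
                 seed: int = 0) -> WeaklyLabeledCorpus:
    """Full weak-labeling pipeline with per-stage provenance counts."""
    tagger = tagger if tagger is not None else DEFAULT_TAGGER
    provenance: dict[str, int] = {"collected": len(tweets)}
    labeled = weak_label(tweets, hashtag_map)
    provenance["labeled"] = len(labeled)
    after1 = pass1_verb_filter(labeled, tagger)
    provenance["after_pass1"] = len(after1)
    after2 = pass2_tense_filter(after1, tagger)
    provenance["after_pass2"] = len(after2)
    counts = {c: 0 for c in TEMPORAL_CLASSES}
    for _, label in after2:
        counts[label] += 1
    for c, n in counts.items():
        provenance[f"after_pass2_{c}"] = n
    if per_class_n is None:
        per_class_n = min(counts.values())
    corpus = balance_and_sample(after2, per_class_n, seed)
    corpus.provenance = {**provenance, **corpus.provenance}
    logger.info("corpus provenance: %s", corpus.provenance)
    return corpus
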