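"""The temporal-orientation classifier as a scikit-learn-style estimator.

:class:`TemporalOrientationClassifier` wires the feature pipeline
(tokenize -> tag -> temporal-keyword detection -> embedding matrices) into
the attention Bi-LSTM + feature-CNN network and trains it with categorical
cross-entropy.  Training uses a stratified validation split; the epoch
snapshot with the highest validation accuracy is the fitted model.

The estimator composes with scikit-learn tooling (``get_params`` /
``set_params``, ``fit`` / ``predict`` / ``predict_proba``, fitted attributes
with a trailing underscore).
"""

from __future__ import annotations

import copy
import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.utils.validation import check_is_fitted

from . import network as net
from .config import RunConfig
from .features import (DEFAULT_TAGGER, annotate, build_feature_bundle,
                       default_temporal_lexicon)
from .io import EmbeddingTable, TemporalLexicon

logger = logging.getLogger(__name__)

CLASSES = net.CLASSES
CHECKPOINT_VERSION = 1


@dataclass
class TemporalPrediction:
    """Class probabilities and the tie-broken argmax label for one text."""

    probabilities: tuple[float, float, float]  # (past, present, future)
    label: str

    def __post_init__(self) -> None:
        if abs(sum(self.probabilities) - 1.0) > 1e-6:
            raise ValueError("probabilities must sum to 1")


def _argmax_label(probs: np.ndarray) -> str:
    # np.argmax returns the first maximum: ties break past < present < future
    return CLASSES[int(np.argmax(probs))]


class TemporalOrientationClassifier(BaseEstimator, ClassifierMixin):
    """Attention Bi-LSTM + linguistic-feature CNN text classifier.

    Parameters
    ----------
    embeddings : EmbeddingTable
        Pre-trained word vectors (GloVe-style); not fine-tuned by default.
    lexicon : TemporalLexicon, optional
        Temporal keyword lexicon; the packaged list when omitted.
    tagger : callable, optional
        Token list -> (coarse tags, fine verb tags); packaged rule-based
        tagger when omitted.
    hidden_size : int
        LSTM hidden units per direction.
    attention_size : int or None
        Width of the attention projection; ``None`` means 2 * hidden_size.
    cnn_windows, cnn_filters : convolution windows over E and feature maps
        per window.
    dropout_rate : float
        Dropout on the merged vector c = [s; f] during training.
    epochs, batch_size, learning_rate, optimizer, validation_fraction :
        training protocol knobs (categorical cross-entropy loss throughout).
    max_seq_len : int
        Word sequences are truncated/zero-padded to this length.
    random_state : int or None
        Seed for every source of randomness (init, splits, shuffling,
        dropout).
    """

    def __init__(self, embeddings: EmbeddingTable | None = None,
                 lexicon: TemporalLexicon | None = None,
                 tagger=None, hidden_size: int = 64,
                 attention_size: int | None = None,
                 cnn_windows: tuple[int, ...] = (5, 6, 7),
                 cnn_filters: int = 32, dropout_rate: float = 0.2,
                 epochs: int = 100, batch_size: int = 128,
                 learning_rate: float = 0.01, optimizer: str = "rmsprop",
                 validation_fraction: float = 0.10, max_seq_len: int = 50,
                 random_state: int | None = None):
        self.embeddings = embeddings
        self.lexicon = lexicon
        self.tagger = tagger
        self.hidden_size = hidden_size
        self.attention_size = attention_size
        self.cnn_windows = cnn_windows
        self.cnn_filters = cnn_filters
        self.dropout_rate = dropout_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.optimizer = optimizer
        self.validation_fraction = validation_fraction
        self.max_seq_len = max_seq_len
        self.random_state = random_state

    # -- feature pipeline ---------------------------------------------------
    def _resolved(self):
        if self.embeddings is None:
            raise ValueError("an EmbeddingTable is required")
        lexicon = (self.lexicon if self.lexicon is not None
                   else default_temporal_lexicon())
        tagger = self.tagger if self.tagger is not None else DEFAULT_TAGGER
        return self.embeddings, lexicon, tagger

    def _featurize(self, texts) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Batch feature tensors: word (B,N,d), E (B,L,d), n_content (B,)."""
        emb, lexicon, tagger = self._resolved()
        windows = tuple(self.cnn_windows)
        bundles = [build_feature_bundle(annotate(t, lexicon, tagger), emb,
                                        self.max_seq_len, windows)
                   for t in texts]
        B = len(bundles)
        d = emb.dimension
        word = np.zeros((B, self.max_seq_len, d))
        L = max(b.E.shape[1] for b in bundles) if bundles else max(windows)
        E = np.zeros((B, L, d))
        n_content = np.zeros(B, dtype=int)
        for i, b in enumerate(bundles):
            word[i] = b.word_matrix.T
            E[i, :b.E.shape[1]] = b.E.T
            n_content[i] = b.n_content
        return word, E, n_content

    # -- training -----------------------------------------------------------
    def fit(self, X, y):
        """Train on texts ``X`` with labels ``y`` in {past, present, future}.

        Holds out a stratified ``validation_fraction`` of the data, records
        per-epoch validation accuracy in ``history_`` and keeps the epoch
        snapshot with the highest validation accuracy (ties: earliest).
        """
        texts = [t.text if hasattr(t, "text") else str(t) for t in X]
        y = np.asarray([str(lab) for lab in y])
        counts = {c: int(np.sum(y == c)) for c in CLASSES}
        bad = set(y) - set(CLASSES)
        if bad:
            raise ValueError(f"unknown labels {sorted(bad)}")
        if any(n == 0 for n in counts.values()):
            raise ValueError(f"every class needs at least one record; "
                             f"got counts {counts}")
        emb, _, _ = self._resolved()
        seed = 0 if self.random_state is None else int(self.random_state)
        rng = np.random.default_rng(seed)
        windows = tuple(self.cnn_windows)

        y_idx = np.array([CLASSES.index(lab) for lab in y])
        word, E, n_content = self._featurize(texts)

        n_val = max(1, int(round(self.validation_fraction * len(texts))))
        stratify = y_idx if min(counts.values()) >= 2 and n_val >= 3 else None
        idx_train, idx_val = train_test_split(
            np.arange(len(texts)), test_size=n_val,
            random_state=seed, stratify=stratify)

        params = net.init_params(rng, emb.dimension, self.hidden_size,
                                 self.attention_size, windows,
                                 self.cnn_filters)
        opt = net.Optimizer(params, self.optimizer, self.learning_rate)

        def val_accuracy(p) -> float:
            yv, _ = net.model_forward(p, word[idx_val], E[idx_val],
                                      n_content[idx_val], windows)
            return float(np.mean(yv.argmax(axis=1) == y_idx[idx_val]))

        history: list[float] = []
        best_params = copy.deepcopy(params)
        best_acc = -1.0
        best_epoch = -1
        if self.epochs == 0:
            best_acc = val_accuracy(params)
        for epoch in range(self.epochs):
            order = rng.permutation(idx_train)
            for start in range(0, len(order), self.batch_size):
                batch = order[start:start + self.batch_size]
                _, cache = net.model_forward(
                    params, word[batch], E[batch], n_content[batch],
                    windows, dropout_rate=self.dropout_rate, rng=rng,
                    train=True)
                grads = net.model_backward(cache, y_idx[batch])
                opt.step(params, grads)
            acc = val_accuracy(params)
            history.append(acc)
            if acc > best_acc:
                best_acc = acc
                best_epoch = epoch
                best_params = copy.deepcopy(params)
            logger.debug("epoch %d: validation accuracy %.4f", epoch, acc)

        self.classes_ = np.array(CLASSES)
        self.params_ = best_params
        self.history_ = history
        self.best_epoch_ = best_epoch
        self.best_validation_accuracy_ = best_acc
        self.n_features_in_ = emb.dimension
        logger.info("training done: best validation accuracy %.4f at "
                    "epoch %d", best_acc, best_epoch)
        return self

    # -- inference ----------------------------------------------------------
    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "params_")
        texts = [t.text if hasattr(t, "text") else str(t) for t in X]
        if not texts:
            return np.zeros((0, len(CLASSES)))
        word, E, n_content = self._featurize(texts)
        probs = []
        windows = tuple(self.cnn_windows)
        for start in range(0, len(texts), 512):
            y, _ = net.model_forward(self.params_,
                                     word[start:start + 512],
                                     E[start:start + 512],
                                     n_content[start:start + 512], windows)
            probs.append(y)
        return np.concatenate(probs)

    def predict(self, X) -> np.ndarray:
        probs = self.predict_proba(X)
        return np.array([_argmax_label(p) for p in probs])

    def predict_one(self, text: str) -> TemporalPrediction:
        probs = self.predict_proba([text])[0]
        return TemporalPrediction(probabilities=tuple(float(p) for p in probs),
                                  label=_argmax_label(probs))

    # -- persistence --------------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Write a single-file versioned checkpoint (weights + settings)."""
        check_is_fitted(self, "params_")
        meta = {"version": CHECKPOINT_VERSION,
                "hidden_size": self.hidden_size,
                "attention_size": self.attention_size,
                "cnn_windows": list(self.cnn_windows),
                "cnn_filters": self.cnn_filters,
                "max_seq_len": self.max_seq_len,
                "embedding_dim": self.embeddings.dimension,
                "history": self.history_,
                "best_epoch": self.best_epoch_}
        emb = self.embeddings
        emb_words = emb.words()
        emb_matrix = np.stack([emb.get(w) for w in emb_words]) \
            if emb_words else np.zeros((0, emb.dimension))
        _, lexicon, _ = self._resolved()
        np.savez(path, __meta__=json.dumps(meta),
                 __emb_words__=np.array(emb_words, dtype=object),
                 __emb_matrix__=emb_matrix,
                 __lexicon__=json.dumps(lexicon.entries),
                 **self.params_)

    @classmethod
    def load(cls, path: str | Path) -> "TemporalOrientationClassifier":
        with np.load(path, allow_pickle=True) as data:
            meta = json.loads(str(data["__meta__"]))
            if meta.get("version") != CHECKPOINT_VERSION:
                raise ValueError(
                    f"unsupported checkpoint version {meta.get('version')}")
            emb = EmbeddingTable(dimension=meta["embedding_dim"])
            for w, vec in zip(data["__emb_words__"], data["__emb_matrix__"]):
                emb.add(str(w), vec)
            lexicon = TemporalLexicon(
                entries=json.loads(str(data["__lexicon__"])))
            params = {k: data[k] for k in data.files
                      if not k.startswith("__")}
        clf = cls(embeddings=emb, lexicon=lexicon,
                  hidden_size=meta["hidden_size"],
                  attention_size=meta["attention_size"],
                  cnn_windows=tuple(meta["cnn_windows"]),
                  cnn_filters=meta["cnn_filters"],
                  max_seq_len=meta["max_seq_len"])
        clf.params_ = params
        clf.history_ = meta["history"]
        clf.best_epoch_ = meta["best_epoch"]
        clf.classes_ = np.array(CLASSES)
        clf.best_validation_accuracy_ = (max(meta["history"])
                                         if meta["history"] else -1.0)
        return clf


# ---------------------------------------------------------------------------
# Module-level operations (thin wrappers over the estimator)
# ---------------------------------------------------------------------------
def train(corpus, config: RunConfig, embeddings: EmbeddingTable,
          lexicon: TemporalLexicon | None = None, tagger=None
          ) -> tuple[TemporalOrientationClassifier, list[float]]:
    """Train on a :class:`~temporient.corpus.WeaklyLabeledCorpus`."""
    texts, labels = corpus.texts_and_labels()
    clf = classifier_from_config(config, embeddings, lexicon, tagger)
    clf.fit(texts, labels)
    return clf, clf.history_


def classifier_from_config(config: RunConfig, embeddings: EmbeddingTable,
                           lexicon: TemporalLexicon | None = None,
                           tagger=None) -> TemporalOrientationClassifier:
    return TemporalOrientationClassifier(
        embeddings=embeddings, lexicon=lexicon, tagger=tagger,
        hidden_size=config.hidden_size,
        attention_size=config.attention_size,
        cnn_windows=config.cnn_windows,
        cnn_filters=config.cnn_filters_per_window,
        dropout_rate=config.dropout_rate, epochs=config.epochs,
        batch_size=config.batch_size, learning_rate=config.learning_rate,
        optimizer=config.optimizer_name,
        validation_fraction=config.validation_fraction,
        max_seq_len=config.max_seq_len, random_state=config.seed)


def forward(text: str, model: TemporalOrientationClassifier
            ) -> TemporalPrediction:
    """Classify one text with a fitted model."""
    return model.predict_one(text)


def grid_search(corpus, param_grid: list[dict], embeddings: EmbeddingTable,
                base_config: RunConfig | None = None, k_folds: int = 10
                ) -> tuple[RunConfig, list[float]]:
    """Mean k-fold CV accuracy per grid point; argmax wins, ties by order.

    Each grid point is a dict of :class:`RunConfig` field overrides.  Folds
    missing a class are skipped with a warning.
    """
    if not param_grid:
        raise ValueError("empty parameter grid")
    base = base_config if base_config is not None else RunConfig()
    texts, labels = corpus.texts_and_labels()
    y = np.asarray(labels)
    texts = np.asarray(texts, dtype=object)
    scores: list[float] = []
    for point in param_grid:
        config = RunConfig(**{**base.to_dict(), **point})
        skf = StratifiedKFold(n_splits=k_folds, shuffle=True,
                              random_state=config.seed)
        fold_scores = []
        for tr, te in skf.split(texts, y):
            if set(CLASSES) - set(y[tr]):
                warnings.warn("fold skipped: class missing from training "
                              "split", stacklevel=2)
                continue
            clf = classifier_from_config(config, embeddings)
            clf.fit(list(texts[tr]), list(y[tr]))
            fold_scores.append(float(np.mean(clf.predict(list(texts[te]))
                                             == y[te])))
        scores.append(float(np.mean(fold_scores)) if fold_scores else -1.0)
    best = int(np.argmax(scores))
    best_config = RunConfig(**{**base.to_dict(), **param_grid[best]})
    return best_config, scores
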