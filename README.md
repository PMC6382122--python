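# temporient

Temporal-orientation classification of short social-media texts and
user-level Time Perspective (TP) profiling.

## The problem

Grammatical tense and actual temporal reference often disagree: *"the cup
starts in 3 days"* is present-tense but future-oriented. Resolving tense
into the underlying temporal orientation — **past**, **present** or
**future** — is the prerequisite for measuring a person's Time Perspective
from their language: the habitual way an individual's thinking is oriented
toward the three time frames. `temporient` is for computational social
scientists and psycholinguists who want to run that measurement pipeline
end to end: weakly supervised corpus construction, a neural temporal
classifier, per-user TP profiles, and an association analysis against user
attributes.

## The model

A text `w = (w_1 … w_N)` of pre-trained word embeddings feeds a
bidirectional LSTM; per-token outputs are merged, `m_t = [h→_t ; h←_t]`.
An attention layer weights the tokens against a learned word-level context
vector `p_w`:

    p_t = tanh(W_w m_t + b_w)
    α_t = softmax_t(p_tᵀ p_w)
    s   = Σ_t α_t m_t

In parallel, two word-level linguistic feature matrices are built: `X`
(d × k) over the tokens tagged as verbs and `Y` (d × l) over the tokens
matched by a temporal-keyword lexicon. Their concatenation `E = [X | Y]`
passes through a one-layer CNN (token-axis windows of 5/6/7, tanh, global
max-pool) giving `f`. The merged vector `c = [s ; f]` is projected and
classified:

    z = tanh(W_i c + b_i),   y = softmax(z)  over {past, present, future}

trained with categorical cross-entropy and RMSprop (batch 128, dropout
0.2, stratified 10 % validation split; the epoch snapshot with the best
validation accuracy is kept). The network and its backward pass are
implemented in NumPy and validated against finite-difference gradients.

Training data come from **weak supervision**: tweets inherit a temporal
class from manually classed hashtags, then two filtering passes clean the
pool — (1) drop texts without a verb; (2) drop present/future-labeled
texts containing a simple-past verb (VBD) — before balanced downsampling.

User-level profiles aggregate per-tweet predictions:

    orientation_t(user)   = |tweets_t(user)|   / |tweets_all(user)|      (unidimensional)
    orientation_{s,t}(u)  = |tweets_{s,t}(u)|  / |tweets_t(u)|           (bidimensional)

with sentiment valence `s ∈ {positive, negative, neutral}` from a pluggable
sentiment function (a lexicon scorer with negation flipping is packaged).
Associations between TP dimensions and user attributes are measured with
Pearson's r, tested by Fisher's R-to-Z transform (SE `1/√(n−3)`,
Bonferroni-corrected, α = 0.001), with OLS fits and loess-smoothed
standardized-frequency curves over age.

## Worked example

Everything runs on synthetic data generated by the package (no downloads).
The generator plants per-class cue words, class-consistent hashtags and
user cohorts whose attributes correlate with a TP dimension at a known ρ:

```python
import numpy as np
from temporient import (SyntheticSpec, TemporalOrientationClassifier,
                        correlation_report, generate_embeddings,
                        generate_tweets, generate_user_cohort, profile_users)

spec = SyntheticSpec(cue_strength=1.0, embedding_dim=16, seed=1)
rng = np.random.default_rng(1)
train = generate_tweets(1500, spec, rng)
test = generate_tweets(500, spec, rng)
emb = generate_embeddings(d=16, seed=1)

clf = TemporalOrientationClassifier(embeddings=emb, hidden_size=64,
                                    epochs=10, max_seq_len=20,
                                    random_state=1)
clf.fit([t.text for t in train], [t.gold_label for t in train])
acc = np.mean(clf.predict([t.text for t in test])
              == np.array([t.gold_label for t in test]))
print(f"held-out accuracy: {acc:.3f}")
print(clf.predict_one("2017 fifa u17 world cup starts in 3 days").label)
```

prints

```
held-out accuracy: 0.952
future
```

— 95.2 % of the held-out synthetic tweets are classified correctly, and a
present-tense sentence with future reference is resolved to `future`.
Profiling a 500-user cohort with a planted age correlation (ρ = 0.47 with
the past dimension) and running the correlation report recovers
`r = 0.44` for `uni_past × age` with a Bonferroni-corrected p ≈ 7e-25.

The same pipeline is available from the shell:

```sh
temporient simulate --seed 3 --out-dir data/
temporient build-corpus --tweets data/tweets.jsonl \
    --hashtag-map data/hashtag_map.csv --seed 3 --out corpus.jsonl
temporient train --corpus corpus.jsonl --embeddings data/embeddings.txt \
    --seed 3 --out model.npz
temporient predict --model model.npz --in data/tweets.jsonl --out pred.jsonl
temporient profile --model model.npz --in data/tweets.jsonl --out profiles.csv
temporient correlate --profiles profiles.csv \
    --attributes data/attributes.csv --out correlations.csv
```

## File formats

Tweets are JSONL (`tweet_id`, `user_id`, `text`, `hashtags`, optional
`timestamp`/`gold_label`/`gold_sentiment`); embeddings are GloVe-style
text; the temporal lexicon is `word<TAB>sense` TSV with senses
past/present/future/neutral; hashtag maps, profiles, attributes and
correlation reports are CSV. Model checkpoints are single-file versioned
`.npz`.

The packaged rule-based tagger emits coarse tags
`verb noun pron det adp conj adj adv num punct intj other` and Penn-style
fine verb subtags `VB VBD VBG VBN VBP VBZ`; any callable mapping a token
list to equal-length coarse/fine tag lists can replace it.

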