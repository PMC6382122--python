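import numpy as np
import pytest

from temporient import (SyntheticSpec, TemporalLexicon, Tweet,
                        default_temporal_lexicon, generate_embeddings,
                        synthetic_vocabulary)


@pytest.fixture(scope="session")
def lexicon() -> TemporalLexicon:
    return default_temporal_lexicon()


@pytest.fixture(scope="session")
def toy_embeddings():
    """Small unit-norm embeddings covering the synthetic vocabulary."""
    return generate_embeddings(synthetic_vocabulary(), d=16, seed=0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_tweet(text: str, tweet_id: str = "t0", user_id: str = "u0",
               hashtags=(), **kwargs) -> Tweet:
    return Tweet(tweet_id=tweet_id, user_id=user_id, text=text,
                 hashtags=list(hashtags), **kwargs)


@pytest.fixture(scope="session")
def small_spec() -> SyntheticSpec:
    return SyntheticSpec(n_users=20, n_tweets_per_user=15, seed=9)
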