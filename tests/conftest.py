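import numpy as np
import pytest

from sudscope import default_lexicon
from sudscope.pipeline import train_feature_models
from sudscope.synthetic import (
    GeneratorConfig,
    examples_from_posts,
    generate_emotion_tweets,
    generate_posts,
)


@pytest.fixture(scope="session")
def lexicon():
    return default_lexicon()


@pytest.fixture(scope="session")
def small_config():
    # compact corpus reused across model tests: 120 authors, short histories
    return GeneratorConfig(seed=7, n_authors=120, posts_per_author=(8, 12),
                           history_len=8)


@pytest.fixture(scope="session")
def small_posts(small_config, lexicon):
    return generate_posts(small_config, lexicon)


@pytest.fixture(scope="session")
def small_examples(small_posts):
    return examples_from_posts(small_posts)


@pytest.fixture(scope="session")
def feature_models(small_posts, lexicon):
    tweets = generate_emotion_tweets(seed=7, n_per_emotion=40)
    return train_feature_models(small_posts, tweets, lexicon, hidden_dim=16, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
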