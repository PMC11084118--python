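"""Affect features: rule-based sentiment, hashtag weak labels, trainable models."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sudscope import (
    EMOTIONS,
    score_sentiment,
    sentiment_distribution_by_drug,
    train_affect_classifier,
    weak_label_emotion,
)
from sudscope.affect import (
    AffectClassifier,
    NEUTRAL_BAND,
    TrainConfig,
    default_valence_lexicon,
)
from sudscope.synthetic import GeneratorConfig, generate_posts

VALENCE = default_valence_lexicon()


class TestScoreSentiment:
    def test_empty_text_is_neutral_zero(self):
        result = score_sentiment("", VALENCE)
        assert (result.score, result.label) == (0.0, "neutral")

    def test_negation_flips_sign(self):
        plain = score_sentiment("good", VALENCE)
        negated = score_sentiment("not good", VALENCE)
        assert plain.score > 0 > negated.score

    def test_negation_window_is_three_tokens(self):
        # negation four tokens back no longer scopes over the valence word
        near = score_sentiment("not at all good", VALENCE)
        far = score_sentiment("not I am told that good", VALENCE)
        assert near.score < 0 < far.score

    def test_repetition_is_monotone_under_pooling(self):
        single = score_sentiment("great", VALENCE).score
        triple = score_sentiment("great great great", VALENCE).score
        assert triple >= single > 0

    def test_booster_intensifies(self):
        assert (
            score_sentiment("very good", VALENCE).score
            > score_sentiment("good", VALENCE).score
        )
        assert (
            score_sentiment("slightly good", VALENCE).score
            < score_sentiment("good", VALENCE).score
        )

    def test_pooling_normalization_bounds(self):
        text = " ".join(["great"] * 50)
        assert -1.0 <= score_sentiment(text, VALENCE).score <= 1.0

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.sampled_from(sorted(VALENCE)), min_size=0, max_size=8))
    def test_label_is_step_function_of_score(self, tokens):
        result = score_sentiment(" ".join(tokens), VALENCE)
        if result.score >= NEUTRAL_BAND:
            assert result.label == "positive"
        elif result.score <= -NEUTRAL_BAND:
            assert result.label == "negative"
        else:
            assert result.label == "neutral"


class TestWeakLabelEmotion:
    def test_trailing_emotion_hashtag(self):
        assert weak_label_emotion("finally clean for 30 days #thankfulness") == (
            "finally clean for 30 days",
            "thankfulness",
        )

    def test_multi_emotion_excluded(self):
        assert weak_label_emotion("what a day #joy #fear") is None

    def test_no_hashtag_excluded(self):
        assert weak_label_emotion("no hashtag here") is None

    def test_mid_text_emotion_hashtag_excluded(self):
        assert weak_label_emotion("#joy is all I feel today, honestly") is None

    def test_scrubs_handles_and_urls(self):
        clean, label = weak_label_emotion(
            "@friend check http://a.b/c made me smile #joy"
        )
        assert label == "joy"
        assert "@" not in clean and "#" not in clean and "http" not in clean

    @settings(deadline=None, derandomize=True)
    @given(st.text(max_size=60), st.sampled_from(EMOTIONS))
    def test_label_always_in_seven_set(self, prefix, emotion):
        out = weak_label_emotion(f"{prefix} #{emotion}")
        if out is not None:
            clean, label = out
            assert label in EMOTIONS
            assert "#" not in clean and "@" not in clean


def make_keyword_corpus(n_per_class, classes, seed=0):
    """Classes distinguished by disjoint keyword sets; linearly separable."""
    rng = np.random.default_rng(seed)
    keywords = {
        c: [f"{c}word{j}" for j in range(5)] for c in classes
    }
    filler = ["the", "a", "some", "note", "entry"]
    corpus = []
    for c in classes:
        for _ in range(n_per_class):
            words = list(rng.choice(keywords[c], 3)) + list(rng.choice(filler, 3))
            rng.shuffle(words)
            corpus.append((" ".join(words), c))
    return corpus


class TestAffectClassifier:
    def test_separable_corpus_reaches_perfect_f1(self):
        corpus = make_keyword_corpus(100, ["pos", "neg"])
        model = train_affect_classifier(corpus, "sentiment", TrainConfig(seed=0))
        assert model.test_macro_f1_ == pytest.approx(1.0)

    def test_label_shuffled_corpus_is_at_chance(self):
        rng = np.random.default_rng(3)
        corpus = make_keyword_corpus(200, ["a", "b", "c"], seed=3)
        labels = [l for _, l in corpus]
        rng.shuffle(labels)
        shuffled = [(t, l) for (t, _), l in zip(corpus, labels)]
        model = train_affect_classifier(shuffled, "emotion", TrainConfig(seed=3))
        assert model.test_macro_f1_ == pytest.approx(1 / 3, abs=0.1)

    def test_seed_determinism(self):
        corpus = make_keyword_corpus(60, ["x", "y"], seed=1)
        texts = [t for t, _ in corpus]
        a = train_affect_classifier(corpus, "sentiment", TrainConfig(seed=5))
        b = train_affect_classifier(corpus, "sentiment", TrainConfig(seed=5))
        assert np.array_equal(a.predict(texts), b.predict(texts))
        assert np.allclose(a.embeddings_, b.embeddings_)

    def test_single_class_corpus_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            AffectClassifier().fit(["a", "b"], ["same", "same"])

    def test_affect_vector_shape_and_determinism(self):
        corpus = make_keyword_corpus(60, ["x", "y"], seed=2)
        model = train_affect_classifier(corpus, "sentiment", TrainConfig(seed=2))
        v1 = model.affect_vector("xword0 xword1")
        v2 = model.affect_vector("xword0 xword1")
        assert v1.shape == (model.hidden_dim,)
        assert np.all(np.isfinite(v1))
        assert np.array_equal(v1, v2)

    def test_representation_separates_classes(self):
        corpus = make_keyword_corpus(100, ["pos", "neg"], seed=4)
        model = train_affect_classifier(corpus, "sentiment", TrainConfig(seed=4))

        def cos(u, v):
            return float(u @ v / (np.linalg.norm(u) * np.linalg.norm(v)))

        same = cos(
            model.affect_vector("posword0 posword1"),
            model.affect_vector("posword2 posword3"),
        )
        cross = cos(
            model.affect_vector("posword0 posword1"),
            model.affect_vector("negword0 negword1"),
        )
        assert cross < same

    def test_untrained_model_refuses(self):
        from sklearn.exceptions import NotFittedError

        with pytest.raises(NotFittedError):
            AffectClassifier().affect_vector("text")


class TestSentimentDistribution:
    def test_all_positive_category(self):
        config = GeneratorConfig(seed=9, n_authors=40, posts_per_author=(10, 12))
        posts = generate_posts(config)
        table = sentiment_distribution_by_drug(posts, n_per_category=10, seed=0)
        assert (table[["positive", "negative", "neutral"]].sum(axis=1) == table["n"]).all()

    def test_binomial_calibration_of_negative_rate(self):
        """P(negative) over history posts matches the planted mixture at 3 sigma."""
        config = GeneratorConfig(seed=21, n_authors=150, posts_per_author=(10, 12))
        posts = generate_posts(config)
        labeled = [p for p in posts if p.sentiment is not None and p.sud_label is None]
        sudp_authors = {p.author_id for p in posts if p.sud_label == "SUDP"}
        sudp_hist = [p for p in labeled if p.author_id in sudp_authors]
        n = len(sudp_hist)
        k = sum(p.sentiment == "negative" for p in sudp_hist)
        p0 = config.p_negative_given_sudp
        assert abs(k / n - p0) <= 3 * np.sqrt(p0 * (1 - p0) / n)

    def test_small_stratum_warns_and_takes_all(self):
        config = GeneratorConfig(seed=9, n_authors=30, posts_per_author=(10, 12))
        posts = generate_posts(config)
        with pytest.warns(UserWarning, match="taking all"):
            table = sentiment_distribution_by_drug(posts, n_per_category=10**6, seed=0)
        assert table["n"].sum() == len([p for p in posts if p.sentiment])
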