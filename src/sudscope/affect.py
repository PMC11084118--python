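"""Sentiment scoring, hashtag-weak-labeled emotion, and trainable affect models.

Sentiment uses a rule-based valence-lexicon scorer of the kind standard for
social-media text: per-token human-annotated valences in [-4, 4], a negation
flip over a three-token window, intensity boosters (+/-0.293 each), and a
normalized-sum pooling s/sqrt(s^2 + 15) mapped to positive/negative/neutral
with a +/-0.05 neutral band.

Emotion labels come from distant supervision: a tweet self-tagged with exactly
one of seven emotion hashtags (joy, sadness, anger, love, fear, thankfulness,
surprise) yields a training example with the hashtag stripped.

:class:`AffectClassifier` is a scikit-learn-style estimator over either task:
a trainable embedding bag (learned token embeddings, mean pooling) feeding a
softmax layer, trained with Adam on cross-entropy. Its pooled penultimate
representation is the fixed-width affect vector consumed by the sequence
classifier.
"""

from __future__ import annotations

import csv
import logging
import re
import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.exceptions import NotFittedError

from sudscope.encoders import tokenize_for_encoding
from sudscope.evaluation import macro_metrics, stratified_sample
from sudscope.lexicon import scrub_pii

__all__ = [
    "EMOTIONS",
    "SentimentResult",
    "TrainConfig",
    "load_valence_lexicon",
    "default_valence_lexicon",
    "score_sentiment",
    "weak_label_emotion",
    "AffectClassifier",
    "train_affect_classifier",
    "affect_vector",
    "sentiment_distribution_by_drug",
]

logger = logging.getLogger(__name__)

#: The seven emotion classes used for hashtag distant supervision.
EMOTIONS: tuple[str, ...] = (
    "joy",
    "sadness",
    "anger",
    "love",
    "fear",
    "thankfulness",
    "surprise",
)

# hashtag stems accepted as self-tags for each emotion
_EMOTION_STEMS = {
    "joy": "joy",
    "joyful": "joy",
    "happiness": "joy",
    "sadness": "sadness",
    "sad": "sadness",
    "depressed": "sadness",
    "anger": "anger",
    "angry": "anger",
    "furious": "anger",
    "love": "love",
    "loved": "love",
    "fear": "fear",
    "afraid": "fear",
    "scared": "fear",
    "thankfulness": "thankfulness",
    "thankful": "thankfulness",
    "grateful": "thankfulness",
    "surprise": "surprise",
    "surprised": "surprise",
}

# rule constants following the published social-media valence-scorer convention
BOOSTER_INCREMENT = 0.293
NEGATION_SCALAR = -0.74
NORMALIZATION_ALPHA = 15.0
NEUTRAL_BAND = 0.05
NEGATION_WINDOW = 3

NEGATIONS = frozenset(
    """not no never none nobody nothing neither nor cannot cant can't dont don't
    wont won't isnt isn't wasnt wasn't didnt didn't doesnt doesn't aint ain't
    without hardly""".split()
)
INTENSIFIERS = frozenset(
    """very really extremely so incredibly absolutely totally completely super
    utterly deeply insanely""".split()
)
DAMPENERS = frozenset(
    """slightly somewhat barely kinda kind_of marginally little less almost
    partly""".split()
)


@dataclass(frozen=True)
class SentimentResult:
    """Pooled valence score in [-1, 1] and its thresholded label."""

    score: float
    label: str

    def __post_init__(self) -> None:
        if self.label != _label_from_score(self.score):
            raise ValueError("label inconsistent with score threshold rule")


def _label_from_score(score: float) -> str:
    if score >= NEUTRAL_BAND:
        return "positive"
    if score <= -NEUTRAL_BAND:
        return "negative"
    return "neutral"


def load_valence_lexicon(path) -> dict[str, float]:
    """Load a TSV valence lexicon (token, mean valence in [-4, 4])."""
    lex: dict[str, float] = {}
    with open(path, encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            lex[row["token"].lower()] = float(row["valence"])
    return lex


def default_valence_lexicon() -> dict[str, float]:
    """The packaged curated valence lexicon (a compact stand-in for the full
    published social-media valence dictionary, skewed toward recovery/withdrawal
    vocabulary)."""
    ref = resources.files("sudscope").joinpath("data/valence_lexicon.tsv")
    with resources.as_file(ref) as path:
        return load_valence_lexicon(path)


def score_sentiment(
    text: str, valence_lexicon: dict[str, float] | None = None
) -> SentimentResult:
    """Rule-based sentiment of a text.

    Each lexicon token contributes its valence, flipped if a negation occurs in
    the three preceding tokens and nudged by +/-0.293 per intensifier/dampener
    in that window; the summed valence s is pooled to s/sqrt(s^2 + 15), clipped
    to [-1, 1] and labeled with the +/-0.05 neutral band.
    """
    if valence_lexicon is None:
        valence_lexicon = default_valence_lexicon()
    tokens = tokenize_for_encoding(text)
    total = 0.0
    for i, tok in enumerate(tokens):
        valence = valence_lexicon.get(tok)
        if valence is None or valence == 0.0:
            continue
        window = tokens[max(0, i - NEGATION_WINDOW) : i]
        for prev in window:
            if prev in INTENSIFIERS:
                valence += BOOSTER_INCREMENT * np.sign(valence)
            elif prev in DAMPENERS:
                valence -= BOOSTER_INCREMENT * np.sign(valence)
        if any(prev in NEGATIONS for prev in window):
            valence *= NEGATION_SCALAR
        total += valence
    score = total / np.sqrt(total * total + NORMALIZATION_ALPHA)
    score = float(np.clip(score, -1.0, 1.0))
    return SentimentResult(score=score, label=_label_from_score(score))


_HASHTAG_RE = re.compile(r"#(\w+)")


def weak_label_emotion(tweet: str) -> tuple[str, str] | None:
    """Distant-supervision labeling from a trailing emotion hashtag.

    Returns ``(clean_text, emotion)`` when the scrubbed text ends with exactly
    one hashtag whose stem names one of the seven emotions and no other emotion
    hashtag appears; ambiguous (multi-emotion) or untagged texts return None.
    The clean text has the label hashtag removed, remaining '#' markers
    stripped, and URLs/usernames scrubbed tokens removed.
    """
    text = scrub_pii(tweet).strip()
    hashtags = _HASHTAG_RE.findall(text)
    emotion_tags = [
        _EMOTION_STEMS[h.lower()] for h in hashtags if h.lower() in _EMOTION_STEMS
    ]
    if len(emotion_tags) != 1:
        return None
    m = re.search(r"#(\w+)\s*$", text)
    if m is None or m.group(1).lower() not in _EMOTION_STEMS:
        return None
    label = _EMOTION_STEMS[m.group(1).lower()]
    clean = text[: m.start()].strip()
    clean = _HASHTAG_RE.sub(r"\1", clean)  # keep stems of topical hashtags
    clean = clean.replace("[URL]", " ").replace("[USER]", " ")
    clean = clean.replace("#", " ").replace("@", " ")  # stray markers
    clean = re.sub(r"\s+", " ", clean).strip()
    if not clean:
        return None
    return clean, label


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters for the affect models.

    The published configuration for pretrained contextual encoders is 10 epochs
    at lr 1e-5; the lightweight trainable embedding bag defaults to lr 1e-3,
    which the small model actually needs to converge within 10 epochs.
    """

    hidden_dim: int = 32
    epochs: int = 10
    learning_rate: float = 1e-3
    batch_size: int = 32
    seed: int = 0


class AffectClassifier(BaseEstimator, ClassifierMixin):
    """Trainable embedding-bag text classifier for sentiment or emotion.

    Architecture: learned token embeddings (width ``hidden_dim``), mean pooling
    over tokens, then a linear softmax layer; cross-entropy loss optimized with
    Adam. The pooled penultimate representation (:meth:`affect_vector`) is the
    fixed-width affect feature consumed downstream.

    Fitted attributes: ``classes_``, ``vocab_``, ``embeddings_``, ``coef_``,
    ``intercept_``, ``history_`` (per-epoch losses/dev metrics).
    """

    def __init__(
        self,
        hidden_dim: int = 32,
        epochs: int = 10,
        learning_rate: float = 1e-3,
        batch_size: int = 32,
        seed: int = 0,
    ):
        self.hidden_dim = hidden_dim
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.seed = seed

    # -- internals ---------------------------------------------------------
    def _indices(self, text: str) -> np.ndarray:
        idx = [self.vocab_[t] for t in tokenize_for_encoding(text) if t in self.vocab_]
        return np.asarray(idx, dtype=np.intp)

    def _pool(self, idx: np.ndarray) -> np.ndarray:
        if idx.size == 0:
            return np.zeros(self.hidden_dim)
        return self.embeddings_[idx].mean(axis=0)

    @staticmethod
    def _softmax(z: np.ndarray) -> np.ndarray:
        z = z - z.max(axis=-1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=-1, keepdims=True)

    # -- estimator API -----------------------------------------------------
    def fit(self, X: Sequence[str], y: Sequence[str], eval_set=None):
        """Fit on texts ``X`` with class labels ``y``; optional ``eval_set``
        (texts, labels) is scored each epoch into ``history_``."""
        X, y = list(X), list(y)
        if len(X) != len(y) or not X:
            raise ValueError("X and y must be equal-length and non-empty")
        self.classes_ = np.array(sorted(set(y)))
        if len(self.classes_) < 2:
            raise ValueError("training corpus contains a single class")
        class_index = {c: i for i, c in enumerate(self.classes_)}
        y_idx = np.array([class_index[label] for label in y])

        vocab = sorted({t for text in X for t in tokenize_for_encoding(text)})
        self.vocab_ = {t: i for i, t in enumerate(vocab)}

        rng = np.random.default_rng(self.seed)
        V, H, C = len(vocab), self.hidden_dim, len(self.classes_)
        self.embeddings_ = rng.standard_normal((V, H)) * 0.1
        self.coef_ = np.zeros((H, C))
        self.intercept_ = np.zeros(C)

        token_idx = [self._indices(text) for text in X]
        params = [self.embeddings_, self.coef_, self.intercept_]
        adam_m = [np.zeros_like(p) for p in params]
        adam_v = [np.zeros_like(p) for p in params]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0
        self.history_ = []

        for epoch in range(self.epochs):
            order = rng.permutation(len(X))
            epoch_loss = 0.0
            for lo in range(0, len(X), self.batch_size):
                batch = order[lo : lo + self.batch_size]
                pooled = np.stack([self._pool(token_idx[i]) for i in batch])
                probs = self._softmax(pooled @ self.coef_ + self.intercept_)
                targets = y_idx[batch]
                epoch_loss -= float(
                    np.log(probs[np.arange(len(batch)), targets] + 1e-12).sum()
                )
                dlogits = probs.copy()
                dlogits[np.arange(len(batch)), targets] -= 1.0
                dlogits /= len(batch)

                grads = [
                    np.zeros_like(self.embeddings_),
                    pooled.T @ dlogits,
                    dlogits.sum(axis=0),
                ]
                dpooled = dlogits @ self.coef_.T
                for row, i in enumerate(batch):
                    idx = token_idx[i]
                    if idx.size:
                        np.add.at(grads[0], idx, dpooled[row] / idx.size)

                step += 1
                for p, g, m, v in zip(params, grads, adam_m, adam_v):
                    m += (1 - beta1) * (g - m)
                    v += (1 - beta2) * (g * g - v)
                    m_hat = m / (1 - beta1**step)
                    v_hat = v / (1 - beta2**step)
                    p -= self.learning_rate * m_hat / (np.sqrt(v_hat) + eps)

            record = {"epoch": epoch, "train_loss": epoch_loss / len(X)}
            if eval_set is not None:
                dev_f1, dev_p, dev_r = macro_metrics(
                    eval_set[1], self.predict(eval_set[0])
                )
                record.update(dev_macro_f1=dev_f1, dev_precision=dev_p, dev_recall=dev_r)
                logger.info(
                    "epoch %d loss %.4f dev macro-F1 %.4f", epoch, record["train_loss"],
                    dev_f1,
                )
            self.history_.append(record)
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "embeddings_"):
            raise NotFittedError("AffectClassifier is not fitted yet")

    def decision_function(self, X: Sequence[str]) -> np.ndarray:
        self._check_fitted()
        pooled = np.stack([self._pool(self._indices(t)) for t in X])
        return pooled @ self.coef_ + self.intercept_

    def predict_proba(self, X: Sequence[str]) -> np.ndarray:
        return self._softmax(self.decision_function(X))

    def predict(self, X: Sequence[str]) -> np.ndarray:
        return self.classes_[np.argmax(self.decision_function(X), axis=1)]

    def affect_vector(self, text: str) -> np.ndarray:
        """Pooled penultimate representation of one text (length ``hidden_dim``)."""
        self._check_fitted()
        return self._pool(self._indices(text))

    def score(self, X, y) -> float:
        return macro_metrics(y, self.predict(X))[0]


def train_affect_classifier(
    corpus: Sequence[tuple[str, str]],
    task: str = "sentiment",
    config: TrainConfig | None = None,
) -> AffectClassifier:
    """Train an affect model on (text, label) pairs with a 75:5:20 protocol.

    The corpus is stratified-split 75:5:20 by label; the model trains on the
    train part, logs dev metrics per epoch, and reports test macro-F1. The
    fitted estimator is returned with ``test_macro_f1_`` attached.
    """
    from sudscope.evaluation import SplitSpec, stratified_split

    if config is None:
        config = TrainConfig()
    if task not in ("sentiment", "emotion"):
        raise ValueError(f"unknown task {task!r}")
    spec = SplitSpec(seed=config.seed, strata_key=lambda pair: pair[1])
    train, dev, test = stratified_split(list(corpus), spec)
    model = AffectClassifier(
        hidden_dim=config.hidden_dim,
        epochs=config.epochs,
        learning_rate=config.learning_rate,
        batch_size=config.batch_size,
        seed=config.seed,
    )
    model.fit(
        [t for t, _ in train],
        [l for _, l in train],
        eval_set=([t for t, _ in dev], [l for _, l in dev]),
    )
    model.test_macro_f1_ = model.score([t for t, _ in test], [l for _, l in test])
    logger.info("%s model test macro-F1 %.4f", task, model.test_macro_f1_)
    return model


def affect_vector(model: AffectClassifier, text: str) -> np.ndarray:
    """Fixed-width affect vector of a text under a trained model."""
    return model.affect_vector(text)


def sentiment_distribution_by_drug(
    posts, n_per_category: int = 800, seed: int = 0
) -> pd.DataFrame:
    """Per-drug sentiment counts and top-3 emotions on a stratified sample.

    Samples ``n_per_category`` posts per drug category (seeded; smaller
    categories contribute everything with a warning) and tabulates positive/
    negative/neutral counts plus the three most frequent emotion labels.
    """
    labeled = [
        p for p in posts if p.drug_category is not None and p.sentiment is not None
    ]
    if not labeled:
        raise ValueError("no posts carry both a drug category and a sentiment label")
    sample = stratified_sample(
        labeled, n_per_category, seed=seed, strata_key="drug_category"
    )
    rows = []
    for category in sorted({p.drug_category for p in sample}):
        group = [p for p in sample if p.drug_category == category]
        counts = {"positive": 0, "negative": 0, "neutral": 0}
        emotions: dict[str, int] = {}
        for p in group:
            if p.sentiment in counts:
                counts[p.sentiment] += 1
            if p.emotion:
                emotions[p.emotion] = emotions.get(p.emotion, 0) + 1
        top3 = [e for e, _ in sorted(emotions.items(), key=lambda kv: (-kv[1], kv[0]))[:3]]
        rows.append(
            {
                "drug_category": category,
                "n": len(group),
                "positive": counts["positive"],
                "negative": counts["negative"],
                "neutral": counts["neutral"],
                "top_emotions": ", ".join(top3),
            }
        )
    return pd.DataFrame(rows).set_index("drug_category")
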