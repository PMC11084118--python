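"""Knowledge- and history-aware SUDP/SUDA sequence classifier.

The model consumes, for each target post, the author's recent posting history
on the same drug category. Every history post is PII-scrubbed, drug-entity
masked (the knowledge component), and encoded three ways: a content vector
from the text encoder and fixed-width sentiment and emotion vectors from
frozen affect models, plus the log1p time gap to the previous post. The step
sequence runs through a bidirectional LSTM whose outputs are pooled with
additive attention; the pooled vector is concatenated with the target post's
content vector, passed through a ReLU dense layer with dropout, and a 2-way
softmax yields P(SUDP) and P(SUDA). Training uses cross-entropy with Adam.

Ablation switches reproduce the component-removal study: no attention
(mean-pool the recurrent outputs), no masking (raw text to the encoders), and
no history (a feed-forward classifier on the target vector alone, exactly
invariant to the history argument).

All forward/backward passes are explicit numpy; the analytic gradients are
verified against numerical differentiation in the test suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.exceptions import NotFittedError
from sklearn.feature_extraction.text import TfidfVectorizer
from sklearn.linear_model import LogisticRegression

from sudscope.affect import AffectClassifier
from sudscope.corpus import Post, PostHistory
from sudscope.encoders import EmbeddingBagEncoder
from sudscope.evaluation import SplitSpec, macro_metrics, median_over_runs, stratified_split
from sudscope.lexicon import Lexicon, find_mentions, mask_mentions, scrub_pii

__all__ = [
    "FeatureModels",
    "FeatureSequence",
    "AblationConfig",
    "SudTrainConfig",
    "SudPrediction",
    "SudClassifier",
    "encode_post",
    "build_feature_sequence",
    "train_sud",
    "predict_sud",
    "run_ablation",
    "tfidf_logreg_baseline",
]

logger = logging.getLogger(__name__)

LABELS = ("SUDA", "SUDP")


def encode_post(text: str, encoder: EmbeddingBagEncoder) -> np.ndarray:
    """Content vector of a (masked, scrubbed) post: mean over token vectors."""
    return encoder.encode(text)


@dataclass(frozen=True)
class FeatureModels:
    """The frozen feature extractors behind the sequence model.

    The content encoder and both affect models must share one width H;
    mismatched widths raise at construction.
    """

    encoder: EmbeddingBagEncoder
    sentiment_model: AffectClassifier
    emotion_model: AffectClassifier

    def __post_init__(self) -> None:
        dims = {
            "encoder": self.encoder.dim,
            "sentiment": self.sentiment_model.hidden_dim,
            "emotion": self.emotion_model.hidden_dim,
        }
        if len(set(dims.values())) != 1:
            raise ValueError(f"feature width H mismatch across models: {dims}")

    @property
    def dim(self) -> int:
        return self.encoder.dim


@dataclass(frozen=True)
class FeatureSequence:
    """Per-step features for one (target, history) pair.

    Arrays are left-padded to K steps: position K-1 is the most recent history
    post and leading positions with ``valid`` False are zero padding, excluded
    from attention. ``delta_t`` holds raw log1p hours (standardization happens
    inside the classifier with fitted statistics).
    """

    content: np.ndarray  # (K, H)
    sentiment: np.ndarray  # (K, H)
    emotion: np.ndarray  # (K, H)
    delta_t: np.ndarray  # (K,)
    valid: np.ndarray  # (K,) bool
    target_vec: np.ndarray  # (H,)

    def __post_init__(self) -> None:
        k, h = self.content.shape
        if self.sentiment.shape != (k, h) or self.emotion.shape != (k, h):
            raise ValueError("content/sentiment/emotion widths disagree")
        if self.delta_t.shape != (k,) or self.valid.shape != (k,):
            raise ValueError("delta_t/valid must have one entry per step")
        if self.target_vec.shape != (h,):
            raise ValueError("target vector width disagrees with step width")
        if np.any(self.delta_t[self.valid] < 0):
            raise ValueError("delta_t must be non-negative")

    @property
    def k(self) -> int:
        return self.content.shape[0]

    @property
    def h(self) -> int:
        return self.content.shape[1]


def _prepare_text(text: str, lexicon: Lexicon, use_masking: bool) -> str:
    text = scrub_pii(text)
    if use_masking:
        text = mask_mentions(text, find_mentions(text, lexicon))
    return text


def build_feature_sequence(
    target: Post,
    history: PostHistory,
    models: FeatureModels,
    lexicon: Lexicon,
    k: int = 10,
    use_masking: bool = True,
) -> FeatureSequence:
    """Scrub, mask and encode a post history into the classifier's input.

    Histories longer than ``k`` keep the ``k`` most recent posts; shorter ones
    are left-padded with masked zero steps. ``delta_t`` is log1p(hours) between
    consecutive retained steps; the first retained step measures hours since
    the earliest post of the full history.
    """
    history.validate_before(target)
    full = list(history)
    kept = full[-k:]
    h_dim = models.dim

    content = np.zeros((k, h_dim))
    sentiment = np.zeros((k, h_dim))
    emotion = np.zeros((k, h_dim))
    delta_t = np.zeros(k)
    valid = np.zeros(k, dtype=bool)

    offset = k - len(kept)
    earliest = full[0].timestamp if full else None
    for j, post in enumerate(kept):
        text = _prepare_text(post.text, lexicon, use_masking)
        pos = offset + j
        content[pos] = encode_post(text, models.encoder)
        sentiment[pos] = models.sentiment_model.affect_vector(text)
        emotion[pos] = models.emotion_model.affect_vector(text)
        if j == 0:
            hours = (post.timestamp - earliest).total_seconds() / 3600.0
        else:
            hours = (post.timestamp - kept[j - 1].timestamp).total_seconds() / 3600.0
        delta_t[pos] = np.log1p(hours)
        valid[pos] = True

    target_text = _prepare_text(target.text, lexicon, use_masking)
    return FeatureSequence(
        content=content,
        sentiment=sentiment,
        emotion=emotion,
        delta_t=delta_t,
        valid=valid,
        target_vec=encode_post(target_text, models.encoder),
    )


@dataclass(frozen=True)
class AblationConfig:
    """Component-removal switches for the ablation study."""

    use_attention: bool = True
    use_masking: bool = True
    use_history: bool = True


@dataclass(frozen=True)
class SudTrainConfig:
    """Sequence-model hyperparameters.

    Defaults follow the published protocol (10 epochs, batch 64, dropout 0.2,
    Adam) except the learning rate: 1e-5 belongs to the pretrained-encoder
    configuration, while the lightweight desk configuration needs 1e-3.
    """

    hidden_dim: int = 32
    ff_dim: int = 32
    attention_dim: int = 32
    epochs: int = 10
    learning_rate: float = 1e-3
    batch_size: int = 64
    dropout: float = 0.2
    seed: int = 0
    history_len: int = 10


@dataclass(frozen=True)
class SudPrediction:
    """SUDP/SUDA decision with class probabilities (aligned to ``classes``)."""

    label: str
    probabilities: np.ndarray
    classes: tuple[str, ...] = LABELS

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        object.__setattr__(self, "probabilities", p)
        if p.shape != (len(self.classes),) or np.any(p < 0):
            raise ValueError("probabilities must be a non-negative class vector")
        if abs(p.sum() - 1.0) > 1e-6:
            raise ValueError("probabilities must sum to 1")
        if self.classes[int(np.argmax(p))] != self.label:
            raise ValueError("label must be the argmax class")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class _LSTM:
    """Single-direction batched LSTM with explicit backward pass."""

    def __init__(self, input_dim: int, hidden_dim: int, rng: np.random.Generator):
        scale_w = 1.0 / np.sqrt(input_dim)
        scale_u = 1.0 / np.sqrt(hidden_dim)
        self.W = rng.uniform(-scale_w, scale_w, (input_dim, 4 * hidden_dim))
        self.U = rng.uniform(-scale_u, scale_u, (hidden_dim, 4 * hidden_dim))
        self.b = np.zeros(4 * hidden_dim)
        self.d = hidden_dim

    def params(self):
        return [self.W, self.U, self.b]

    def forward(self, X: np.ndarray):
        """X: (B, K, D) -> H: (B, K, d) plus caches for backward."""
        B, K, _ = X.shape
        d = self.d
        h = np.zeros((B, d))
        c = np.zeros((B, d))
        H = np.zeros((B, K, d))
        caches = []
        for t in range(K):
            z = X[:, t] @ self.W + h @ self.U + self.b
            i = _sigmoid(z[:, :d])
            f = _sigmoid(z[:, d : 2 * d])
            g = np.tanh(z[:, 2 * d : 3 * d])
            o = _sigmoid(z[:, 3 * d :])
            c_new = f * c + i * g
            tanh_c = np.tanh(c_new)
            h_new = o * tanh_c
            caches.append((X[:, t], h, c, i, f, g, o, tanh_c))
            h, c = h_new, c_new
            H[:, t] = h
        return H, caches

    def backward(self, dH: np.ndarray, caches):
        """dH: (B, K, d) upstream gradient -> (dX, grads[W, U, b])."""
        B, K, d = dH.shape
        dW = np.zeros_like(self.W)
        dU = np.zeros_like(self.U)
        db = np.zeros_like(self.b)
        dX = np.zeros((B, K, self.W.shape[0]))
        dh_carry = np.zeros((B, d))
        dc_carry = np.zeros((B, d))
        for t in range(K - 1, -1, -1):
            x_t, h_prev, c_prev, i, f, g, o, tanh_c = caches[t]
            dh = dH[:, t] + dh_carry
            do = dh * tanh_c
            dc = dc_carry + dh * o * (1 - tanh_c**2)
            di = dc * g
            dg = dc * i
            df = dc * c_prev
            dc_carry = dc * f
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g**2), do * o * (1 - o)],
                axis=1,
            )
            dW += x_t.T @ dz
            dU += h_prev.T @ dz
            db += dz.sum(axis=0)
            dX[:, t] = dz @ self.W.T
            dh_carry = dz @ self.U.T
        return dX, [dW, dU, db]


class SudClassifier(BaseEstimator, ClassifierMixin):
    """Bidirectional LSTM + attention classifier over post-history features.

    scikit-learn-style estimator: ``fit(sequences, y)`` on a list of
    :class:`FeatureSequence` with SUDP/SUDA labels, then ``predict`` /
    ``predict_proba``. With ``use_history=False`` the network reduces to a
    feed-forward classifier on the target-post vector and is exactly invariant
    to the history; with ``use_attention=False`` the recurrent outputs are
    mean-pooled over valid steps instead of attention-pooled.

    Fitted attributes end in an underscore; ``dt_mean_``/``dt_std_`` hold the
    training-set standardization of the log1p time-gap feature.
    """

    def __init__(
        self,
        hidden_dim: int = 32,
        ff_dim: int = 32,
        attention_dim: int = 32,
        epochs: int = 10,
        learning_rate: float = 1e-3,
        batch_size: int = 64,
        dropout: float = 0.2,
        seed: int = 0,
        use_attention: bool = True,
        use_history: bool = True,
    ):
        self.hidden_dim = hidden_dim
        self.ff_dim = ff_dim
        self.attention_dim = attention_dim
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.dropout = dropout
        self.seed = seed
        self.use_attention = use_attention
        self.use_history = use_history

    # -- array assembly ----------------------------------------------------
    def _stack(self, sequences: Sequence[FeatureSequence]):
        X = np.stack(
            [
                np.concatenate(
                    [s.content, s.sentiment, s.emotion, s.delta_t[:, None]], axis=1
                )
                for s in sequences
            ]
        )
        valid = np.stack([s.valid for s in sequences])
        T = np.stack([s.target_vec for s in sequences])
        return X, valid, T

    def _standardize_dt(self, X: np.ndarray, valid: np.ndarray) -> np.ndarray:
        X = X.copy()
        dt = X[:, :, -1]
        dt = np.where(valid, (dt - self.dt_mean_) / self.dt_std_, 0.0)
        X[:, :, -1] = dt
        return X

    # -- forward -----------------------------------------------------------
    @staticmethod
    def _softmax(z: np.ndarray) -> np.ndarray:
        z = z - z.max(axis=-1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=-1, keepdims=True)

    def _forward(self, X, valid, T, drop_mask=None):
        """Full forward pass; returns probabilities and a cache for backward."""
        cache: dict = {"valid": valid, "T": T}
        if self.use_history:
            Hf, cf = self.lstm_f_.forward(X)
            Hb_rev, cb = self.lstm_b_.forward(X[:, ::-1])
            Hb = Hb_rev[:, ::-1]
            H = np.concatenate([Hf, Hb], axis=2)  # (B, K, 2d)
            vmask = valid.astype(float)
            n_valid = vmask.sum(axis=1, keepdims=True)  # (B, 1)
            if self.use_attention:
                U = np.tanh(H @ self.Wa_ + self.ba_)  # (B, K, a)
                scores = U @ self.va_  # (B, K)
                scores = np.where(valid, scores, -np.inf)
                # rows with no valid step get an all-zero attention vector
                safe = np.where(np.isneginf(scores), -1e30, scores)
                alpha = self._softmax(safe) * vmask
                denom = np.maximum(alpha.sum(axis=1, keepdims=True), 1e-12)
                alpha = alpha / denom * (n_valid > 0)
                ctx = np.einsum("bk,bkh->bh", alpha, H)
                cache.update(U=U, alpha=alpha, H=H, cf=cf, cb=cb)
            else:
                denom = np.maximum(n_valid, 1.0)
                ctx = (H * vmask[:, :, None]).sum(axis=1) / denom
                cache.update(H=H, cf=cf, cb=cb, denom=denom)
            z = np.concatenate([ctx, T], axis=1)
        else:
            z = T
        pre = z @ self.W1_ + self.b1_
        f = np.maximum(pre, 0.0)
        if drop_mask is not None:
            f = f * drop_mask
        logits = f @ self.W2_ + self.b2_
        probs = self._softmax(logits)
        cache.update(z=z, pre=pre, f=f, drop_mask=drop_mask, probs=probs)
        return probs, cache

    def _backward(self, cache, y_idx):
        """Analytic gradients of mean cross-entropy w.r.t. every parameter."""
        probs = cache["probs"]
        B = probs.shape[0]
        dlogits = probs.copy()
        dlogits[np.arange(B), y_idx] -= 1.0
        dlogits /= B

        f, z, pre = cache["f"], cache["z"], cache["pre"]
        grads = {
            "W2_": f.T @ dlogits,
            "b2_": dlogits.sum(axis=0),
        }
        df = dlogits @ self.W2_.T
        if cache["drop_mask"] is not None:
            df = df * cache["drop_mask"]
        dpre = df * (pre > 0)
        grads["W1_"] = z.T @ dpre
        grads["b1_"] = dpre.sum(axis=0)
        dz = dpre @ self.W1_.T

        if not self.use_history:
            return grads

        d = self.hidden_dim
        dctx = dz[:, : 2 * d]
        H = cache["H"]
        valid = cache["valid"]
        vmask = valid.astype(float)
        if self.use_attention:
            alpha, U = cache["alpha"], cache["U"]
            dH = alpha[:, :, None] * dctx[:, None, :]
            dalpha = np.einsum("bh,bkh->bk", dctx, H)
            # softmax jacobian restricted to valid steps
            inner = (alpha * dalpha).sum(axis=1, keepdims=True)
            dscores = alpha * (dalpha - inner)
            dU_att = dscores[:, :, None] * self.va_[None, None, :]
            dpre_att = dU_att * (1 - U**2)
            grads["va_"] = np.einsum("bka,bk->a", U, dscores)
            grads["Wa_"] = np.einsum("bkh,bka->ha", H, dpre_att)
            grads["ba_"] = dpre_att.sum(axis=(0, 1))
            dH = dH + dpre_att @ self.Wa_.T
        else:
            denom = cache["denom"]
            dH = (vmask / denom)[:, :, None] * dctx[:, None, :]

        dHf = dH[:, :, :d]
        dHb = dH[:, :, d:]
        _, g_f = self.lstm_f_.backward(dHf, cache["cf"])
        _, g_b = self.lstm_b_.backward(dHb[:, ::-1], cache["cb"])
        grads["lstm_f"] = g_f
        grads["lstm_b"] = g_b
        return grads

    # -- estimator API -----------------------------------------------------
    def fit(self, sequences: Sequence[FeatureSequence], y: Sequence[str], eval_set=None):
        sequences, y = list(sequences), list(y)
        if len(sequences) != len(y) or not sequences:
            raise ValueError("sequences and y must be equal-length and non-empty")
        self.classes_ = np.array(sorted(set(y)))
        if len(self.classes_) != 2:
            raise ValueError(
                f"SUD detection is binary; got classes {list(self.classes_)}"
            )
        class_index = {c: i for i, c in enumerate(self.classes_)}
        y_idx = np.array([class_index[label] for label in y])

        X, valid, T = self._stack(sequences)
        h_dim = T.shape[1]
        if X.shape[2] != 3 * h_dim + 1:
            raise ValueError("feature width mismatch between steps and target vector")
        dts = X[:, :, -1][valid]
        self.dt_mean_ = float(dts.mean()) if dts.size else 0.0
        self.dt_std_ = float(dts.std()) if dts.size and dts.std() > 1e-8 else 1.0
        X = self._standardize_dt(X, valid)

        rng = np.random.default_rng(self.seed)
        d, a, ff = self.hidden_dim, self.attention_dim, self.ff_dim
        D = X.shape[2]
        self.lstm_f_ = _LSTM(D, d, rng)
        self.lstm_b_ = _LSTM(D, d, rng)
        self.Wa_ = rng.uniform(-1, 1, (2 * d, a)) / np.sqrt(2 * d)
        self.ba_ = np.zeros(a)
        self.va_ = rng.uniform(-1, 1, a) / np.sqrt(a)
        z_dim = (2 * d + h_dim) if self.use_history else h_dim
        self.W1_ = rng.uniform(-1, 1, (z_dim, ff)) / np.sqrt(z_dim)
        self.b1_ = np.zeros(ff)
        self.W2_ = rng.uniform(-1, 1, (ff, 2)) / np.sqrt(ff)
        self.b2_ = np.zeros(2)

        names = ["W1_", "b1_", "W2_", "b2_"]
        if self.use_history:
            names = ["Wa_", "ba_", "va_"] + names
        flat_params = [getattr(self, n) for n in names]
        if self.use_history:
            flat_params += self.lstm_f_.params() + self.lstm_b_.params()
        adam_m = [np.zeros_like(p) for p in flat_params]
        adam_v = [np.zeros_like(p) for p in flat_params]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0
        self.history_ = []

        def flat_grads(grads: dict) -> list[np.ndarray]:
            out = [grads.get(n, np.zeros_like(getattr(self, n))) for n in names]
            if self.use_history:
                zf = [np.zeros_like(p) for p in self.lstm_f_.params()]
                out += grads.get("lstm_f", zf)
                zb = [np.zeros_like(p) for p in self.lstm_b_.params()]
                out += grads.get("lstm_b", zb)
            return out

        n = len(sequences)
        for epoch in range(self.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for lo in range(0, n, self.batch_size):
                batch = order[lo : lo + self.batch_size]
                drop = None
                if self.dropout > 0:
                    keep = 1.0 - self.dropout
                    drop = (rng.random((len(batch), self.ff_dim)) < keep) / keep
                probs, cache = self._forward(
                    X[batch], valid[batch], T[batch], drop_mask=drop
                )
                epoch_loss -= float(
                    np.log(probs[np.arange(len(batch)), y_idx[batch]] + 1e-12).sum()
                )
                grads = self._backward(cache, y_idx[batch])
                step += 1
                for p, g, m, v in zip(flat_params, flat_grads(grads), adam_m, adam_v):
                    m += (1 - beta1) * (g - m)
                    v += (1 - beta2) * (g * g - v)
                    p -= (
                        self.learning_rate
                        * (m / (1 - beta1**step))
                        / (np.sqrt(v / (1 - beta2**step)) + eps)
                    )
            record = {"epoch": epoch, "train_loss": epoch_loss / n}
            if eval_set is not None:
                f1, prec, rec = macro_metrics(eval_set[1], self.predict(eval_set[0]))
                record.update(dev_macro_f1=f1, dev_precision=prec, dev_recall=rec)
            logger.info("epoch %d: %s", epoch, record)
            self.history_.append(record)
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "W1_"):
            raise NotFittedError("SudClassifier is not fitted yet")

    def predict_proba(self, sequences: Sequence[FeatureSequence]) -> np.ndarray:
        """Class probabilities in inference mode (dropout off); deterministic."""
        self._check_fitted()
        X, valid, T = self._stack(sequences)
        X = self._standardize_dt(X, valid)
        probs, _ = self._forward(X, valid, T, drop_mask=None)
        return probs

    def predict(self, sequences: Sequence[FeatureSequence]) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(sequences), axis=1)]

    def attention_weights(self, sequences: Sequence[FeatureSequence]) -> np.ndarray:
        """Per-example attention distribution over history steps (zeros if padded)."""
        self._check_fitted()
        if not (self.use_history and self.use_attention):
            raise ValueError("model was built without an attention layer")
        X, valid, T = self._stack(sequences)
        X = self._standardize_dt(X, valid)
        _, cache = self._forward(X, valid, T, drop_mask=None)
        return cache["alpha"]

    def score(self, sequences, y) -> float:
        return macro_metrics(y, self.predict(sequences))[0]


# -- pipeline-level training, prediction and ablation -----------------------


def _build_dataset(
    examples, models: FeatureModels, lexicon: Lexicon, k: int, use_masking: bool
):
    sequences = [
        build_feature_sequence(t, h, models, lexicon, k=k, use_masking=use_masking)
        for t, h, _ in examples
    ]
    labels = [label for _, _, label in examples]
    return sequences, labels


def train_sud(
    examples: Sequence[tuple[Post, PostHistory, str]],
    models: FeatureModels,
    lexicon: Lexicon,
    config: SudTrainConfig | None = None,
    ablation: AblationConfig | None = None,
) -> SudClassifier:
    """Train the sequence model on labeled (target, history, label) triples.

    The data is stratified-split 75:5:20 by label; dev metrics are logged per
    epoch and the fitted model carries ``test_metrics_`` (macro-F1, precision,
    recall on the held-out test part) plus the feature-building context needed
    by :func:`predict_sud`.
    """
    config = config or SudTrainConfig()
    ablation = ablation or AblationConfig()
    spec = SplitSpec(seed=config.seed, strata_key=lambda ex: ex[2])
    train, dev, test = stratified_split(list(examples), spec)

    def featurize(part):
        return _build_dataset(
            part, models, lexicon, k=config.history_len, use_masking=ablation.use_masking
        )

    X_tr, y_tr = featurize(train)
    X_dev, y_dev = featurize(dev)
    X_te, y_te = featurize(test)

    model = SudClassifier(
        hidden_dim=config.hidden_dim,
        ff_dim=config.ff_dim,
        attention_dim=config.attention_dim,
        epochs=config.epochs,
        learning_rate=config.learning_rate,
        batch_size=config.batch_size,
        dropout=config.dropout,
        seed=config.seed,
        use_attention=ablation.use_attention,
        use_history=ablation.use_history,
    )
    model.fit(X_tr, y_tr, eval_set=(X_dev, y_dev))
    f1, prec, rec = macro_metrics(y_te, model.predict(X_te))
    model.test_metrics_ = {"macro_f1": f1, "precision": prec, "recall": rec}
    model.feature_models_ = models
    model.lexicon_ = lexicon
    model.k_ = config.history_len
    model.use_masking_ = ablation.use_masking
    logger.info("test metrics: %s", model.test_metrics_)
    return model


def predict_sud(
    model: SudClassifier, target: Post, history: PostHistory
) -> SudPrediction:
    """Label one post given its history, using the model's stored feature context."""
    model._check_fitted()
    if not hasattr(model, "feature_models_"):
        raise NotFittedError(
            "model lacks feature-building context; train it with train_sud"
        )
    seq = build_feature_sequence(
        target,
        history,
        model.feature_models_,
        model.lexicon_,
        k=model.k_,
        use_masking=model.use_masking_,
    )
    probs = model.predict_proba([seq])[0]
    label = str(model.classes_[int(np.argmax(probs))])
    return SudPrediction(label=label, probabilities=probs, classes=tuple(model.classes_))


def tfidf_logreg_baseline(
    examples: Sequence[tuple[Post, PostHistory, str]], seed: int = 0
) -> dict:
    """Language-feature baseline: TF-IDF n-grams of the target text + logistic
    regression, under the same 75:5:20 split protocol."""
    spec = SplitSpec(seed=seed, strata_key=lambda ex: ex[2])
    train, _, test = stratified_split(list(examples), spec)
    vec = TfidfVectorizer(ngram_range=(1, 2), min_df=1)
    Xtr = vec.fit_transform([t.text for t, _, _ in train])
    clf = LogisticRegression(max_iter=1000, random_state=seed)
    clf.fit(Xtr, [l for _, _, l in train])
    y_pred = clf.predict(vec.transform([t.text for t, _, _ in test]))
    f1, prec, rec = macro_metrics([l for _, _, l in test], y_pred)
    return {"macro_f1": f1, "precision": prec, "recall": rec}


_VARIANTS = {
    "full": AblationConfig(),
    "minus_attention": AblationConfig(use_attention=False),
    "minus_masking": AblationConfig(use_masking=False),
    "minus_history": AblationConfig(use_history=False),
}


def run_ablation(
    examples: Sequence[tuple[Post, PostHistory, str]],
    models: FeatureModels,
    lexicon: Lexicon,
    config: SudTrainConfig | None = None,
    n_runs: int = 5,
    base_seed: int = 0,
) -> pd.DataFrame:
    """Median test metrics for the full model and its minus-one-component variants.

    Each variant is trained ``n_runs`` times with seeds derived from
    ``base_seed``; medians of macro-F1/precision/recall are reported per
    variant along with deltas (full minus variant, so a weaker variant shows a
    positive drop). A TF-IDF + logistic-regression baseline rides along.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    config = config or SudTrainConfig()
    rows = {}
    for name, ablation in _VARIANTS.items():
        runs = []
        for r in range(n_runs):
            run_config = SudTrainConfig(
                **{
                    **config.__dict__,
                    "seed": (base_seed * 1000 + r * 101 + 17) % (2**31 - 1),
                }
            )
            model = train_sud(examples, models, lexicon, run_config, ablation)
            runs.append(model.test_metrics_)
        rows[name] = median_over_runs(runs)
    baseline_runs = [
        tfidf_logreg_baseline(examples, seed=(base_seed * 1000 + r * 101 + 17) % (2**31 - 1))
        for r in range(n_runs)
    ]
    rows["tfidf_logreg"] = median_over_runs(baseline_runs)

    table = pd.DataFrame(rows).T
    for metric in ("macro_f1", "precision", "recall"):
        table[f"delta_{metric}"] = table.loc["full", metric] - table[metric]
    return table
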