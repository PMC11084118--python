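"""Sequence classifier: features, gradients, ablations, prediction contracts."""

from dataclasses import replace
from datetime import datetime, timedelta, timezone

import numpy as np
import pytest

from sudscope import Post, PostHistory, build_feature_sequence, predict_sud, train_sud
from sudscope.sud import (
    AblationConfig,
    FeatureSequence,
    SudClassifier,
    SudTrainConfig,
    encode_post,
    run_ablation,
)
from sudscope.encoders import EmbeddingBagEncoder


def make_post(pid, hours, text="hello world", author="u1"):
    t0 = datetime(2019, 1, 1, tzinfo=timezone.utc)
    return Post(
        post_id=pid, author_id=author, timestamp=t0 + timedelta(hours=hours), text=text
    )


def random_sequences(rng, n, k=3, h=4):
    seqs = []
    for _ in range(n):
        n_valid = int(rng.integers(1, k + 1))
        valid = np.zeros(k, dtype=bool)
        valid[k - n_valid :] = True
        mk = lambda: rng.normal(size=(k, h)) * valid[:, None]
        seqs.append(
            FeatureSequence(
                content=mk(),
                sentiment=mk(),
                emotion=mk(),
                delta_t=np.abs(rng.normal(size=k)) * valid,
                valid=valid,
                target_vec=rng.normal(size=h),
            )
        )
    return seqs


class TestEncodePost:
    def test_single_token_is_that_tokens_vector(self):
        enc = EmbeddingBagEncoder(dim=8, seed=0)
        assert np.allclose(encode_post("fentanyl", enc), enc.token_vector("fentanyl"))

    def test_token_order_invariance(self):
        enc = EmbeddingBagEncoder(dim=8, seed=0)
        assert np.allclose(
            encode_post("alpha beta gamma", enc), encode_post("gamma alpha beta", enc)
        )

    def test_mask_tokens_get_distinct_vectors(self):
        enc = EmbeddingBagEncoder(dim=16, seed=0)
        a = encode_post("[DRUG_FENTANYL]", enc)
        b = encode_post("[DRUG_KRATOM]", enc)
        assert not np.allclose(a, b)

    def test_empty_text_zero_vector_with_warning(self):
        enc = EmbeddingBagEncoder(dim=8, seed=0)
        with pytest.warns(UserWarning, match="empty"):
            assert np.array_equal(encode_post("...", enc), np.zeros(8))


class TestBuildFeatureSequence:
    def test_empty_history_all_padded(self, feature_models, lexicon):
        target = make_post("t", 100, "feeling odd about fent")
        seq = build_feature_sequence(
            target, PostHistory(()), feature_models, lexicon, k=5
        )
        assert not seq.valid.any()
        assert np.allclose(seq.content, 0)
        assert np.linalg.norm(seq.target_vec) > 0

    def test_truncation_keeps_most_recent(self, feature_models, lexicon):
        history = PostHistory(tuple(make_post(f"h{i}", i, f"post {i}") for i in range(5)))
        target = make_post("t", 100)
        seq = build_feature_sequence(target, history, feature_models, lexicon, k=3)
        assert seq.valid.all()
        expected = build_feature_sequence(
            target, PostHistory(history.posts[-3:]), feature_models, lexicon, k=3
        )
        assert np.allclose(seq.content[1:], expected.content[1:])

    def test_delta_t_log1p_hours(self, feature_models, lexicon):
        history = PostHistory((make_post("h0", 0), make_post("h1", 1)))
        seq = build_feature_sequence(
            make_post("t", 10), history, feature_models, lexicon, k=4
        )
        assert seq.delta_t[-1] == pytest.approx(np.log1p(1.0))
        assert seq.delta_t[-2] == pytest.approx(0.0)  # first step, hours since earliest

    def test_timestamp_violation_rejected(self, feature_models, lexicon):
        history = PostHistory((make_post("h0", 50),))
        with pytest.raises(ValueError, match="precede"):
            build_feature_sequence(
                make_post("t", 10), history, feature_models, lexicon
            )

    def test_masking_changes_features(self, feature_models, lexicon):
        history = PostHistory((make_post("h0", 0, "scored some fent today"),))
        target = make_post("t", 10, "another fent day")
        masked = build_feature_sequence(target, history, feature_models, lexicon, k=2)
        raw = build_feature_sequence(
            target, history, feature_models, lexicon, k=2, use_masking=False
        )
        assert not np.allclose(masked.target_vec, raw.target_vec)


class TestGradients:
    @pytest.mark.parametrize("use_attention,use_history", [
        (True, True), (False, True), (True, False),
    ])
    def test_analytic_gradients_match_numerical(self, rng, use_attention, use_history):
        """Backprop through BiLSTM, attention and dense layers is exact."""
        seqs = random_sequences(rng, 6, k=3, h=4)
        y = ["SUDP", "SUDA"] * 3
        model = SudClassifier(
            hidden_dim=3, ff_dim=4, attention_dim=3, epochs=0, dropout=0.0,
            seed=0, use_attention=use_attention, use_history=use_history,
        )
        model.fit(seqs, y)  # zero epochs: initializes parameters only
        X, valid, T = model._stack(seqs)
        X = model._standardize_dt(X, valid)
        y_idx = np.array([0 if label == model.classes_[0] else 1 for label in y])

        def loss():
            probs, _ = model._forward(X, valid, T)
            return -float(np.log(probs[np.arange(len(y)), y_idx] + 1e-12).mean())

        probs, cache = model._forward(X, valid, T)
        grads = model._backward(cache, y_idx)

        named = {"W1_": grads["W1_"], "b2_": grads["b2_"]}
        if use_history:
            named["lstm_f.W"] = grads["lstm_f"][0]
            named["lstm_b.U"] = grads["lstm_b"][1]
            if use_attention:
                named["Wa_"] = grads["Wa_"]
                named["va_"] = grads["va_"]
        params = {
            "W1_": model.W1_, "b2_": model.b2_, "Wa_": getattr(model, "Wa_", None),
            "va_": getattr(model, "va_", None),
        }
        if use_history:
            params["lstm_f.W"] = model.lstm_f_.W
            params["lstm_b.U"] = model.lstm_b_.U

        eps = 1e-6
        for name, grad in named.items():
            p = params[name]
            flat = p.reshape(-1)
            for idx in rng.choice(flat.size, size=min(5, flat.size), replace=False):
                orig = flat[idx]
                flat[idx] = orig + eps
                up = loss()
                flat[idx] = orig - eps
                down = loss()
                flat[idx] = orig
                numeric = (up - down) / (2 * eps)
                assert grad.reshape(-1)[idx] == pytest.approx(numeric, rel=1e-4, abs=1e-7), name


class TestSudClassifier:
    def test_probabilities_normalized(self, rng):
        seqs = random_sequences(rng, 12)
        model = SudClassifier(hidden_dim=4, ff_dim=4, epochs=2, seed=0)
        model.fit(seqs, ["SUDP", "SUDA"] * 6)
        probs = model.predict_proba(random_sequences(rng, 5))
        assert np.all(probs >= 0)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_seed_determinism_of_training(self, rng):
        seqs = random_sequences(rng, 16)
        y = ["SUDP", "SUDA"] * 8
        runs = []
        for _ in range(2):
            model = SudClassifier(hidden_dim=4, ff_dim=4, epochs=3, seed=9)
            model.fit(seqs, y)
            runs.append([rec["train_loss"] for rec in model.history_])
        assert runs[0] == runs[1]

    def test_minus_history_invariant_to_history(self, rng):
        seqs = random_sequences(rng, 12)
        model = SudClassifier(hidden_dim=4, ff_dim=4, epochs=2, seed=0,
                              use_history=False)
        model.fit(seqs, ["SUDP", "SUDA"] * 6)
        a = random_sequences(rng, 4)
        b = [
            replace(
                s,
                content=np.random.default_rng(1).normal(size=s.content.shape)
                * s.valid[:, None],
            )
            for s in a
        ]
        assert np.array_equal(model.predict_proba(a), model.predict_proba(b))

    def test_attention_weights_normalized_over_valid_steps(self, rng):
        seqs = random_sequences(rng, 10)
        model = SudClassifier(hidden_dim=4, ff_dim=4, epochs=2, seed=0)
        model.fit(seqs, ["SUDP", "SUDA"] * 5)
        alpha = model.attention_weights(seqs)
        valid = np.stack([s.valid for s in seqs])
        assert np.all(alpha >= 0)
        assert np.allclose(alpha.sum(axis=1), 1.0)
        assert np.all(alpha[~valid] == 0)

    def test_non_binary_labels_rejected(self, rng):
        seqs = random_sequences(rng, 6)
        with pytest.raises(ValueError, match="binary"):
            SudClassifier().fit(seqs, ["a", "b", "c", "a", "b", "c"])

    def test_k1_no_attention_reduces_to_feedforward(self, rng):
        """With a single step and attention off, the pooled context is just that
        step's BiLSTM output: the model is a feed-forward net over one step."""
        seqs = random_sequences(rng, 8, k=1, h=4)
        for s in seqs:
            assert s.valid.all()
        model = SudClassifier(hidden_dim=3, ff_dim=4, epochs=1, seed=0,
                              use_attention=False, dropout=0.0)
        model.fit(seqs, ["SUDP", "SUDA"] * 4)
        X, valid, T = model._stack(seqs)
        X = model._standardize_dt(X, valid)
        _, cache = model._forward(X, valid, T)
        H = cache["H"]  # (B, 1, 2d): single recurrent step
        ctx = H[:, 0, :]
        z = np.concatenate([ctx, T], axis=1)
        f = np.maximum(z @ model.W1_ + model.b1_, 0)
        logits = f @ model.W2_ + model.b2_
        assert np.allclose(model._softmax(logits), model.predict_proba(seqs))


# small-corpus desk configuration: few batches per epoch, so more epochs
@pytest.fixture(scope="module")
def trained(small_examples, feature_models, lexicon):
    config = SudTrainConfig(hidden_dim=16, history_len=8, seed=0, epochs=25)
    return train_sud(small_examples, feature_models, lexicon, config)


class TestPipelineTraining:

    def test_history_signal_recovered(self, trained):
        assert trained.test_metrics_["macro_f1"] >= 0.8

    def test_predict_sud_contract(self, trained, small_examples):
        target, history, _ = small_examples[0]
        pred = predict_sud(trained, target, history)
        assert pred.label in ("SUDP", "SUDA")
        assert pred.probabilities.sum() == pytest.approx(1.0, abs=1e-6)
        again = predict_sud(trained, target, history)
        assert np.array_equal(pred.probabilities, again.probabilities)

    def test_sudp_probability_ordering(self, trained, small_examples, feature_models,
                                       lexicon):
        from sudscope.sud import _build_dataset

        seqs, labels = _build_dataset(small_examples, feature_models, lexicon, 8, True)
        probs = trained.predict_proba(seqs)
        sudp_col = list(trained.classes_).index("SUDP")
        p = probs[:, sudp_col]
        labels = np.array(labels)
        assert p[labels == "SUDP"].mean() > p[labels == "SUDA"].mean()

    def test_label_shuffled_corpus_at_chance(self, small_examples, feature_models,
                                             lexicon):
        rng = np.random.default_rng(0)
        labels = [l for _, _, l in small_examples]
        rng.shuffle(labels)
        shuffled = [(t, h, l) for (t, h, _), l in zip(small_examples, labels)]
        config = SudTrainConfig(hidden_dim=16, history_len=8, seed=0, epochs=25)
        model = train_sud(shuffled, feature_models, lexicon, config)
        assert model.test_metrics_["macro_f1"] == pytest.approx(0.5, abs=0.25)


class TestRunAblation:
    def test_single_run_medians_and_deltas(self, small_examples, feature_models,
                                           lexicon):
        config = SudTrainConfig(hidden_dim=16, history_len=8, epochs=5)
        table = run_ablation(
            small_examples, feature_models, lexicon, config, n_runs=1, base_seed=0
        )
        assert {"full", "minus_attention", "minus_masking", "minus_history",
                "tfidf_logreg"} <= set(table.index)
        for metric in ("macro_f1", "precision", "recall"):
            expected = table.loc["full", metric] - table[metric]
            assert np.allclose(table[f"delta_{metric}"], expected)
        assert table.loc["full", "delta_macro_f1"] == 0.0
        # planted signal: the history-blind variant trails the full model
        assert table.loc["full", "macro_f1"] >= table.loc["minus_history", "macro_f1"]
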