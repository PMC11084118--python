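"""End-to-end orchestration: corpus -> affect models -> features -> SUD model.

These helpers wire the stages together the way the full study runs them:
train the sentiment and emotion feature extractors, freeze them, featurize
every (target, history) pair, and train/evaluate the sequence classifier and
its ablation variants. The synthetic-recovery experiment repeats this over
several corpus seeds and reports median test metrics per variant.
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np

from sudscope.affect import AffectClassifier, TrainConfig, weak_label_emotion
from sudscope.encoders import EmbeddingBagEncoder
from sudscope.evaluation import median_over_runs
from sudscope.lexicon import Lexicon, default_lexicon, mask_text, scrub_pii
from sudscope.sud import (
    AblationConfig,
    FeatureModels,
    SudTrainConfig,
    train_sud,
)
from sudscope.synthetic import (
    GeneratorConfig,
    examples_from_posts,
    generate_emotion_tweets,
    generate_posts,
)

__all__ = ["train_feature_models", "run_synthetic_experiment"]

logger = logging.getLogger(__name__)


def _prepare(text: str, lexicon: Lexicon) -> str:
    return mask_text(scrub_pii(text), lexicon)


def train_feature_models(
    posts,
    emotion_tweets,
    lexicon: Lexicon,
    hidden_dim: int = 32,
    seed: int = 0,
    max_train: int = 2500,
) -> FeatureModels:
    """Train the frozen sentiment/emotion extractors and build the encoder bundle.

    The sentiment model learns from posts carrying ground-truth sentiment; the
    emotion model from hashtag-weak-labeled tweets. Both see scrubbed, masked
    text — the same representation the sequence model will query them with.
    ``max_train`` caps the per-task corpus for desk-scale runtimes.
    """
    rng = np.random.default_rng(seed)
    cfg = TrainConfig(hidden_dim=hidden_dim, seed=seed)

    sent_pairs = [
        (_prepare(p.text, lexicon), p.sentiment) for p in posts if p.sentiment
    ]
    if len(sent_pairs) > max_train:
        idx = rng.choice(len(sent_pairs), size=max_train, replace=False)
        sent_pairs = [sent_pairs[i] for i in sorted(idx)]
    sentiment_model = AffectClassifier(
        hidden_dim=cfg.hidden_dim, epochs=cfg.epochs, learning_rate=cfg.learning_rate,
        batch_size=cfg.batch_size, seed=cfg.seed,
    ).fit([t for t, _ in sent_pairs], [l for _, l in sent_pairs])

    emo_pairs = [pair for pair in map(weak_label_emotion, emotion_tweets) if pair]
    emo_pairs = [(_prepare(t, lexicon), l) for t, l in emo_pairs][:max_train]
    emotion_model = AffectClassifier(
        hidden_dim=cfg.hidden_dim, epochs=cfg.epochs, learning_rate=cfg.learning_rate,
        batch_size=cfg.batch_size, seed=cfg.seed + 1,
    ).fit([t for t, _ in emo_pairs], [l for _, l in emo_pairs])

    encoder = EmbeddingBagEncoder(dim=hidden_dim, seed=seed)
    return FeatureModels(
        encoder=encoder, sentiment_model=sentiment_model, emotion_model=emotion_model
    )


_EXPERIMENT_VARIANTS = {
    "full": AblationConfig(),
    "minus_attention": AblationConfig(use_attention=False),
    "minus_history": AblationConfig(use_history=False),
}


def run_synthetic_experiment(
    base_seed: int = 0,
    n_seeds: int = 5,
    generator: GeneratorConfig | None = None,
    sud_config: SudTrainConfig | None = None,
    hidden_dim: int = 32,
    variants: dict[str, AblationConfig] | None = None,
) -> dict:
    """Planted-signal recovery study over independently seeded corpora.

    For each seed: generate a default-condition corpus, train the affect
    extractors, then train the full sequence model and the requested ablation
    variants, recording held-out test metrics. Returns per-variant medians
    (and the per-seed records under ``"runs"``).
    """
    generator = generator or GeneratorConfig()
    variants = variants or _EXPERIMENT_VARIANTS
    per_variant: dict[str, list[dict]] = {name: [] for name in variants}
    lexicon = default_lexicon()

    for s in range(n_seeds):
        seed = (base_seed * 7919 + s * 104729 + 1) % (2**31 - 1)
        gen = replace(generator, seed=seed)
        posts = generate_posts(gen, lexicon)
        tweets = generate_emotion_tweets(seed=seed, n_per_emotion=60)
        models = train_feature_models(
            posts, tweets, lexicon, hidden_dim=hidden_dim, seed=seed
        )
        examples = examples_from_posts(posts)
        cfg = sud_config or SudTrainConfig(
            hidden_dim=hidden_dim, history_len=generator.history_len
        )
        cfg = replace(cfg, seed=seed)
        for name, ablation in variants.items():
            model = train_sud(examples, models, lexicon, cfg, ablation)
            per_variant[name].append(model.test_metrics_)
            logger.info("seed %d %s: %s", seed, name, model.test_metrics_)

    result = {name: median_over_runs(runs) for name, runs in per_variant.items()}
    result["runs"] = per_variant
    return result
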