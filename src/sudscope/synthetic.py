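"""Synthetic corpora with planted ground truth for end-to-end testing.

No corpus used by this pipeline is publicly deposited, so every stage is
exercised on generated stand-ins that mimic their statistical structure:

* a drug lexicon spanning all eight categories (fixed generic terms, seeded
  pseudo-slang),
* per-author timestamped post histories in which the SUDP/SUDA state drives
  the *historical* sentiment/emotion trajectory (P(negative | SUDP) = 0.8 vs
  P(negative | SUDA) = 0.3 by default, sadness/fear skew under SUDP) while the
  target post's text is class-neutral — so a classifier can only succeed by
  reading the history,
* emotion-hashtag tweets for distant supervision, and
* cryptomarket listings with configured category shares (heroin 57.8% by
  default) and exactly recoverable templated quantities and prices.

Everything is deterministic per seed (integer-state PRNG, no hash-order
dependence).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone
from pathlib import Path

import numpy as np

from sudscope.corpus import Post, PostHistory
from sudscope.lexicon import CATEGORIES, Lexicon, LexiconEntry, default_lexicon
from sudscope.listings import RawListing, format_price

__all__ = [
    "GeneratorConfig",
    "generate_lexicon",
    "generate_posts",
    "generate_emotion_tweets",
    "generate_listings",
    "examples_from_posts",
]

#: drug-category proportions echoing the subreddit corpus composition
_POST_CATEGORY_SHARES = {
    "heroin": 0.4708,
    "kratom": 0.2666,
    "fentanyl": 0.1245,
    "oxycodone": 0.0891,
    "opium": 0.0333,
    "nonpharmaceutical_fentanyl": 0.0096,
    "pharmaceutical_fentanyl": 0.0031,
    "synthetic_heroin": 0.0030,
}

#: listing-category proportions echoing the marketplace composition
#: (heroin 57.8% of matched listings, novel synthetics 4.2%)
_LISTING_CATEGORY_SHARES = {
    "heroin": 0.578,
    "synthetic_heroin": 0.042,
    "pharmaceutical_fentanyl": 0.010,
    "nonpharmaceutical_fentanyl": 0.009,
    "fentanyl": 0.150,
    "oxycodone": 0.120,
    "kratom": 0.050,
    "opium": 0.041,
}

_SUDP_EMOTIONS = {
    "sadness": 0.35,
    "fear": 0.20,
    "anger": 0.12,
    "love": 0.10,
    "joy": 0.08,
    "thankfulness": 0.08,
    "surprise": 0.07,
}
_SUDA_EMOTIONS = {
    "joy": 0.22,
    "love": 0.22,
    "thankfulness": 0.18,
    "sadness": 0.12,
    "surprise": 0.10,
    "fear": 0.08,
    "anger": 0.08,
}

_POSITIVE_WORDS = (
    "good", "great", "happy", "hopeful", "relieved", "calm", "proud",
    "strong", "grateful", "better", "glad", "peaceful",
)
_NEGATIVE_WORDS = (
    "awful", "terrible", "sick", "anxious", "depressed", "hopeless",
    "miserable", "exhausted", "desperate", "ashamed", "hurting", "worthless",
)
_EMOTION_WORDS = {
    "joy": ("smiling", "sunshine", "celebrating", "laughing"),
    "sadness": ("tears", "grieving", "downhearted", "sobbing"),
    "anger": ("furious", "fuming", "irritated", "seething"),
    "love": ("adore", "cherish", "sweetheart", "darling"),
    "fear": ("terrified", "dread", "frightened", "panicking"),
    "thankfulness": ("blessed", "appreciate", "gratitude", "thankyou"),
    "surprise": ("unexpected", "astonished", "stunned", "speechless"),
}
# neutral filler vocabulary; deliberately disjoint from the drug lexicon, the
# valence lexicon, negations/boosters and the emotion pools
_FILLER_WORDS = (
    "today", "morning", "later", "update", "writing", "thread", "question",
    "advice", "routine", "weekly", "checking", "notes", "journal", "daily",
    "schedule", "errands", "weather", "coffee", "reading", "evening",
)

_CATEGORY_GENERIC = {
    "heroin": "heroin",
    "synthetic_heroin": "u-47700",
    "pharmaceutical_fentanyl": "duragesic",
    "nonpharmaceutical_fentanyl": "carfentanil",
    "fentanyl": "fentanyl",
    "oxycodone": "oxycodone",
    "kratom": "kratom",
    "opium": "opium",
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic corpora.

    ``p_negative_given_sudp``/``suda`` plant the historical-sentiment signal;
    ``emotion_probs_sudp``/``suda`` shift the emotion mixture (sadness/fear
    dominant under SUDP, echoing the observed per-drug emotion pattern);
    ``target_leak`` optionally plants signal in the target text itself for
    baseline sanity checks. Timestamps span 2015--2020.
    """

    seed: int = 0
    n_authors: int = 400
    posts_per_author: tuple[int, int] = (12, 18)
    history_len: int = 10
    p_negative_given_sudp: float = 0.8
    p_negative_given_suda: float = 0.3
    emotion_probs_sudp: dict = field(default_factory=lambda: dict(_SUDP_EMOTIONS))
    emotion_probs_suda: dict = field(default_factory=lambda: dict(_SUDA_EMOTIONS))
    drug_mention_rate: float = 0.9
    p_sudp: float = 0.5
    timestamp_span: tuple[str, str] = ("2015-01-01", "2020-12-31")
    category_shares: dict = field(default_factory=lambda: dict(_POST_CATEGORY_SHARES))
    target_leak: bool = False
    n_listings: int = 1000
    listing_category_shares: dict = field(
        default_factory=lambda: dict(_LISTING_CATEGORY_SHARES)
    )

    def __post_init__(self) -> None:
        for p in (
            self.p_negative_given_sudp,
            self.p_negative_given_suda,
            self.drug_mention_rate,
            self.p_sudp,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        for shares in (self.category_shares, self.listing_category_shares):
            if abs(sum(shares.values()) - 1.0) > 1e-6:
                raise ValueError("category shares must sum to 1")
            unknown = set(shares) - set(CATEGORIES)
            if unknown:
                raise ValueError(f"unknown categories in shares: {sorted(unknown)}")
        for probs in (self.emotion_probs_sudp, self.emotion_probs_suda):
            if abs(sum(probs.values()) - 1.0) > 1e-6:
                raise ValueError("emotion probabilities must sum to 1")
        if self.posts_per_author[0] < self.history_len:
            raise ValueError(
                f"posts_per_author minimum {self.posts_per_author[0]} is below the "
                f"history window {self.history_len}; histories would be infeasible"
            )


def _pseudo_slang(rng: np.random.Generator) -> str:
    consonants = "bdfgklmnprstvz"
    vowels = "aeiou"
    n_syll = int(rng.integers(2, 4))
    word = "".join(
        consonants[rng.integers(len(consonants))] + vowels[rng.integers(len(vowels))]
        for _ in range(n_syll)
    )
    return word + "x"  # suffix keeps pseudo-slang clear of real vocabulary


def generate_lexicon(seed: int = 0, path=None) -> Lexicon:
    """A minimal deterministic lexicon: per category one fixed generic term and
    two seeded pseudo-slang terms. Optionally written as a loadable TSV."""
    rng = np.random.default_rng(seed)
    entries = []
    used: set[str] = set()
    for category in CATEGORIES:
        generic = _CATEGORY_GENERIC[category]
        entries.append(
            LexiconEntry(generic, generic.capitalize(), category, "generic")
        )
        for _ in range(2):
            slang = _pseudo_slang(rng)
            while slang in used:
                slang = _pseudo_slang(rng)
            used.add(slang)
            entries.append(
                LexiconEntry(slang, generic.capitalize(), category, "slang")
            )
    lexicon = Lexicon(entries)
    if path is not None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t")
            writer.writerow(["surface_form", "normalized_name", "category", "term_type"])
            for e in lexicon:
                writer.writerow([e.surface_form, e.normalized_name, e.category, e.term_type])
    return lexicon


def _choice(rng: np.random.Generator, words, n: int) -> list[str]:
    return [words[int(i)] for i in rng.integers(0, len(words), size=n)]


def _category_terms(lexicon: Lexicon) -> dict[str, list[str]]:
    terms: dict[str, list[str]] = {c: [] for c in CATEGORIES}
    for e in lexicon:
        terms[e.category].append(e.surface_form)
    return terms


def generate_posts(
    config: GeneratorConfig | None = None, lexicon: Lexicon | None = None
) -> list[Post]:
    """Per-author timestamped posts with planted history-borne SUD signal.

    Each author carries a latent SUDP/SUDA state and a drug category. History
    posts mix neutral filler with sentiment words drawn via P(negative | state)
    and emotion words from the state's shifted distribution; the final post per
    author is the class-neutral target carrying the ``sud_label``. Ground-truth
    sentiment and emotion labels ride on every history post.
    """
    config = config or GeneratorConfig()
    lexicon = lexicon or default_lexicon()
    rng = np.random.default_rng(config.seed)
    terms = _category_terms(lexicon)

    categories = list(config.category_shares)
    cat_p = np.array([config.category_shares[c] for c in categories])
    cat_p = cat_p / cat_p.sum()

    span_start = datetime.fromisoformat(config.timestamp_span[0]).replace(
        tzinfo=timezone.utc
    )
    span_end = datetime.fromisoformat(config.timestamp_span[1]).replace(
        tzinfo=timezone.utc
    )
    span_hours = (span_end - span_start).total_seconds() / 3600.0

    posts: list[Post] = []
    for a in range(config.n_authors):
        author = f"author{a:05d}"
        state = "SUDP" if rng.random() < config.p_sudp else "SUDA"
        category = categories[int(rng.choice(len(categories), p=cat_p))]
        cat_terms = terms.get(category) or [_CATEGORY_GENERIC[category]]
        n_posts = int(rng.integers(config.posts_per_author[0],
                                   config.posts_per_author[1] + 1))
        p_neg = (
            config.p_negative_given_sudp
            if state == "SUDP"
            else config.p_negative_given_suda
        )
        emo_probs = (
            config.emotion_probs_sudp if state == "SUDP" else config.emotion_probs_suda
        )
        emotions = list(emo_probs)
        emo_p = np.array([emo_probs[e] for e in emotions])

        # timestamps: random start early enough to fit the history, then
        # exponential gaps with a two-day mean
        start_offset = rng.random() * max(span_hours - 24.0 * 2 * n_posts, 1.0)
        t = span_start + timedelta(hours=float(start_offset))
        for j in range(n_posts):
            t = t + timedelta(hours=float(rng.exponential(48.0) + 1.0))
            is_target = j == n_posts - 1
            words: list[str] = _choice(rng, _FILLER_WORDS, 3)
            if is_target and not config.target_leak:
                sentiment_label = None
                emotion_label = None
            else:
                sentiment_label = "negative" if rng.random() < p_neg else "positive"
                pool = _NEGATIVE_WORDS if sentiment_label == "negative" else _POSITIVE_WORDS
                words.extend(_choice(rng, pool, int(rng.integers(2, 4))))
                emotion_label = emotions[int(rng.choice(len(emotions), p=emo_p))]
                words.extend(_choice(rng, _EMOTION_WORDS[emotion_label], 2))
            if rng.random() < config.drug_mention_rate:
                words.append(cat_terms[int(rng.integers(len(cat_terms)))])
            rng.shuffle(words)
            posts.append(
                Post(
                    post_id=f"{author}_p{j:03d}",
                    author_id=author,
                    timestamp=t,
                    text=" ".join(words),
                    source="synthetic",
                    drug_category=category,
                    sud_label=state if is_target else None,
                    sentiment=sentiment_label,
                    emotion=emotion_label,
                )
            )
    return posts


def examples_from_posts(
    posts: list[Post],
) -> list[tuple[Post, PostHistory, str]]:
    """Group a generated corpus into (target, history, label) training triples.

    The last post of each author is the labeled target; all earlier posts form
    the history (window truncation happens at feature-building time).
    """
    by_author: dict[str, list[Post]] = {}
    for p in posts:
        by_author.setdefault(p.author_id, []).append(p)
    examples = []
    for author in sorted(by_author):
        stream = sorted(by_author[author], key=lambda p: (p.timestamp, p.post_id))
        target = stream[-1]
        if target.sud_label is None:
            continue
        examples.append((target, PostHistory(tuple(stream[:-1])), target.sud_label))
    return examples


def generate_emotion_tweets(seed: int = 0, n_per_emotion: int = 60) -> list[str]:
    """Self-tagged tweets for distant supervision: emotion-keyword text ending
    in the matching hashtag, with occasional scrub-bait handles and URLs."""
    rng = np.random.default_rng(seed)
    tweets = []
    for emotion, pool in _EMOTION_WORDS.items():
        for i in range(n_per_emotion):
            words = _choice(rng, _FILLER_WORDS, 2) + _choice(rng, pool, 3)
            rng.shuffle(words)
            if rng.random() < 0.2:
                words.insert(0, "@someone")
            if rng.random() < 0.2:
                words.append("http://example.com/x")
            tweets.append(" ".join(words) + f" #{emotion}")
    order = rng.permutation(len(tweets))
    return [tweets[i] for i in order]


_LISTING_FILLERS = (
    "AAA", "premium", "quality", "stealth", "express", "shipping", "fast",
    "direct", "sealed", "vacuum",
)
_SHIP_COUNTRIES = ("Germany", "Netherlands", "USA", "Canada", "UK", "Australia")
_QUANTITIES_G = (1.0, 2.0, 5.0, 10.0, 25.0, 50.0, 100.0, 250.0)


def generate_listings(
    config: GeneratorConfig | None = None, lexicon: Lexicon | None = None
) -> tuple[list[RawListing], dict]:
    """Templated cryptomarket listings with recoverable ground truth.

    Titles follow ``"<qty> <unit> <drug term> <filler> <filler>"`` with mass
    units only, prices are Bitcoin in the supported dialects, and categories
    are drawn from ``listing_category_shares`` — so the parser's market summary
    can be checked against the configured shares and quantities exactly.
    Returns the listings plus a ground-truth manifest.
    """
    config = config or GeneratorConfig()
    lexicon = lexicon or default_lexicon()
    rng = np.random.default_rng(config.seed + 1)
    terms = _category_terms(lexicon)
    categories = list(config.listing_category_shares)
    cat_p = np.array([config.listing_category_shares[c] for c in categories])
    cat_p = cat_p / cat_p.sum()

    listings = []
    truth = {"category": [], "quantity_g": [], "price_btc": []}
    for i in range(config.n_listings):
        category = categories[int(rng.choice(len(categories), p=cat_p))]
        term = terms[category][int(rng.integers(len(terms[category])))]
        qty = float(rng.choice(np.array(_QUANTITIES_G)))
        unit = ("g", "gr", "gram")[int(rng.integers(3))]
        fillers = _choice(rng, _LISTING_FILLERS, 2)
        title = f"{qty:g} {unit} {term} {' '.join(fillers)}"
        price = round(float(rng.uniform(0.001, 0.5)), 4)
        price_text = (
            format_price("BTC", price) if rng.random() < 0.5 else f"{price:g} BTC"
        )
        year = 2015 + int(rng.integers(6))
        month = 1 + int(rng.integers(12))
        listings.append(
            RawListing(
                title=title,
                description=f"{qty:g} {unit} dose lots available",
                vendor=f"vendor{int(rng.integers(60)):03d}",
                price_text=price_text,
                ship_from=_SHIP_COUNTRIES[int(rng.integers(len(_SHIP_COUNTRIES)))],
                ship_to="Worldwide",
                timestamp=datetime(year, month, 1).date(),
            )
        )
        truth["category"].append(category)
        truth["quantity_g"].append(qty)
        truth["price_btc"].append(price)
    return listings, truth
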