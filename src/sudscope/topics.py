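"""TF-IDF n-gram topic extraction per group and over quarterly time bins.

One document per group (e.g. per subreddit or drug category) is formed by
concatenating that group's posts. Unigrams through trigrams are scored with a
smoothed TF-IDF — tf = raw count / group token count, idf = ln((1+N)/(1+df))+1
— after stop-word removal, with drug-mask and scrub tokens excluded so the
topics reflect context terms rather than the query drugs themselves.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from math import log
from typing import Mapping, Sequence

import pandas as pd
from sklearn.feature_extraction.text import ENGLISH_STOP_WORDS

from sudscope.corpus import Post

__all__ = ["TopicTable", "tokenize", "tfidf_topics", "topics_over_time", "group_posts"]

_TOKEN_RE = re.compile(r"\[[a-z_]+\]|[a-z0-9']+")


def tokenize(text: str) -> list[str]:
    """Lowercased word tokens with stop words and bracketed mask tokens removed."""
    return [
        t
        for t in _TOKEN_RE.findall(text.lower())
        if not t.startswith("[") and t not in ENGLISH_STOP_WORDS
    ]


@dataclass(frozen=True)
class TopicTable:
    """Ranked (ngram, tfidf) terms for one group (optionally one calendar quarter)."""

    group: str
    terms: tuple[tuple[str, float], ...]
    n_top: int
    quarter: str | None = field(default=None)

    def __post_init__(self) -> None:
        scores = [s for _, s in self.terms]
        if any(b > a + 1e-12 for a, b in zip(scores, scores[1:])):
            raise ValueError("topic scores must be non-increasing down the ranking")


def _ngrams(tokens: Sequence[str], orders=(1, 2, 3)) -> list[str]:
    out = []
    for n in orders:
        out.extend(
            " ".join(tokens[i : i + n]) for i in range(len(tokens) - n + 1)
        )
    return out


def tfidf_topics(
    corpus: Mapping[str, Sequence[str]], n_top: int = 10
) -> list[TopicTable]:
    """Top TF-IDF n-grams (n = 1..3) per group.

    ``corpus`` maps each group key to its posts; the group's document is their
    concatenation. Scores use tf = count / group token count and the smoothed
    idf = ln((1+N)/(1+df)) + 1, so a single-group corpus stays finite. Ties are
    broken alphabetically; ``n_top`` larger than the vocabulary returns the full
    ranked vocabulary.
    """
    if not corpus:
        raise ValueError("empty corpus: no groups to extract topics from")
    docs = {g: tokenize(" ".join(texts)) for g, texts in corpus.items()}
    n_groups = len(docs)

    doc_counts: dict[str, dict[str, int]] = {}
    df: dict[str, int] = {}
    for g, tokens in docs.items():
        counts: dict[str, int] = {}
        for ng in _ngrams(tokens):
            counts[ng] = counts.get(ng, 0) + 1
        doc_counts[g] = counts
        for ng in counts:
            df[ng] = df.get(ng, 0) + 1

    idf = {ng: log((1 + n_groups) / (1 + d)) + 1.0 for ng, d in df.items()}

    tables = []
    for g in corpus:
        counts = doc_counts[g]
        length = len(docs[g])
        ranked = sorted(
            ((ng, (c / length) * idf[ng]) for ng, c in counts.items()),
            key=lambda kv: (-kv[1], kv[0]),
        )
        tables.append(TopicTable(group=str(g), terms=tuple(ranked[:n_top]), n_top=n_top))
    return tables


def group_posts(posts: Sequence[Post], by: str = "source") -> dict[str, list[str]]:
    """Group post texts by a post attribute (e.g. source or drug_category)."""
    grouped: dict[str, list[str]] = {}
    for p in posts:
        key = getattr(p, by) or "unknown"
        grouped.setdefault(str(key), []).append(p.text)
    return grouped


def topics_over_time(
    posts: Sequence[Post], by: str = "source", n_top: int = 10
) -> list[TopicTable]:
    """Quarterly-binned topic tables: posts are assigned to calendar quarters and
    :func:`tfidf_topics` runs within each quarter; quarters in the observed span
    with no posts emit empty tables."""
    if not posts:
        raise ValueError("empty corpus: no posts to bin")
    periods = [
        pd.Timestamp(p.timestamp).tz_convert("UTC").tz_localize(None).to_period("Q")
        for p in posts
    ]
    by_quarter: dict[pd.Period, list[Post]] = {}
    for period, post in zip(periods, posts):
        by_quarter.setdefault(period, []).append(post)

    tables: list[TopicTable] = []
    period = min(by_quarter)
    last = max(by_quarter)
    while period <= last:
        label = str(period)
        quarter_posts = by_quarter.get(period, [])
        if quarter_posts:
            for table in tfidf_topics(group_posts(quarter_posts, by=by), n_top=n_top):
                tables.append(
                    TopicTable(
                        group=table.group,
                        terms=table.terms,
                        n_top=n_top,
                        quarter=label,
                    )
                )
        else:
            tables.append(TopicTable(group="", terms=(), n_top=n_top, quarter=label))
        period += 1
    return tables


def topics_to_frame(tables: Sequence[TopicTable]) -> pd.DataFrame:
    """Flatten topic tables to (group, quarter, rank, ngram, score) rows."""
    rows = [
        {
            "group": t.group,
            "quarter": t.quarter,
            "rank": rank,
            "ngram": ng,
            "score": score,
        }
        for t in tables
        for rank, (ng, score) in enumerate(t.terms, start=1)
    ]
    return pd.DataFrame(rows, columns=["group", "quarter", "rank", "ngram", "score"])
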