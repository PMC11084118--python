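"""Timestamped social-media post containers and JSONL input/output.

Posts are newline-delimited JSON records with at least ``id``, ``author``,
``timestamp`` (ISO-8601), ``text`` and optionally ``source``, ``drug_category``,
and ground-truth labels (``sud_label``, ``sentiment``, ``emotion``) when the
corpus is synthetic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Iterator

__all__ = ["Post", "PostHistory", "read_posts_jsonl", "write_posts_jsonl"]


def _parse_timestamp(value) -> datetime:
    if isinstance(value, datetime):
        ts = value
    else:
        ts = datetime.fromisoformat(str(value))
    if ts.tzinfo is None:
        ts = ts.replace(tzinfo=timezone.utc)
    return ts.astimezone(timezone.utc)


@dataclass(frozen=True)
class Post:
    """One social-media document with author, UTC timestamp and optional labels."""

    post_id: str
    author_id: str
    timestamp: datetime
    text: str
    source: str = "unknown"
    drug_category: str | None = None
    sud_label: str | None = None
    sentiment: str | None = None
    emotion: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "timestamp", _parse_timestamp(self.timestamp))
        if not self.text:
            raise ValueError(f"post {self.post_id!r} has empty text")

    def to_record(self) -> dict:
        rec = {
            "id": self.post_id,
            "author": self.author_id,
            "timestamp": self.timestamp.isoformat(),
            "text": self.text,
            "source": self.source,
        }
        for key in ("drug_category", "sud_label", "sentiment", "emotion"):
            value = getattr(self, key)
            if value is not None:
                rec[key] = value
        return rec

    @classmethod
    def from_record(cls, rec: dict) -> "Post":
        return cls(
            post_id=str(rec["id"]),
            author_id=str(rec["author"]),
            timestamp=rec["timestamp"],
            text=rec["text"],
            source=rec.get("source", "unknown"),
            drug_category=rec.get("drug_category"),
            sud_label=rec.get("sud_label"),
            sentiment=rec.get("sentiment"),
            emotion=rec.get("emotion"),
        )


@dataclass(frozen=True)
class PostHistory:
    """An author's prior posts ordered oldest to newest, all preceding a target time.

    ``max_len`` is the history window K; longer histories are truncated to the
    K most recent posts at feature-building time, not here.
    """

    posts: tuple[Post, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        posts = tuple(self.posts)
        object.__setattr__(self, "posts", posts)
        for earlier, later in zip(posts, posts[1:]):
            if later.timestamp < earlier.timestamp:
                raise ValueError(
                    "history timestamps must be non-decreasing "
                    f"({earlier.post_id!r} at {earlier.timestamp} precedes "
                    f"{later.post_id!r} at {later.timestamp})"
                )

    def __len__(self) -> int:
        return len(self.posts)

    def __iter__(self) -> Iterator[Post]:
        return iter(self.posts)

    def validate_before(self, target: Post) -> None:
        """Check that every history post strictly precedes the target in time."""
        for p in self.posts:
            if p.timestamp >= target.timestamp:
                raise ValueError(
                    f"history post {p.post_id!r} does not precede target "
                    f"{target.post_id!r} in time"
                )

    def most_recent(self, k: int) -> "PostHistory":
        return replace(self, posts=self.posts[-k:]) if k < len(self.posts) else self


def read_posts_jsonl(path) -> list[Post]:
    """Read posts from a JSONL file, one object per line."""
    posts = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                posts.append(Post.from_record(json.loads(line)))
            except (json.JSONDecodeError, KeyError) as exc:
                raise ValueError(f"bad JSONL record at line {lineno}: {exc}") from exc
    return posts


def write_posts_jsonl(posts: Iterable[Post], path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        for post in posts:
            fh.write(json.dumps(post.to_record(), sort_keys=True) + "\n")
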