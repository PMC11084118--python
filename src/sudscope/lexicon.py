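"""Miniature drug-abuse-ontology layer.

A :class:`Lexicon` maps drug surface forms (generic names, brand names, slang,
street and marketing names, abbreviations) to a normalized drug name and one of
eight opioid-focused super-categories. On top of it sit gazetteer-style mention
finding, category mapping, entity masking (the "knowledge" component of the
downstream classifier) and PII scrubbing of URLs and usernames.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Iterator

__all__ = [
    "CATEGORIES",
    "TERM_TYPES",
    "LexiconEntry",
    "Lexicon",
    "DrugMention",
    "load_lexicon",
    "default_lexicon",
    "find_mentions",
    "map_to_category",
    "mask_mentions",
    "mask_text",
    "scrub_pii",
]

#: The eight drug super-categories distinguished by the ontology layer.
CATEGORIES: tuple[str, ...] = (
    "heroin",
    "synthetic_heroin",
    "pharmaceutical_fentanyl",
    "nonpharmaceutical_fentanyl",
    "fentanyl",
    "oxycodone",
    "kratom",
    "opium",
)

#: Admissible term types for a lexicon row.
TERM_TYPES: tuple[str, ...] = (
    "generic",
    "brand",
    "slang",
    "street",
    "marketing",
    "common",
    "abbreviation",
)

_LEXICON_COLUMNS = ("surface_form", "normalized_name", "category", "term_type")


@dataclass(frozen=True)
class LexiconEntry:
    """One drug vocabulary row: a surface form with its normalization and category."""

    surface_form: str
    normalized_name: str
    category: str
    term_type: str

    def __post_init__(self) -> None:
        if not self.surface_form:
            raise ValueError("surface_form must be non-empty")
        if self.category not in CATEGORIES:
            raise ValueError(
                f"unknown category {self.category!r}; expected one of {CATEGORIES}"
            )
        if self.term_type not in TERM_TYPES:
            raise ValueError(
                f"unknown term_type {self.term_type!r}; expected one of {TERM_TYPES}"
            )


@dataclass(frozen=True)
class DrugMention:
    """A matched drug term: half-open character span plus its lexicon entry."""

    start: int
    end: int
    matched_text: str
    entry: LexiconEntry

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid span [{self.start}, {self.end})")


class Lexicon:
    """Immutable, case-insensitively indexed drug vocabulary.

    Matching is token-boundary-delimited and resolves overlapping candidates
    longest-match-first, then leftmost, so multi-word terms ("china white",
    "fentanyl transdermal system") win over their unigram substrings.
    """

    def __init__(self, entries: Iterable[LexiconEntry]):
        entries = tuple(entries)
        seen: set[tuple[str, str]] = set()
        for e in entries:
            key = (e.surface_form.lower(), e.category)
            if key in seen:
                raise ValueError(
                    f"duplicate lexicon row: surface form {e.surface_form!r} "
                    f"appears twice under category {e.category!r}"
                )
            seen.add(key)
        self._entries = entries
        # first row wins if one surface form is listed under two categories
        self._by_surface: dict[str, LexiconEntry] = {}
        for e in entries:
            self._by_surface.setdefault(e.surface_form.lower(), e)
        if entries:
            alternation = "|".join(
                re.escape(e.surface_form)
                for e in sorted(entries, key=lambda e: -len(e.surface_form))
            )
            self._pattern: re.Pattern[str] | None = re.compile(
                rf"(?<!\w)(?:{alternation})(?!\w)", re.IGNORECASE
            )
        else:
            self._pattern = None

    @property
    def entries(self) -> tuple[LexiconEntry, ...]:
        return self._entries

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self) -> Iterator[LexiconEntry]:
        return iter(self._entries)

    def lookup(self, surface_form: str) -> LexiconEntry | None:
        """Case-insensitive exact lookup of a surface form."""
        return self._by_surface.get(surface_form.lower())

    def candidate_matches(self, text: str) -> list[tuple[int, int, LexiconEntry]]:
        """All boundary-delimited matches of any term, including overlapping ones."""
        if self._pattern is None or not text:
            return []
        out: list[tuple[int, int, LexiconEntry]] = []
        # scan every start position so overlapping candidates are all seen
        pos = 0
        while pos <= len(text):
            m = self._pattern.search(text, pos)
            if m is None:
                break
            entry = self._by_surface[m.group(0).lower()]
            out.append((m.start(), m.end(), entry))
            pos = m.start() + 1
        return out


def load_lexicon(path) -> Lexicon:
    """Load a TSV lexicon with columns surface_form, normalized_name, category, term_type.

    Raises ``ValueError`` naming the offending line for malformed rows, unknown
    categories/term types, or duplicate (surface_form, category) pairs.
    """
    entries: list[LexiconEntry] = []
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            return Lexicon(())
        missing = set(_LEXICON_COLUMNS) - set(reader.fieldnames)
        if missing:
            raise ValueError(f"lexicon file missing columns: {sorted(missing)}")
        for row in reader:
            lineno = reader.line_num
            values = [row.get(col) for col in _LEXICON_COLUMNS]
            if any(v is None or v == "" for v in values):
                raise ValueError(f"malformed lexicon row at line {lineno}: {row!r}")
            try:
                entries.append(LexiconEntry(*[v.strip() for v in values]))
            except ValueError as exc:
                raise ValueError(f"invalid lexicon row at line {lineno}: {exc}") from exc
    return Lexicon(entries)


def default_lexicon() -> Lexicon:
    """The packaged ~120-term opioid lexicon spanning all eight categories."""
    ref = resources.files("sudscope").joinpath("data/default_lexicon.tsv")
    with resources.as_file(ref) as path:
        return load_lexicon(path)


def find_mentions(text: str, lexicon: Lexicon) -> list[DrugMention]:
    """Find non-overlapping drug mentions in ``text``.

    Case-insensitive and token-boundary-delimited; overlapping candidates are
    resolved longest-match-first, then leftmost. The returned mentions are
    sorted by start offset and index the original (unmodified) text.
    """
    candidates = lexicon.candidate_matches(text)
    candidates.sort(key=lambda c: (-(c[1] - c[0]), c[0]))
    accepted: list[tuple[int, int, LexiconEntry]] = []
    for start, end, entry in candidates:
        if all(end <= s or start >= e for s, e, _ in accepted):
            accepted.append((start, end, entry))
    accepted.sort(key=lambda c: c[0])
    return [
        DrugMention(start=s, end=e, matched_text=text[s:e], entry=entry)
        for s, e, entry in accepted
    ]


def map_to_category(entry: LexiconEntry) -> str:
    """Map a lexicon entry to its super drug category (total over lexicon entries)."""
    return entry.category


def mask_mentions(text: str, mentions: list[DrugMention]) -> str:
    """Replace each mention span with ``[DRUG_<CATEGORY>]``.

    Idempotent when composed with :func:`find_mentions`: mask tokens match no
    lexicon entry, so re-masking a masked text is a no-op.
    """
    for m in mentions:
        if not (0 <= m.start < m.end <= len(text)):
            raise ValueError(
                f"mention span [{m.start}, {m.end}) out of range for text of "
                f"length {len(text)}"
            )
    out = text
    for m in sorted(mentions, key=lambda m: -m.start):
        token = f"[DRUG_{m.entry.category.upper()}]"
        out = out[: m.start] + token + out[m.end :]
    return out


def mask_text(text: str, lexicon: Lexicon) -> str:
    """Convenience composition: find mentions and mask them in one call."""
    return mask_mentions(text, find_mentions(text, lexicon))


_URL_RE = re.compile(r"(?:https?://|www\.)\S+", re.IGNORECASE)
_USER_RE = re.compile(r"@\w+")


def scrub_pii(text: str) -> str:
    """Replace URL spans with ``[URL]`` and @-handles with ``[USER]``; idempotent."""
    text = _URL_RE.sub("[URL]", text)
    return _USER_RE.sub("[USER]", text)
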