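"""Cryptomarket listing parsing and market summary statistics.

A raw listing (title, description, vendor, price string, shipping fields) is
parsed into a property schema: the drug it offers (via lexicon matching on the
title), its super-category, quantity and dosage in grams, and a normalized
price. Summaries report vendor/substance counts, per-category listing shares
and mean offered quantities.
"""

from __future__ import annotations

import csv
import json
import logging
import re
from dataclasses import dataclass, asdict
from datetime import date, datetime
from typing import Iterable, Sequence

import pandas as pd

from sudscope.lexicon import Lexicon, find_mentions, map_to_category

__all__ = [
    "RawListing",
    "ParsedListing",
    "MarketSummary",
    "PriceParseError",
    "parse_price",
    "format_price",
    "normalize_quantity",
    "parse_listing",
    "summarize_market",
    "read_listings",
    "write_parsed_listings",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RawListing:
    """One crawled listing record as it comes off a marketplace page."""

    title: str
    description: str = ""
    vendor: str = ""
    price_text: str = ""
    ship_from: str = ""
    ship_to: str = ""
    timestamp: date | None = None

    def __post_init__(self) -> None:
        if not self.title:
            raise ValueError("listing title must be non-empty")


@dataclass(frozen=True)
class ParsedListing:
    """A listing mapped onto the property schema (nullable where extraction failed)."""

    product_name: str
    substance: str | None
    drug_class: str | None
    quantity_g: float | None
    dosage_g: float | None
    vendor: str
    price_currency: str | None
    price_amount: float | None
    ship_from: str
    ship_to: str
    timestamp: date | None = None

    def __post_init__(self) -> None:
        if self.quantity_g is not None and not self.quantity_g > 0:
            raise ValueError("quantity_g must be positive when present")
        if self.price_amount is not None and self.price_amount < 0:
            raise ValueError("price_amount must be non-negative")


class PriceParseError(ValueError):
    """Raised when a price string matches no supported dialect."""


_NUM = r"(\d+(?:[.,]\d+)?)"
_PRICE_PATTERNS = (
    (re.compile(rf"^\s*BTC\s*{_NUM}\s*$", re.IGNORECASE), "BTC"),
    (re.compile(rf"^\s*{_NUM}\s*BTC\s*$", re.IGNORECASE), "BTC"),
    (re.compile(rf"^\s*\$\s*{_NUM}\s*$"), "USD"),
    (re.compile(rf"^\s*USD\s*{_NUM}\s*$", re.IGNORECASE), "USD"),
    (re.compile(rf"^\s*{_NUM}\s*USD\s*$", re.IGNORECASE), "USD"),
)


def parse_price(price_text: str) -> tuple[str, float]:
    """Parse a marketplace price string into ``(currency, amount)``.

    Supported dialects: ``"BTC 0.0444"``, ``"0.0444 BTC"``, ``"$120"``,
    ``"USD 120"``, ``"120 USD"``.
    """
    for pattern, currency in _PRICE_PATTERNS:
        m = pattern.match(price_text or "")
        if m:
            return currency, float(m.group(1).replace(",", "."))
    raise PriceParseError(f"unrecognized price string: {price_text!r}")


def format_price(currency: str, amount: float) -> str:
    """Canonical price rendering; right inverse of :func:`parse_price`."""
    if currency == "BTC":
        return f"BTC {amount:g}"
    if currency == "USD":
        return f"USD {amount:g}"
    raise ValueError(f"unknown currency {currency!r}")


#: Mass units convertible to grams; non-mass dose units are recognized but unconvertible.
_MASS_UNITS = {
    "g": 1.0,
    "gr": 1.0,
    "gram": 1.0,
    "grams": 1.0,
    "kg": 1000.0,
    "mg": 0.001,
}
_NON_MASS_UNITS = ("pint", "pints", "tablet", "tablets", "pill", "pills", "ml", "oz")

_QTY_RE = re.compile(
    rf"{_NUM}\s*({'|'.join(list(_MASS_UNITS) + list(_NON_MASS_UNITS))})\b",
    re.IGNORECASE,
)


def normalize_quantity(quantity_text: str) -> float | None:
    """Convert a ``"<number> <unit>"`` string to grams.

    Non-mass units (pint, tablets, ...) are accepted but yield ``None`` since
    no mass conversion is defined for them; unknown units raise ``ValueError``.
    """
    m = _QTY_RE.match((quantity_text or "").strip())
    if not m:
        raise ValueError(
            f"unrecognized quantity {quantity_text!r}; supported units: "
            f"{sorted(_MASS_UNITS)} (mass) and {sorted(_NON_MASS_UNITS)} (counted, "
            "returned as null grams)"
        )
    value = float(m.group(1).replace(",", "."))
    unit = m.group(2).lower()
    if unit in _MASS_UNITS:
        return value * _MASS_UNITS[unit]
    logger.warning("non-mass unit %r in %r; grams set to null", unit, quantity_text)
    return None


def _first_quantity(text: str) -> float | None:
    """First number + mass-unit pattern in free text, in grams (None if absent)."""
    for m in _QTY_RE.finditer(text or ""):
        unit = m.group(2).lower()
        if unit in _MASS_UNITS:
            value = float(m.group(1).replace(",", ".")) * _MASS_UNITS[unit]
            if value > 0:
                return value
        else:
            logger.warning("non-mass unit %r in %r ignored", unit, text)
    return None


def parse_listing(raw: RawListing, lexicon: Lexicon) -> ParsedListing:
    """Map a raw listing onto the property schema.

    The substance is the first drug mention in the title (longest-match wins);
    quantity is the first number+mass-unit pattern in the title; dosage is read
    from the description. Per-field parse failures become nulls with a warning,
    never exceptions, so a crawl batch parses end to end.
    """
    mentions = find_mentions(raw.title, lexicon)
    substance = None
    drug_class = None
    if mentions:
        entry = mentions[0].entry
        substance = entry.normalized_name
        drug_class = map_to_category(entry)
    else:
        logger.warning("no lexicon match in title %r; substance left null", raw.title)

    currency = amount = None
    if raw.price_text:
        try:
            currency, amount = parse_price(raw.price_text)
        except PriceParseError as exc:
            logger.warning("%s; price left null", exc)

    return ParsedListing(
        product_name=raw.title,
        substance=substance,
        drug_class=drug_class,
        quantity_g=_first_quantity(raw.title),
        dosage_g=_first_quantity(raw.description),
        vendor=raw.vendor,
        price_currency=currency,
        price_amount=amount,
        ship_from=raw.ship_from,
        ship_to=raw.ship_to,
        timestamp=raw.timestamp,
    )


@dataclass(frozen=True)
class MarketSummary:
    """Distinct-vendor/substance counts, category listing shares, mean quantities."""

    n_listings: int
    n_matched: int
    vendor_count: int
    substance_count: int
    category_share_pct: dict[str, float]
    mean_quantity_g: dict[str, float]
    mean_quantity_g_by_time: pd.DataFrame | None = None


def summarize_market(listings: Sequence[ParsedListing]) -> MarketSummary:
    """Summarize parsed listings; shares are over lexicon-matched listings and sum to 100."""
    listings = list(listings)
    if not listings:
        return MarketSummary(0, 0, 0, 0, {}, {}, None)

    matched = [l for l in listings if l.drug_class is not None]
    vendors = {l.vendor for l in listings if l.vendor}
    substances = {l.substance for l in matched}

    share: dict[str, float] = {}
    mean_q: dict[str, float] = {}
    if matched:
        counts: dict[str, int] = {}
        for l in matched:
            counts[l.drug_class] = counts.get(l.drug_class, 0) + 1
        share = {c: 100.0 * n / len(matched) for c, n in sorted(counts.items())}
        for c in counts:
            qs = [l.quantity_g for l in matched if l.drug_class == c and l.quantity_g]
            if qs:
                mean_q[c] = float(sum(qs) / len(qs))

    by_time = None
    timed = [l for l in matched if l.timestamp is not None and l.quantity_g]
    if timed:
        df = pd.DataFrame(
            {
                "category": [l.drug_class for l in timed],
                "timestamp": [pd.Timestamp(l.timestamp) for l in timed],
                "quantity_g": [l.quantity_g for l in timed],
            }
        )
        by_time = (
            df.groupby(["category", df["timestamp"].dt.to_period("M")])["quantity_g"]
            .mean()
            .unstack(fill_value=float("nan"))
        )

    return MarketSummary(
        n_listings=len(listings),
        n_matched=len(matched),
        vendor_count=len(vendors),
        substance_count=len(substances),
        category_share_pct=share,
        mean_quantity_g=mean_q,
        mean_quantity_g_by_time=by_time,
    )


_RAW_FIELDS = ("title", "description", "vendor", "price_text", "ship_from", "ship_to")


def read_listings(path) -> list[RawListing]:
    """Read raw listings from CSV or JSONL (decided by file extension)."""
    path = str(path)
    rows: Iterable[dict]
    if path.endswith((".jsonl", ".json")):
        with open(path, encoding="utf-8") as fh:
            rows = [json.loads(line) for line in fh if line.strip()]
    else:
        with open(path, encoding="utf-8", newline="") as fh:
            rows = list(csv.DictReader(fh))
    out = []
    for row in rows:
        ts = row.get("timestamp") or None
        if isinstance(ts, str):
            ts = datetime.fromisoformat(ts).date()
        out.append(
            RawListing(
                **{f: row.get(f, "") or "" for f in _RAW_FIELDS}, timestamp=ts
            )
        )
    return out


def write_parsed_listings(listings: Iterable[ParsedListing], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for l in listings:
            rec = asdict(l)
            if rec["timestamp"] is not None:
                rec["timestamp"] = rec["timestamp"].isoformat()
            fh.write(json.dumps(rec, sort_keys=True) + "\n")
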