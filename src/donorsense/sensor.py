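"""Keyword sensor for organ-donation awareness in short social-media posts.

A post counts as a *digital marker* of awareness when it contains at least
one context word (transplant, transplantation, donor, donation, donate) and
at least one subject word naming a major solid organ (heart, kidney, liver,
lung, pancreas, intestine).  Requiring the conjunction keeps "heart of
gold" and "blood donor drive" out while keeping "I want to donate my
kidney" in.

Location handling is a pure offline lookup against a gazetteer table
(normalized alias -> structured address); no network geocoding is ever
performed.  Retained posts are those that pass the marker filter and
resolve to a US address.
"""
from __future__ import annotations

import datetime as _dt
import re
from dataclasses import dataclass, field
from decimal import ROUND_HALF_EVEN, Decimal
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ValidationError
from .records import StructuredAddress, Tweet

DEFAULT_CONTEXT_WORDS = frozenset(
    {"transplant", "transplantation", "donor", "donation", "donate"}
)
DEFAULT_SUBJECT_WORDS = frozenset(
    {"heart", "kidney", "liver", "lung", "pancreas", "intestine"}
)

_TOKEN_SPLIT = re.compile(r"[^0-9a-z]+")
_NORM_COLLAPSE = re.compile(r"[^0-9a-z]+")


@dataclass(frozen=True)
class MarkerLexicon:
    """The context/subject word sets defining the sensor."""

    context_words: frozenset[str] = DEFAULT_CONTEXT_WORDS
    subject_words: frozenset[str] = DEFAULT_SUBJECT_WORDS

    def __post_init__(self):
        for name, words in (("context", self.context_words), ("subject", self.subject_words)):
            if not words:
                raise ValidationError(f"{name} word set must be non-empty")
            if any(w != w.lower() for w in words):
                raise ValidationError(f"{name} words must be lowercase")


@dataclass(frozen=True)
class SensorSummary:
    """Descriptive statistics of a retained-tweet stream."""

    start_date: _dt.date
    end_date: _dt.date
    n_days: int
    n_tweets: int
    n_users: int
    tweets_per_day: int
    tweets_per_user: float
    organs_per_tweet: float
    organs_per_user: float


def _round2(x: float) -> float:
    """2-decimal round-half-even, stable across platforms."""
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_EVEN))


def tokenize(text: str) -> list[str]:
    """Lowercase and split on runs of non-alphanumeric characters."""
    return [t for t in _TOKEN_SPLIT.split(text.lower()) if t]


def match_markers(
    text: str, lexicon: MarkerLexicon | None = None, substring: bool = False
) -> tuple[set[str], set[str]]:
    """Return the distinct (context_hits, subject_hits) present in ``text``.

    Default matching is case-insensitive whole-word: "donated" does not hit
    "donate".  With ``substring=True`` a lexicon word hits whenever it
    occurs anywhere in the lowercased text.
    """
    lexicon = lexicon or MarkerLexicon()
    if substring:
        low = text.lower()
        ctx = {w for w in lexicon.context_words if w in low}
        subj = {w for w in lexicon.subject_words if w in low}
    else:
        tokens = set(tokenize(text))
        ctx = tokens & lexicon.context_words
        subj = tokens & lexicon.subject_words
    return ctx, subj


def is_organ_tweet(
    text: str, lexicon: MarkerLexicon | None = None, substring: bool = False
) -> bool:
    """True iff the text hits >= 1 context word AND >= 1 subject word."""
    ctx, subj = match_markers(text, lexicon, substring=substring)
    return bool(ctx) and bool(subj)


def normalize_alias(raw: str) -> str:
    """Canonical form used for gazetteer lookup: lowercase, punctuation
    collapsed to single spaces, trimmed."""
    return _NORM_COLLAPSE.sub(" ", raw.lower()).strip()


class Gazetteer:
    """Offline alias -> structured-address lookup table.

    Built from a table with columns alias, country, state, county, city,
    zip.  Aliases are normalized once at load time; lookups are exact
    matches on the normalized form.
    """

    COLUMNS = ["alias", "country", "state", "county", "city", "zip"]

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in table.columns]
        if missing:
            raise ValidationError(f"gazetteer missing columns {missing}")
        if len(table) == 0:
            raise ValidationError("gazetteer must be non-empty")
        self._index: dict[str, StructuredAddress] = {}
        self.table = table.reset_index(drop=True)
        for row in self.table.itertuples(index=False):
            key = normalize_alias(str(row.alias))
            addr = StructuredAddress(
                country=str(row.country),
                state="" if pd.isna(row.state) else str(row.state),
                county="" if pd.isna(row.county) else str(row.county),
                city="" if pd.isna(row.city) else str(row.city),
                zip="" if pd.isna(row.zip) else str(row.zip),
            )
            # first definition of an alias wins; later duplicates ignored
            self._index.setdefault(key, addr)

    def __len__(self) -> int:
        return len(self._index)

    def lookup(self, raw: str) -> StructuredAddress | None:
        key = normalize_alias(raw)
        if not key:
            return None
        return self._index.get(key)

    @property
    def aliases(self) -> list[str]:
        return list(self.table["alias"])


def resolve_location(raw: str, gazetteer: Gazetteer) -> StructuredAddress | None:
    """Resolve a free-text profile location, or None when not in the table."""
    return gazetteer.lookup(raw)


def filter_and_aggregate(
    tweets: Iterable[Tweet],
    lexicon: MarkerLexicon | None = None,
    gazetteer: Gazetteer | None = None,
    level: str = "city",
    substring: bool = False,
) -> pd.DataFrame:
    """Count marker tweets from US users per city or state.

    A tweet is retained when it passes :func:`is_organ_tweet`, its location
    resolves against the gazetteer to a US address, and the requested unit
    (city or state) is non-empty.  Returns a DataFrame with columns
    ``level``, ``unit``, ``tweets`` sorted by unit.
    """
    if level not in ("city", "state"):
        raise ValidationError(f"level must be 'city' or 'state', got {level!r}")
    if gazetteer is None:
        raise ValidationError("a gazetteer is required")
    lexicon = lexicon or MarkerLexicon()
    counts: dict[str, int] = {}
    for tw in tweets:
        if not is_organ_tweet(tw.text, lexicon, substring=substring):
            continue
        addr = tw.resolved or resolve_location(tw.raw_location, gazetteer)
        if addr is None or addr.country != "US":
            continue
        unit = getattr(addr, level)
        if not unit:
            continue
        counts[unit] = counts.get(unit, 0) + 1
    return pd.DataFrame(
        {"level": level, "unit": sorted(counts), "tweets": [counts[u] for u in sorted(counts)]}
    )


def retained_tweets(
    tweets: Iterable[Tweet],
    lexicon: MarkerLexicon | None = None,
    gazetteer: Gazetteer | None = None,
    substring: bool = False,
) -> list[Tweet]:
    """The tweets the sensor keeps: marker-positive and resolving to a US
    address.  Resolved addresses are attached to the returned records."""
    if gazetteer is None:
        raise ValidationError("a gazetteer is required")
    lexicon = lexicon or MarkerLexicon()
    kept: list[Tweet] = []
    for tw in tweets:
        if not is_organ_tweet(tw.text, lexicon, substring=substring):
            continue
        addr = tw.resolved or resolve_location(tw.raw_location, gazetteer)
        if addr is None or addr.country != "US":
            continue
        kept.append(Tweet(tw.text, tw.user_id, tw.timestamp, tw.raw_location, addr))
    return kept


def sensor_rates(n_tweets: int, n_users: int, n_days: int) -> tuple[int, float]:
    """(tweets per day, tweets per user) under the pinned conventions.

    Tweets per day uses integer floor division; tweets per user is rounded
    half-even to 2 decimals.
    """
    if n_days < 1:
        raise ValidationError("n_days must be >= 1")
    if n_tweets > 0 and n_users < 1:
        raise ValidationError("nonzero tweets require at least one user")
    per_day = n_tweets // n_days
    per_user = _round2(n_tweets / n_users) if n_users else 0.0
    return per_day, per_user


def descriptive_stats(
    tweets: Sequence[Tweet],
    start_date: _dt.date,
    end_date: _dt.date,
    lexicon: MarkerLexicon | None = None,
    inclusive: bool = False,
) -> SensorSummary:
    """Table-style descriptive statistics of a retained tweet stream.

    ``n_days`` defaults to the exclusive span ``end_date - start_date``;
    ``inclusive=True`` adds one.  Organ mentions count distinct subject
    words per tweet (and the union per user), rounded half-even to 2
    decimals.
    """
    if end_date < start_date:
        raise ValidationError("end_date must be >= start_date")
    lexicon = lexicon or MarkerLexicon()
    n_days = (end_date - start_date).days + (1 if inclusive else 0)
    n_days = max(n_days, 1)
    n_tweets = len(tweets)
    users: dict[str, set[str]] = {}
    organ_counts: list[int] = []
    for tw in tweets:
        _, subj = match_markers(tw.text, lexicon)
        organ_counts.append(len(subj))
        users.setdefault(tw.user_id, set()).update(subj)
    n_users = len(users)
    per_day, per_user = sensor_rates(n_tweets, n_users, n_days)
    organs_per_tweet = _round2(sum(organ_counts) / n_tweets) if n_tweets else 0.0
    organs_per_user = (
        _round2(sum(len(s) for s in users.values()) / n_users) if n_users else 0.0
    )
    return SensorSummary(
        start_date=start_date,
        end_date=end_date,
        n_days=n_days,
        n_tweets=n_tweets,
        n_users=n_users,
        tweets_per_day=per_day,
        tweets_per_user=per_user,
        organs_per_tweet=organs_per_tweet,
        organs_per_user=organs_per_user,
    )
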