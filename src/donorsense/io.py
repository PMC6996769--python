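"""CSV readers/writers for every record schema, plus packaged fixtures.

Schemas (exact header match required, UTF-8, RFC-4180 quoting):

* transplants: donor_zip,recipient_zip,donor_group,recipient_group,
  donor_lat,donor_lon,recipient_lat,recipient_lon
* tweets: text,user_id,timestamp,raw_location (ISO-8601 timestamps)
* panel: city,tweets,registrations,population
* campaign: date,phase,impressions,clicks,views (ISO dates; phase 0/1)
* gazetteer: alias,country,state,county,city,zip

Two fixtures ship with the package: the daily delivery table of the 2016
Los Angeles awareness campaign (`table4_daily.csv`) and a small *synthetic*
demo gazetteer (`demo_gazetteer.csv`) for examples and tests.
"""
from __future__ import annotations

import datetime as _dt
from importlib import resources
from pathlib import Path
from typing import Sequence

import pandas as pd

from .errors import SchemaError
from .records import CampaignDayRecord, CityPanelRow, TransplantRecord, Tweet
from .sensor import Gazetteer

TRANSPLANT_COLUMNS = [
    "donor_zip", "recipient_zip", "donor_group", "recipient_group",
    "donor_lat", "donor_lon", "recipient_lat", "recipient_lon",
]
TWEET_COLUMNS = ["text", "user_id", "timestamp", "raw_location"]
PANEL_COLUMNS = ["city", "tweets", "registrations", "population"]
CAMPAIGN_COLUMNS = ["date", "phase", "impressions", "clicks", "views"]


def _read_checked(path: str | Path, columns: list[str], **kwargs) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False, **kwargs)
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise SchemaError(f"cannot parse {path}: {exc}") from exc
    if list(df.columns) != columns:
        raise SchemaError(
            f"{path}: header {list(df.columns)} does not match schema {columns}"
        )
    return df


def _to_int(value: str, row: int, column: str) -> int:
    try:
        out = int(value)
    except ValueError:
        raise SchemaError(f"expected an integer, got {value!r}", row=row, column=column)
    if out < 0:
        raise SchemaError(f"negative count {out}", row=row, column=column)
    return out


def _to_float(value: str, row: int, column: str) -> float:
    try:
        return float(value)
    except ValueError:
        raise SchemaError(f"expected a number, got {value!r}", row=row, column=column)


def read_transplants(path: str | Path) -> list[TransplantRecord]:
    df = _read_checked(path, TRANSPLANT_COLUMNS)
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            records.append(
                TransplantRecord(
                    donor_zip=row.donor_zip,
                    recipient_zip=row.recipient_zip,
                    donor_group=row.donor_group,
                    recipient_group=row.recipient_group,
                    donor_lat=_to_float(row.donor_lat, i, "donor_lat"),
                    donor_lon=_to_float(row.donor_lon, i, "donor_lon"),
                    recipient_lat=_to_float(row.recipient_lat, i, "recipient_lat"),
                    recipient_lon=_to_float(row.recipient_lon, i, "recipient_lon"),
                )
            )
        except ValueError as exc:
            raise SchemaError(str(exc), row=i) from exc
    return records


def write_transplants(records: Sequence[TransplantRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "donor_zip": r.donor_zip, "recipient_zip": r.recipient_zip,
                "donor_group": r.donor_group, "recipient_group": r.recipient_group,
                "donor_lat": repr(r.donor_lat), "donor_lon": repr(r.donor_lon),
                "recipient_lat": repr(r.recipient_lat),
                "recipient_lon": repr(r.recipient_lon),
            }
            for r in records
        ],
        columns=TRANSPLANT_COLUMNS,
    ).to_csv(path, index=False, encoding="utf-8")


def read_tweets(path: str | Path) -> list[Tweet]:
    df = _read_checked(path, TWEET_COLUMNS)
    tweets = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            ts = _dt.datetime.fromisoformat(row.timestamp)
        except ValueError:
            raise SchemaError(
                f"bad ISO timestamp {row.timestamp!r}", row=i, column="timestamp"
            )
        tweets.append(
            Tweet(text=row.text, user_id=row.user_id, timestamp=ts,
                  raw_location=row.raw_location)
        )
    return tweets


def write_tweets(tweets: Sequence[Tweet], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "text": t.text, "user_id": t.user_id,
                "timestamp": t.timestamp.isoformat(),
                "raw_location": t.raw_location,
            }
            for t in tweets
        ],
        columns=TWEET_COLUMNS,
    ).to_csv(path, index=False, encoding="utf-8")


def read_panel(path: str | Path) -> list[CityPanelRow]:
    df = _read_checked(path, PANEL_COLUMNS)
    rows = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            rows.append(
                CityPanelRow(
                    city=row.city,
                    tweets=_to_int(row.tweets, i, "tweets"),
                    registrations=_to_int(row.registrations, i, "registrations"),
                    population=_to_int(row.population, i, "population"),
                )
            )
        except ValueError as exc:
            raise SchemaError(str(exc), row=i) from exc
    return rows


def write_panel(rows: Sequence[CityPanelRow], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"city": r.city, "tweets": r.tweets,
             "registrations": r.registrations, "population": r.population}
            for r in rows
        ],
        columns=PANEL_COLUMNS,
    ).to_csv(path, index=False, encoding="utf-8")


def read_campaign(path: str | Path) -> list[CampaignDayRecord]:
    df = _read_checked(path, CAMPAIGN_COLUMNS)
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            date = _dt.date.fromisoformat(row.date)
        except ValueError:
            raise SchemaError(f"bad ISO date {row.date!r}", row=i, column="date")
        phase = _to_int(row.phase, i, "phase")
        impressions = _to_int(row.impressions, i, "impressions")
        clicks = _to_int(row.clicks, i, "clicks")
        views = _to_int(row.views, i, "views")
        if phase not in (0, 1):
            raise SchemaError(f"phase must be 0 or 1, got {phase}", row=i, column="phase")
        if clicks > impressions:
            raise SchemaError(
                f"clicks {clicks} exceed impressions {impressions}", row=i, column="clicks"
            )
        records.append(CampaignDayRecord(date, phase, impressions, clicks, views))
    return records


def write_campaign(records: Sequence[CampaignDayRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"date": r.date.isoformat(), "phase": r.phase,
             "impressions": r.impressions, "clicks": r.clicks, "views": r.views}
            for r in records
        ],
        columns=CAMPAIGN_COLUMNS,
    ).to_csv(path, index=False, encoding="utf-8")


def read_gazetteer(path: str | Path) -> Gazetteer:
    df = _read_checked(path, Gazetteer.COLUMNS)
    return Gazetteer(df)


def _fixture_path(name: str) -> Path:
    return Path(resources.files("donorsense").joinpath("data", name))


def load_table4() -> list[CampaignDayRecord]:
    """The packaged daily delivery table of the 2016 Los Angeles
    organ-donation awareness campaign (31 days; 20 pre-optimization,
    11 post-optimization)."""
    return read_campaign(_fixture_path("table4_daily.csv"))


def load_demo_gazetteer() -> Gazetteer:
    """A small synthetic demo gazetteer (hand-written alias table, not an
    extract of any real geocoding service)."""
    return read_gazetteer(_fixture_path("demo_gazetteer.csv"))
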