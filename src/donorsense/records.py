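"""Core record types shared by the generators, the analysis modules and I/O.

Each record is a plain frozen dataclass mirroring one row of the
corresponding CSV schema (see :mod:`donorsense.io`).
"""
from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

ETHNORACIAL_GROUPS = ("hispanic", "black", "white")


@dataclass(frozen=True)
class TransplantRecord:
    """One organ transplant: donor home zip -> recipient home zip.

    Coordinates are decimal degrees for the centroid of each zip code.
    """

    donor_zip: str
    recipient_zip: str
    donor_group: str
    recipient_group: str
    donor_lat: float
    donor_lon: float
    recipient_lat: float
    recipient_lon: float

    def __post_init__(self):
        if not self.donor_zip or not self.recipient_zip:
            raise ValueError("zip codes must be non-empty")
        for lat in (self.donor_lat, self.recipient_lat):
            if not -90.0 <= lat <= 90.0:
                raise ValueError(f"latitude {lat} outside [-90, 90]")
        for lon in (self.donor_lon, self.recipient_lon):
            if not -180.0 <= lon <= 180.0:
                raise ValueError(f"longitude {lon} outside [-180, 180]")


@dataclass(frozen=True)
class StructuredAddress:
    """A structured location: country is required for retention, the rest
    may be empty strings."""

    country: str
    state: str = ""
    county: str = ""
    city: str = ""
    zip: str = ""


@dataclass(frozen=True)
class Tweet:
    """A raw social-media post with an optional resolved address."""

    text: str
    user_id: str
    timestamp: _dt.datetime
    raw_location: str = ""
    resolved: StructuredAddress | None = None

    def __post_init__(self):
        if self.text is None:
            raise ValueError("tweet text must not be None")


@dataclass(frozen=True)
class CityPanelRow:
    """Per-city tweet count, donor-registration count and population."""

    city: str
    tweets: int
    registrations: int
    population: int

    def __post_init__(self):
        if self.tweets < 0 or self.registrations < 0:
            raise ValueError("counts must be non-negative")
        if self.population < 1:
            raise ValueError("population must be >= 1")


@dataclass
class ContentArm:
    """One piece of ad content with its accumulated delivery counts.

    ``true_ctr`` is the per-impression click probability used only in
    simulation; observed counts are what the selection rule sees.
    """

    arm_id: str
    true_ctr: float | None = None
    impressions: int = 0
    clicks: int = 0
    views: int = 0

    def __post_init__(self):
        if self.clicks > self.impressions:
            raise ValueError("clicks cannot exceed impressions")
        if self.views < 0:
            raise ValueError("views must be non-negative")


@dataclass(frozen=True)
class CampaignDayRecord:
    """One day of campaign delivery, aggregated over content arms.

    ``phase`` is 0 before content optimization and 1 after.
    """

    date: _dt.date
    phase: int
    impressions: int
    clicks: int
    views: int

    def __post_init__(self):
        if self.phase not in (0, 1):
            raise ValueError("phase must be 0 (pre) or 1 (post)")
        if self.clicks > self.impressions:
            raise ValueError("clicks cannot exceed impressions")
        if min(self.impressions, self.clicks, self.views) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def clicks_per_impression(self) -> float:
        if self.impressions == 0:
            raise ValueError("C/I undefined when impressions == 0")
        return self.clicks / self.impressions

    @property
    def views_per_impression(self) -> float:
        if self.impressions == 0:
            raise ValueError("V/I undefined when impressions == 0")
        return self.views / self.impressions


@dataclass(frozen=True)
class ArmDayRecord:
    """Arm-level delivery for one day (the unaggregated campaign unit)."""

    date: _dt.date
    phase: int
    arm_id: str
    impressions: int
    clicks: int
    views: int
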