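"""Synthetic inputs with the statistical structure the pipeline assumes.

Each generator emulates one of the study's (non-deposited) data sources:

* transplant records with planted zip-code community blocks, so community
  detection on the resulting flow network has a known ground truth;
* tweet streams with a controlled fraction of marker-bearing posts and
  gazetteer-drawn or garbage profile locations;
* city panels where registrations follow a Poisson law with a known
  awareness effect, so calibration can be checked for parameter recovery;
* ad-campaign day records with per-arm click probabilities and optional
  impression saturation.

All generators take an explicit integer seed, never touch global random
state, and are byte-deterministic for a fixed configuration.
"""
from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ConfigurationError
from .records import (
    ArmDayRecord,
    CityPanelRow,
    ContentArm,
    TransplantRecord,
    Tweet,
)
from .sensor import DEFAULT_CONTEXT_WORDS, DEFAULT_SUBJECT_WORDS, Gazetteer

# inflected variants used to exercise the whole-word-vs-substring decision
_INFLECTED = {
    "transplant": "transplants",
    "transplantation": "transplantations",
    "donor": "donors",
    "donation": "donations",
    "donate": "donated",
    "heart": "hearts",
    "kidney": "kidneys",
    "liver": "livers",
    "lung": "lungs",
    "pancreas": "pancreases",
    "intestine": "intestines",
}
_NOISE_WORDS = (
    "coffee", "morning", "game", "music", "weather", "traffic",
    "lunch", "weekend", "movie", "friends", "family", "work",
)

DEFAULT_GROUP_MIX = {"hispanic": 0.3, "black": 0.2, "white": 0.5}


def _check_probability(name: str, p: float) -> None:
    if not 0.0 <= p <= 1.0:
        raise ConfigurationError(f"{name} must be in [0, 1], got {p}")


def gen_transplant_records(
    n_transplants: int,
    n_zips: int = 60,
    n_blocks: int = 3,
    p_within: float = 0.9,
    p_between: float = 0.02,
    group_mix: dict[str, float] | None = None,
    seed: int = 0,
) -> list[TransplantRecord]:
    """Transplant flows over zip codes with planted community blocks.

    Zip codes are split into ``n_blocks`` contiguous blocks, each placed
    around its own geographic center.  A transplant's donor block is drawn
    uniformly; the recipient block equals the donor block with relative
    propensity ``p_within`` against ``p_between`` per other block.  Donor
    and recipient ethnoracial groups are drawn independently from
    ``group_mix``.
    """
    if n_transplants < 0 or n_zips < 1 or n_blocks < 1:
        raise ConfigurationError("counts must be non-negative (n_zips, n_blocks >= 1)")
    if n_blocks > n_zips:
        raise ConfigurationError("n_blocks must not exceed n_zips")
    _check_probability("p_within", p_within)
    _check_probability("p_between", p_between)
    if p_within < p_between:
        raise ConfigurationError("p_within must be >= p_between")
    group_mix = dict(group_mix or DEFAULT_GROUP_MIX)
    if abs(sum(group_mix.values()) - 1.0) > 1e-9:
        raise ConfigurationError("group_mix proportions must sum to 1")
    if any(p < 0 for p in group_mix.values()):
        raise ConfigurationError("group_mix proportions must be non-negative")

    rng = np.random.default_rng(seed)
    zips = [f"{90000 + i:05d}" for i in range(n_zips)]
    block_of = np.array([i * n_blocks // n_zips for i in range(n_zips)])
    members = [np.flatnonzero(block_of == b) for b in range(n_blocks)]
    # spread block centers on a coarse grid, jitter each zip around its center
    centers = [(28.0 + 7.0 * (b % 4), -120.0 + 12.0 * (b // 4)) for b in range(n_blocks)]
    lat = np.empty(n_zips)
    lon = np.empty(n_zips)
    for i in range(n_zips):
        c_lat, c_lon = centers[block_of[i]]
        lat[i] = c_lat + rng.uniform(-1.0, 1.0)
        lon[i] = c_lon + rng.uniform(-1.0, 1.0)

    groups = list(group_mix)
    probs = np.array([group_mix[g] for g in groups])
    block_kernel = np.full((n_blocks, n_blocks), p_between)
    np.fill_diagonal(block_kernel, p_within)
    block_kernel /= block_kernel.sum(axis=1, keepdims=True)

    records: list[TransplantRecord] = []
    for _ in range(n_transplants):
        b_d = rng.integers(n_blocks)
        b_r = rng.choice(n_blocks, p=block_kernel[b_d])
        zd = int(rng.choice(members[b_d]))
        zr = int(rng.choice(members[b_r]))
        g_d, g_r = rng.choice(groups, size=2, p=probs)
        records.append(
            TransplantRecord(
                donor_zip=zips[zd],
                recipient_zip=zips[zr],
                donor_group=str(g_d),
                recipient_group=str(g_r),
                donor_lat=float(lat[zd]),
                donor_lon=float(lon[zd]),
                recipient_lat=float(lat[zr]),
                recipient_lon=float(lon[zr]),
            )
        )
    return records


def planted_blocks(n_zips: int, n_blocks: int) -> dict[str, int]:
    """Ground-truth zip -> block labels matching gen_transplant_records."""
    return {
        f"{90000 + i:05d}": i * n_blocks // n_zips for i in range(n_zips)
    }


def gen_tweets(
    n_users: int,
    n_days: int,
    rate_per_user_day: float,
    p_marker: float,
    gazetteer: Gazetteer,
    seed: int = 0,
    p_garbage_location: float = 0.1,
    p_inflected: float = 0.2,
    start: _dt.datetime = _dt.datetime(2015, 4, 22),
) -> list[Tweet]:
    """Tweet stream with a controlled marker-bearing fraction.

    Each user posts Poisson(rate_per_user_day * n_days) tweets at uniform
    times in the window.  With probability ``p_marker`` a tweet contains at
    least one context and one subject word in base form (so it passes the
    whole-word filter by construction); otherwise it contains at most one
    of the two classes — possibly an *inflected* form of the other class
    ("donated", "kidneys"), which a substring matcher would catch but a
    whole-word matcher must not.  Locations are gazetteer aliases except
    for a ``p_garbage_location`` fraction of unresolvable strings.
    """
    if n_users < 0 or n_days < 0 or rate_per_user_day < 0:
        raise ConfigurationError("counts and rates must be non-negative")
    for name, p in (
        ("p_marker", p_marker),
        ("p_garbage_location", p_garbage_location),
        ("p_inflected", p_inflected),
    ):
        _check_probability(name, p)
    if len(gazetteer) == 0:
        raise ConfigurationError("gazetteer must be non-empty")

    rng = np.random.default_rng(seed)
    aliases = gazetteer.aliases
    context = sorted(DEFAULT_CONTEXT_WORDS)
    subject = sorted(DEFAULT_SUBJECT_WORDS)
    tweets: list[Tweet] = []
    for u in range(n_users):
        if rng.random() < p_garbage_location:
            location = f"nowhere-{u}"
        else:
            location = str(aliases[rng.integers(len(aliases))])
        n_posts = rng.poisson(rate_per_user_day * n_days)
        for _ in range(n_posts):
            t = start + _dt.timedelta(seconds=float(rng.uniform(0, n_days * 86400)))
            noise = " ".join(rng.choice(_NOISE_WORDS, size=2))
            if rng.random() < p_marker:
                c = context[rng.integers(len(context))]
                s = subject[rng.integers(len(subject))]
                text = f"please {c} a {s} today {noise}"
                if rng.random() < p_inflected:
                    text += f" {_INFLECTED[c]} {_INFLECTED[s]}"
            else:
                kind = rng.integers(3)
                if kind == 0:  # context word only
                    text = f"{context[rng.integers(len(context))]} drive {noise}"
                elif kind == 1:  # subject word only
                    text = f"my {subject[rng.integers(len(subject))]} aches {noise}"
                else:  # inflected forms only: substring-positive, word-negative
                    c = context[rng.integers(len(context))]
                    s = subject[rng.integers(len(subject))]
                    text = f"{_INFLECTED[c]} two {_INFLECTED[s]} {noise}"
            tweets.append(
                Tweet(text=text, user_id=f"u{u}", timestamp=t, raw_location=location)
            )
    return tweets


@dataclass(frozen=True)
class CityPanel:
    """A generated city panel plus its ground-truth parameters."""

    rows: list[CityPanelRow]
    alpha: float
    beta: float

    def __iter__(self):
        return iter(self.rows)

    def __len__(self) -> int:
        return len(self.rows)


def gen_city_panel(
    n_cities: int,
    pop_low: int = 10_000,
    pop_high: int = 200_000,
    alpha: float = -6.0,
    beta: float = 0.0032,
    tweet_rate_scale: float = 5e-4,
    seed: int = 0,
) -> CityPanel:
    """City panel with a known Poisson awareness effect.

    Per city: population ~ Uniform{pop_low..pop_high}; tweets ~
    Poisson(population * tweet_rate_scale); registrations ~
    Poisson(population * exp(alpha + beta * tweets)), i.e. population acts
    as a multiplicative exposure.  The default ``beta`` matches the scale
    of the fitted awareness association the framework is built to detect.
    """
    if n_cities < 0:
        raise ConfigurationError("n_cities must be non-negative")
    if pop_low > pop_high or pop_low < 1:
        raise ConfigurationError("require 1 <= pop_low <= pop_high")
    if tweet_rate_scale <= 0:
        raise ConfigurationError("tweet_rate_scale must be positive")
    rng = np.random.default_rng(seed)
    rows: list[CityPanelRow] = []
    for i in range(n_cities):
        pop = int(rng.integers(pop_low, pop_high + 1))
        tweets = int(rng.poisson(pop * tweet_rate_scale))
        mu = pop * float(np.exp(alpha + beta * tweets))
        regs = int(rng.poisson(mu))
        rows.append(CityPanelRow(city=f"city{i:04d}", tweets=tweets,
                                 registrations=regs, population=pop))
    return CityPanel(rows=rows, alpha=alpha, beta=beta)


@dataclass(frozen=True)
class CampaignConfig:
    """Parameters of a simulated explore-then-commit ad campaign.

    Daily impression totals grow geometrically at ``impression_growth``
    per day, emulating the ramp-up of a real ad campaign; some day-to-day
    variation in impressions is also required for the effect regression's
    impressions term to be identifiable.  ``saturation_slope`` lowers each
    arm's effective click probability by ``slope * daily_impressions``
    (floored at ``ctr_floor``), emulating the audience-saturation decline
    seen in real delivery data.
    """

    arms: Sequence[ContentArm]
    days_pre: int = 20
    days_post: int = 11
    base_impressions: int = 20_000
    impression_growth: float = 0.05
    saturation_slope: float = 0.0
    view_rate: float = 0.35
    ctr_floor: float = 1e-4
    start: _dt.date = _dt.date(2016, 8, 4)
    seed: int = 0

    def validate(self) -> None:
        if not self.arms:
            raise ConfigurationError("at least one content arm is required")
        for arm in self.arms:
            if arm.true_ctr is None or not 0.0 < arm.true_ctr < 1.0:
                raise ConfigurationError(
                    f"arm {arm.arm_id!r} needs a true_ctr strictly in (0, 1)"
                )
        if self.days_pre < 1:
            raise ConfigurationError("days_pre must be >= 1")
        if self.days_post < 0:
            raise ConfigurationError("days_post must be >= 0")
        if self.base_impressions < 0 or self.saturation_slope < 0:
            raise ConfigurationError("impressions and saturation must be non-negative")
        _check_probability("view_rate", self.view_rate)


def _simulate_day(
    rng: np.random.Generator,
    config: CampaignConfig,
    day_index: int,
    phase: int,
    arm_ids: Sequence[str],
) -> list[ArmDayRecord]:
    ctr = {a.arm_id: a.true_ctr for a in config.arms}
    total = int(round(config.base_impressions * (1.0 + config.impression_growth) ** day_index))
    share = total // len(arm_ids)
    remainder = total - share * len(arm_ids)
    date = config.start + _dt.timedelta(days=day_index)
    out: list[ArmDayRecord] = []
    for k, arm_id in enumerate(arm_ids):
        imp = share + (1 if k < remainder else 0)
        p = max(ctr[arm_id] - config.saturation_slope * total, config.ctr_floor)
        clicks = int(rng.binomial(imp, p)) if imp else 0
        views = int(rng.binomial(clicks, config.view_rate)) if clicks else 0
        out.append(ArmDayRecord(date=date, phase=phase, arm_id=arm_id,
                                impressions=imp, clicks=clicks, views=views))
    return out


def gen_campaign(
    config: CampaignConfig, selected_arm: str | None = None,
    rng: np.random.Generator | None = None,
) -> list[ArmDayRecord]:
    """Arm-level campaign records.

    The pre-optimization phase splits each day's impressions equally across
    all arms.  Post-phase records are generated only when ``selected_arm``
    is given (normally by the explore-then-commit policy in
    :func:`donorsense.campaign.run_campaign`), and deliver that arm alone.
    """
    config.validate()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    arm_ids = [a.arm_id for a in config.arms]
    records: list[ArmDayRecord] = []
    for d in range(config.days_pre):
        records.extend(_simulate_day(rng, config, d, phase=0, arm_ids=arm_ids))
    if selected_arm is not None:
        if selected_arm not in arm_ids:
            raise ConfigurationError(f"unknown arm {selected_arm!r}")
        for d in range(config.days_pre, config.days_pre + config.days_post):
            records.extend(
                _simulate_day(rng, config, d, phase=1, arm_ids=[selected_arm])
            )
    return records
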