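"""Two-phase ad-content optimization and its effect evaluation.

The intervention runs explore-then-commit: during a pre-optimization phase
impressions are split equally across content arms; at the phase boundary
the arm with the highest observed clicks-per-impression (C/I) is selected,
and the post-optimization phase delivers that arm exclusively.

The optimization effect is evaluated with an OLS regression of the daily
per-impression ratio (C/I or V/I) on the phase indicator O, the raw daily
impression count I and their interaction:

    ratio_t = b0 + b1*O_t + b2*I_t + b3*(O_t * I_t) + e_t

b1 is the level shift due to optimization (at the zero-impression
baseline); b2 captures audience saturation; b3 its change after
optimization.  The headline effect is 1000*b1 extra clicks per thousand
impressions.
"""
from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from decimal import ROUND_HALF_EVEN, Decimal
from fractions import Fraction
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .errors import FittingError, ValidationError
from .records import ArmDayRecord, CampaignDayRecord, ContentArm
from .synthetic_data import CampaignConfig, _simulate_day, gen_campaign

OUTCOMES = ("clicks_per_impression", "views_per_impression")


def _pct2(numer: int, denom: int) -> float:
    """100 * numer/denom rounded half-even to 2 decimals."""
    if denom == 0:
        raise ValidationError("ratio undefined when impressions == 0")
    return float(
        (Decimal(100 * numer) / Decimal(denom)).quantize(
            Decimal("0.01"), rounding=ROUND_HALF_EVEN
        )
    )


def _round_int(x: float) -> int:
    return int(Decimal(repr(x)).quantize(Decimal("1"), rounding=ROUND_HALF_EVEN))


@dataclass(frozen=True)
class PhaseTotals:
    """Exact count totals for one phase (or the whole campaign)."""

    impressions: int
    clicks: int
    views: int
    ci_pct: float
    vi_pct: float


@dataclass(frozen=True)
class CampaignSummary:
    """Pre/post/overall totals with percentage engagement rates."""

    pre: PhaseTotals
    post: PhaseTotals
    overall: PhaseTotals


@dataclass(frozen=True)
class OLSFit:
    """Fitted per-day ratio regression on {1, O, I, O*I}."""

    outcome: str
    params: dict[str, float]
    bse: dict[str, float]
    pvalues: dict[str, float]
    fvalue: float
    f_df: tuple[int, int]
    f_pvalue: float
    rsquared: float
    rsquared_adj: float
    df_resid: int

    TERMS = ("const", "optimization", "impressions", "interaction")


@dataclass(frozen=True)
class EffectEstimate:
    """Optimization effect on the per-thousand-impressions scale."""

    extra_clicks_per_1000: int
    ci_low: float
    ci_high: float
    pre_baseline_per_1000: int
    post_baseline_per_1000: int


def select_best_arm(arms: Sequence[ContentArm]) -> str:
    """Arm id with the highest observed C/I; ties break to the
    lexicographically smallest id.  Ratios are compared exactly."""
    if not arms:
        raise ValidationError("no arms to select from")
    for arm in arms:
        if arm.impressions <= 0:
            raise ValidationError(f"arm {arm.arm_id!r} has no impressions")
    return min(arms, key=lambda a: (-Fraction(a.clicks, a.impressions), a.arm_id)).arm_id


def run_campaign(config: CampaignConfig) -> list[CampaignDayRecord]:
    """Simulate a full explore-then-commit campaign, one record per day.

    Pre-phase days split impressions equally across arms; the arm with the
    highest cumulative pre-phase C/I is then committed to for every
    post-phase day.  Arm-level draws are aggregated into daily totals with
    the phase flag.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    arm_records = gen_campaign(config, selected_arm=None, rng=rng)
    totals: dict[str, ContentArm] = {
        a.arm_id: ContentArm(a.arm_id, a.true_ctr) for a in config.arms
    }
    for rec in arm_records:
        t = totals[rec.arm_id]
        t.impressions += rec.impressions
        t.clicks += rec.clicks
        t.views += rec.views
    if config.days_post > 0:
        best = select_best_arm(list(totals.values()))
        for d in range(config.days_pre, config.days_pre + config.days_post):
            arm_records.extend(
                _simulate_day(rng, config, d, phase=1, arm_ids=[best])
            )
    return aggregate_daily(arm_records)


def aggregate_daily(arm_records: Sequence[ArmDayRecord]) -> list[CampaignDayRecord]:
    """Sum arm-level records into one record per calendar day."""
    by_day: dict[_dt.date, list[ArmDayRecord]] = {}
    for rec in arm_records:
        by_day.setdefault(rec.date, []).append(rec)
    out = []
    for date in sorted(by_day):
        recs = by_day[date]
        phases = {r.phase for r in recs}
        if len(phases) != 1:
            raise ValidationError(f"mixed phases on {date}")
        out.append(
            CampaignDayRecord(
                date=date,
                phase=phases.pop(),
                impressions=sum(r.impressions for r in recs),
                clicks=sum(r.clicks for r in recs),
                views=sum(r.views for r in recs),
            )
        )
    return out


def _phase_totals(records: Sequence[CampaignDayRecord]) -> PhaseTotals:
    i = sum(r.impressions for r in records)
    c = sum(r.clicks for r in records)
    v = sum(r.views for r in records)
    return PhaseTotals(i, c, v, _pct2(c, i), _pct2(v, i))


def summarize_campaign(records: Sequence[CampaignDayRecord]) -> CampaignSummary:
    """Exact integer totals per phase and overall, with C/I and V/I as
    percentages rounded half-even to 2 decimals."""
    if not records:
        raise ValidationError("no campaign records to summarize")
    pre = [r for r in records if r.phase == 0]
    post = [r for r in records if r.phase == 1]
    if not pre or not post:
        # single-phase campaigns still get exact totals; the missing phase
        # is reported as zeros with undefined (nan) rates
        empty = PhaseTotals(0, 0, 0, float("nan"), float("nan"))
        return CampaignSummary(
            pre=_phase_totals(pre) if pre else empty,
            post=_phase_totals(post) if post else empty,
            overall=_phase_totals(records),
        )
    return CampaignSummary(
        pre=_phase_totals(pre), post=_phase_totals(post),
        overall=_phase_totals(list(records)),
    )


def fit_effect_model(
    records: Sequence[CampaignDayRecord], outcome: str = "clicks_per_impression"
) -> OLSFit:
    """Unweighted OLS of the daily ratio on {1, O, I, O*I}.

    Impressions enter in raw units.  Requires >= 5 days spanning both
    phases; a single-phase design is singular in O and rejected.
    """
    if outcome not in OUTCOMES:
        raise ValidationError(f"outcome must be one of {OUTCOMES}, got {outcome!r}")
    records = list(records)
    if len(records) < 5:
        raise FittingError("effect model requires >= 5 daily records")
    phases = {r.phase for r in records}
    if phases != {0, 1}:
        raise FittingError("effect model requires records from both phases")
    y = np.array([getattr(r, outcome) for r in records])
    o = np.array([r.phase for r in records], dtype=float)
    i = np.array([r.impressions for r in records], dtype=float)
    X = pd.DataFrame(
        {"const": 1.0, "optimization": o, "impressions": i, "interaction": o * i}
    )
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise FittingError("singular design matrix")
    res = sm.OLS(y, X).fit()
    return OLSFit(
        outcome=outcome,
        params=dict(zip(X.columns, res.params)),
        bse=dict(zip(X.columns, res.bse)),
        pvalues=dict(zip(X.columns, res.pvalues)),
        fvalue=float(res.fvalue),
        f_df=(int(res.df_model), int(res.df_resid)),
        f_pvalue=float(res.f_pvalue),
        rsquared=float(res.rsquared),
        rsquared_adj=float(res.rsquared_adj),
        df_resid=int(res.df_resid),
    )


def marginal_effects(fit: OLSFit, level: float = 0.95) -> EffectEstimate:
    """Optimization effect per 1000 impressions from a C/I fit.

    Point estimate 1000*b1 with a t-interval 1000*(b1 +/- t_{a/2,df}*SE);
    baselines are the zero-impression intercepts of each phase.  Integer
    values use half-even rounding.
    """
    if fit.outcome != "clicks_per_impression":
        raise ValidationError("marginal effects are defined for the C/I model")
    b0, b1 = fit.params["const"], fit.params["optimization"]
    se1 = fit.bse["optimization"]
    t_crit = scipy.stats.t.ppf(0.5 + level / 2, fit.df_resid)
    return EffectEstimate(
        extra_clicks_per_1000=_round_int(1000.0 * b1),
        ci_low=float(1000.0 * (b1 - t_crit * se1)),
        ci_high=float(1000.0 * (b1 + t_crit * se1)),
        pre_baseline_per_1000=_round_int(1000.0 * b0),
        post_baseline_per_1000=_round_int(1000.0 * (b0 + b1)),
    )
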