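"""Calibrating the awareness sensor against donor-registration counts.

The calibration unit is a city panel: per city, the number of organ-related
tweets, the number of organ-donor registrations and the population.  Two
complementary estimates are provided:

* a Poisson regression of registrations on tweet counts with population as
  exposure (log offset by default), whose tweet coefficient ``beta``
  converts to "k extra tweets ~ 100*k*beta percent more registrations";
* a model-free bootstrap that bins cities into percentile groups of their
  tweet *rate* (tweets/population) and resamples each group's mean
  registration count.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .errors import FittingError, ValidationError
from .records import CityPanelRow


@dataclass(frozen=True)
class PoissonFit:
    """Fitted Poisson regression of registrations on tweet counts.

    ``params``/``bse``/``pvalues`` are keyed by term name; ``mode`` records
    how population entered the model ("offset" or "covariate").
    """

    params: dict[str, float]
    bse: dict[str, float]
    pvalues: dict[str, float]
    mode: str
    n_obs: int
    converged: bool

    @property
    def alpha(self) -> float:
        return self.params["const"]

    @property
    def beta(self) -> float:
        return self.params["tweets"]

    def conf_int(self, term: str = "tweets", level: float = 0.95) -> tuple[float, float]:
        z = scipy.stats.norm.ppf(0.5 + level / 2)
        return self.params[term] - z * self.bse[term], self.params[term] + z * self.bse[term]


@dataclass(frozen=True)
class BootstrapGroupEstimate:
    """Bootstrap estimate of one percentile group's mean registrations."""

    group: str
    n_cities: int
    mean: float
    ci_low: float
    ci_high: float
    B: int

    @property
    def defined(self) -> bool:
        return not math.isnan(self.mean)


def _panel_frame(panel: Sequence[CityPanelRow]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "city": [r.city for r in panel],
            "tweets": [r.tweets for r in panel],
            "registrations": [r.registrations for r in panel],
            "population": [r.population for r in panel],
        }
    )


def fit_poisson_registrations(
    panel: Sequence[CityPanelRow], mode: str = "offset"
) -> PoissonFit:
    """Maximum-likelihood Poisson regression of registrations on tweets.

    With ``mode="offset"`` (default) the model is
    ``registrations_i ~ Poisson(population_i * exp(alpha + beta * tweets_i))``,
    i.e. log(population) enters as exposure with coefficient fixed at 1.
    ``mode="covariate"`` instead adds log(population) as a free regressor.
    """
    if mode not in ("offset", "covariate"):
        raise ValidationError(f"mode must be 'offset' or 'covariate', got {mode!r}")
    if len(panel) < 3:
        raise ValidationError("Poisson calibration requires >= 3 cities")
    df = _panel_frame(panel)
    if df["tweets"].nunique() < 2:
        raise ValidationError("degenerate panel: tweet counts show no variation")
    y = df["registrations"].to_numpy(dtype=float)
    X = pd.DataFrame({"const": 1.0, "tweets": df["tweets"].astype(float)})
    offset = None
    if mode == "offset":
        offset = np.log(df["population"].to_numpy(dtype=float))
    else:
        X["log_population"] = np.log(df["population"].to_numpy(dtype=float))
    try:
        res = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset).fit()
    except Exception as exc:  # perfect separation / singular design
        raise FittingError(f"Poisson fit failed: {exc}") from exc
    if not res.converged:
        raise FittingError("Poisson fit did not converge")
    return PoissonFit(
        params=dict(zip(X.columns, res.params)),
        bse=dict(zip(X.columns, res.bse)),
        pvalues=dict(zip(X.columns, res.pvalues)),
        mode=mode,
        n_obs=len(df),
        converged=bool(res.converged),
    )


def percent_effect(beta: float, k_tweets: int, method: str = "linear") -> float:
    """Percent change in registrations associated with ``k_tweets`` extra
    tweets.

    ``linear`` is the first-order approximation 100*k*beta; ``multiplicative``
    is the exact log-link change 100*(exp(k*beta) - 1).  They agree to first
    order for small k*beta.
    """
    if k_tweets < 0:
        raise ValidationError("k_tweets must be >= 0")
    if method == "linear":
        return 100.0 * k_tweets * beta
    if method == "multiplicative":
        return 100.0 * (math.exp(k_tweets * beta) - 1.0)
    raise ValidationError(f"method must be 'linear' or 'multiplicative', got {method!r}")


def bootstrap_percentile_groups(
    panel: Sequence[CityPanelRow],
    boundaries: Sequence[float] = (0, 25, 50, 75, 100),
    B: int = 10_000,
    seed: int = 0,
) -> list[BootstrapGroupEstimate]:
    """Bootstrap the mean registrations of tweet-rate percentile groups.

    Cities are binned by the percentile of their tweet rate
    (tweets/population) into ``len(boundaries)-1`` groups; bins are
    left-closed/right-open except the top bin, which is closed.  Each
    group's cities are resampled with replacement ``B`` times; the estimate
    is the mean of resample means with a 2.5/97.5 percentile interval.
    An empty group yields a NaN-flagged estimate.
    """
    boundaries = list(boundaries)
    if len(boundaries) < 2 or boundaries != sorted(boundaries):
        raise ValidationError("boundaries must be an increasing percentile list")
    n_groups = len(boundaries) - 1
    if len(panel) < n_groups:
        raise ValidationError("panel smaller than the number of groups")
    if B < 1:
        raise ValidationError("B must be >= 1")
    rng = np.random.default_rng(seed)
    rates = np.array([r.tweets / r.population for r in panel])
    regs = np.array([r.registrations for r in panel], dtype=float)
    cuts = np.percentile(rates, boundaries)
    out: list[BootstrapGroupEstimate] = []
    for g in range(n_groups):
        lo, hi = cuts[g], cuts[g + 1]
        if g == n_groups - 1:
            mask = (rates >= lo) & (rates <= hi)
        else:
            mask = (rates >= lo) & (rates < hi)
        label = f"{boundaries[g]:g}-{boundaries[g + 1]:g}"
        grp = regs[mask]
        if grp.size == 0:
            out.append(
                BootstrapGroupEstimate(label, 0, math.nan, math.nan, math.nan, B)
            )
            continue
        idx = rng.integers(0, grp.size, size=(B, grp.size))
        means = grp[idx].mean(axis=1)
        out.append(
            BootstrapGroupEstimate(
                group=label,
                n_cities=int(grp.size),
                mean=float(means.mean()),
                ci_low=float(np.percentile(means, 2.5)),
                ci_high=float(np.percentile(means, 97.5)),
                B=B,
            )
        )
    return out


def state_level_correlation(
    tweets_by_state: pd.DataFrame, registrations_by_state: pd.DataFrame
) -> tuple[float, float]:
    """Pearson correlation of state-level tweets vs registrations.

    Both inputs need columns ``state`` and a single count column; states
    are inner-joined and at least 3 matches are required.  Returns (r, p).
    """
    def _series(df: pd.DataFrame, what: str) -> pd.Series:
        if "state" not in df.columns or df.shape[1] < 2:
            raise ValidationError(f"{what} table needs 'state' plus one count column")
        value_col = [c for c in df.columns if c != "state"][0]
        return df.set_index("state")[value_col]

    t = _series(tweets_by_state, "tweets")
    r = _series(registrations_by_state, "registrations")
    joined = pd.concat([t, r], axis=1, join="inner").dropna()
    if len(joined) < 3:
        raise ValidationError("state correlation requires >= 3 matched states")
    r_val, p_val = scipy.stats.pearsonr(joined.iloc[:, 0], joined.iloc[:, 1])
    return float(r_val), float(p_val)
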