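# Methods

This note documents the models, conventions and design choices behind
`donorsense`, and what the synthetic-data tests do and do not establish.

## Transplant-flow networks

A geographical social network (GSN) is a directed graph over home zip
codes; an edge donor-zip → recipient-zip carries an integer weight equal
to the number of transplants between that ordered pair. Ethnoracial GSNs
filter on the *recipient's* group only: in the Hispanic network every edge
ends at a Hispanic recipient's zip code, while donors of any group appear
as origins. Same-zip transplants produce self-loops, which are kept in
the graph but ignored by the clustering coefficient (triangles through a
self-loop are not meaningful).

Conventions where the summary statistics admit variants:

* **Link count M** is the number of distinct weighted zip-pair edges, not
  the number of transplants. Average degree is M/N_n.
* **Clustering coefficient (CC)** is the global transitivity of the
  undirected, unweighted projection — 3·triangles / connected triples,
  i.e. the probability that two zip codes sharing a transplant partner
  are themselves connected. This matches the verbal "likelihood of two
  nodes being connected given they share a common node"; the mean-local
  variant is available via `method="average_local"`.
* **Average path length (L)** is the mean shortest-path hop count over
  ordered pairs within the largest connected component of the undirected
  projection. Directed zip-flow graphs are rarely strongly connected, so
  the undirected/largest-component convention keeps L finite; it is
  undefined (error / NaN in summaries) when that component has < 2 nodes.
* **Communities** come from Louvain modularity maximization on the
  weighted undirected projection with an explicit seed; the partition is
  deterministic given the seed, and community ids are renumbered 0,1,…
  by each community's smallest node label so output files are stable.
* **Dispersion** is the mean pairwise great-circle (haversine) distance
  of a community's node coordinates, spherical Earth R = 6371 km;
  singleton communities score 0.

## Awareness sensor

Marker matching tokenizes on runs of non-alphanumeric characters and
lowercases, then intersects tokens with the two word sets. Whole-word
matching is the default: "donated" and "kidneys" do **not** match. This
is deliberately conservative — substring matching would hit inside
unrelated words — and the `substring=True` option exposes the permissive
alternative; the synthetic tweet generator plants inflected-only posts
precisely to keep the two dialects distinguishable in tests.

Location resolution is an exact lookup of the normalized profile string
(lowercased, punctuation collapsed to single spaces) against an offline
gazetteer table. Lookup failures are expected and silently drop the
tweet from geographic aggregates; only US addresses are retained. The
packaged `demo_gazetteer.csv` is a small hand-written synthetic table for
examples and tests, not an extract of any geocoding service.

Descriptive statistics pin two ambiguous conventions: the day count of a
collection window defaults to the exclusive difference `end − start` in
days, tweets/day uses integer floor division, and all other ratios round
half-even to 2 decimals. Under these conventions the reference
collection (134,986 tweets, 71,947 users, 385 days) gives 350 tweets/day
and 1.88 tweets/user. Organ mentions count *distinct* subject words per
tweet, and per user the union over the user's tweets.

## Calibration

The default Poisson model treats population as a multiplicative exposure:

    registrations_i ~ Poisson( pop_i · exp(α + β · tweets_i) )

fitted by IRLS maximum likelihood (log-population offset). The
alternative `mode="covariate"` frees the population elasticity by adding
log(pop) as a regressor; the offset default is also what the synthetic
panel generator simulates, keeping generator and fitter internally
consistent. A useful invariant: rescaling every population by c shifts
only α by −log c under the offset model.

The percent conversion of the coefficient is linear by default,
100·k·β for k extra tweets (β = 0.0032, k = 10 → 3.20 %); the exact
log-link change 100·(exp(kβ) − 1) is available as `multiplicative`
(→ 3.2518 % for the same inputs). The linear form is the package default
because it is the first-order reading of a small coefficient and is what
the headline arithmetic of such analyses conventionally reports.

The bootstrap cross-check ranks cities by tweet *rate* (tweets divided by
population), cuts the rate distribution at the requested percentiles
(default 0/25/50/75/100, linear interpolation), and assigns
left-closed/right-open bins except the top bin, which is closed — so
group assignment is deterministic, with rate ties resolved identically
for identical rates. Each group's mean registrations is estimated from
B = 10,000 resamples with replacement; the interval is the 2.5/97.5
percentile of the resample means. Empty groups are flagged with NaN
rather than raising.

## Campaign optimization

The policy is explore-then-commit. During `days_pre` days each day's
impression budget is split equally across arms (integer remainder spread
over the first arms); at the boundary the arm with the highest cumulative
C/I is selected — ratios compared as exact fractions, ties broken by
lexicographically smallest arm id — and all `days_post` delivery goes to
it.

The effect model is unweighted OLS of the *daily ratio* (C/I or V/I) on
{1, O, I, O·I} with impressions in raw units. The ratio-outcome choice
makes the intercept interpretable as the zero-impression baseline rate
and the O coefficient as the optimization level shift; 1000·b₁ is the
extra-clicks-per-thousand headline, with a t-interval
1000·(b₁ ± t₀.₉₇₅,n−4·SE). There is no external control group: the
pre-optimization phase serves as the counterfactual, so the estimate is a
before/after contrast and inherits any time-trend confounding; the I and
O·I terms absorb the observable saturation trend but nothing else.
Percentages round half-even to 2 decimals and per-1000 effects to
integers; exact integer totals are preserved everywhere (overall totals
equal the sum of phase subtotals by construction).

## Synthetic-data generators

All generators consume a single `numpy.random.default_rng(seed)` and
never touch global state, so identical configurations are byte-identical.
Defaults are chosen once to represent a realistic study:

* **Transplants**: 60 zips in 3 planted blocks, within/between propensity
  0.9/0.02, group mix 30 % Hispanic / 20 % black / 50 % white. Blocks are
  geographically separated clusters with ±1° jitter, so community
  dispersion is exercised. At ≥ ~300 transplants per block this
  separation makes Louvain recovery essentially certain (adjusted Rand
  ≥ 0.9); the recovery tests measure exactly that.
* **Tweets**: users post at a Poisson rate (default scenarios use a few
  thousand posts); a fraction `p_marker` (default scenarios 0.4) contain
  base-form context+subject words and therefore pass the filter by
  construction, the rest contain at most one marker class, including an
  inflected-only class that separates whole-word from substring matching.
  10 % of users get unresolvable garbage locations.
* **City panel**: population ~ Uniform{10,000…200,000}, tweets ~
  Poisson(5·10⁻⁴·pop), registrations from the offset Poisson model with
  α = −6.0 and β = 0.0032 — an awareness effect of the magnitude the
  calibration stage is designed to detect, used as simulation truth for
  recovery and coverage checks.
* **Campaign**: 20 pre + 11 post days, ~20,000 base impressions/day with
  5 % daily geometric growth (a ramping budget; day-to-day variation in I
  is also what identifies the impressions term — constant delivery makes
  the design singular), clicks ~ Binomial(impressions, ctr_eff) with
  ctr_eff = ctr − saturation_slope·(daily impressions) floored at 10⁻⁴,
  page views ~ Binomial(clicks, 0.35).

What the generators do *not* emulate: retweets/bots, non-English text,
geocoder fuzziness beyond misses, day-of-week and diurnal patterns,
spatial correlation between city panels, ad-auction price dynamics, or
any behavioural feedback from the intervention to the sensor. Passing
recovery tests therefore show the estimators are correct under their
assumed data-generating processes, not that those processes describe any
particular real platform.

## Problem sizes and numerical choices

The test-suite and acceptance-script study sizes — 100 replicate
2000-city panels for coverage, 20 replicate 1000-transplant networks for
community recovery, 200 replicate 2-arm campaigns for selection
reliability, 200 random ≤ 50-node graphs against brute-force metric
oracles — were chosen as the smallest sizes at which the binomial noise
of the measured rates is well inside the asserted bands. Fits use
statsmodels (IRLS GLM, OLS); independent test oracles use hand-rolled
Newton–Raphson for the Poisson likelihood, the normal equations for OLS,
matrix-power triangle counts and sparse BFS for the graph metrics, and
exhaustive partition enumeration for modularity on 6-node graphs.

## Known limitations

* The structural summaries of real national transplant networks depend on
  registry data with restricted access; the package validates its network
  statistics property-based (against oracles and planted structure), not
  against published registry values.
* The campaign effect estimate is a single-campaign before/after
  contrast; the reported CI reflects day-level OLS sampling noise only.
* The sensor's whole-word English lexicon will undercount inflected,
  misspelled or non-English awareness expressions; the gazetteer lookup
  resolves only exact normalized aliases.
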