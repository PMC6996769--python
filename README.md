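# donorsense

Tools for monitoring and improving public awareness of organ donation.
Only about half of US adults are registered organ donors, and the shortage
falls hardest on ethnoracial minority patients, whose chances of a
well-matched organ improve with donors from comparable communities.
`donorsense` implements a four-stage analytic framework for health
researchers and organ-procurement organizations who want to quantify that
disparity, track awareness in real time, and run optimized social-media
education campaigns:

1. **Transplant-flow networks** (`donorsense.gsn`). Transplant records
   define a directed *geographical social network* (GSN): nodes are home
   zip codes, an edge donor-zip → recipient-zip is weighted by the number
   of transplants between that pair. Per recipient group the package
   reports the structural summary (N_n, M, M/N_n, CC, L, N_c): node and
   link counts, average degree, global clustering coefficient (transitivity
   — the probability that two zip codes sharing a transplant partner are
   themselves connected), average shortest-path length on the largest
   component, and the number of communities found by Louvain modularity
   maximization, plus each community's geographic dispersion in km.

2. **Awareness sensor** (`donorsense.sensor`). A post counts as an
   awareness marker when it contains ≥ 1 *context* word
   {transplant, transplantation, donor, donation, donate} **and** ≥ 1
   *subject* word naming a solid organ {heart, kidney, liver, lung,
   pancreas, intestine}. Matching is case-insensitive whole-word by
   default (a `substring` option exists). Free-text profile locations are
   resolved against an offline gazetteer table and marker counts are
   aggregated per city or state.

3. **Calibration** (`donorsense.calibration`). City-level marker counts
   are related to donor-registration counts with a Poisson regression,
   registrations_i ~ Poisson(pop_i · exp(α + β · tweets_i)), population
   entering as exposure. The headline conversion is linear:
   k extra tweets ↦ 100·k·β percent more registrations. A model-free
   cross-check bins cities into tweet-rate percentile groups (0–25, …,
   75–100) and bootstraps each group's mean registrations (B = 10,000).

4. **Campaign optimization** (`donorsense.campaign`). An ad campaign runs
   explore-then-commit: impressions are split equally across content arms
   for a pre-optimization phase, then the arm with the highest observed
   clicks-per-impression (C/I) gets all delivery. The effect is estimated
   by OLS on daily ratios, C/I_t = b₀ + b₁·O_t + b₂·I_t + b₃·O_t·I_t + ε_t
   (O = post-phase indicator, I = daily impressions), and reported as
   1000·b₁ extra clicks per thousand impressions.

`donorsense.synthetic_data` generates transplant records with planted
community blocks, tweet streams with a controlled marker fraction, city
panels with a known awareness effect and simulated campaigns, so the whole
pipeline is exercisable without any restricted data source. The package
ships one real dataset: the daily impressions/clicks/page-views table of a
31-day awareness campaign run in Los Angeles in August–September 2016
(20 pre-optimization days, 11 post-optimization days).

## Worked example

Analyze the packaged campaign table:

```bash
$ donorsense campaign report
pre: I=372524 C=10077 V=3705 C/I=2.71% V/I=0.99%
post: I=802059 C=43911 V=16196 C/I=5.47% V/I=2.02%
overall: I=1174583 C=53988 V=19901 C/I=4.6% V/I=1.69%
outcome: clicks_per_impression
  const: coef=0.04148 se=0.00328 p=7.58e-13
  optimization: coef=0.0213 se=0.00671 p=0.00373
  impressions: coef=-6.977e-07 se=1.67e-07 p=0.000281
  interaction: coef=5.938e-07 se=1.85e-07 p=0.00335
  F(3,27)=85.29 (p=6.85e-14) R2=0.905 adjR2=0.894
...
optimization effect: +21 clicks per 1000 impressions (95% CI 7.5-35.1); baseline 41 -> 63 per 1000
```

Reading: the campaign delivered 1.17 M impressions; the click-through rate
roughly doubled after optimization (2.71 % → 5.47 %). The regression
separates that into a level shift (b₁ = 0.0213: about 21 extra clicks per
1000 impressions, p = .004) and a saturation term (b₂ < 0: engagement
decays as daily impressions grow, and the interaction shows the decay
flattens after optimization).

The full synthetic pipeline in one run:

```bash
$ donorsense report --seed 7
donorsense pipeline report (seed=7)
network: N_n=60 M=1048 M/N_n=17.47 CC=0.715 L=1.680 N_c=3
sensor: 2434 tweets generated, 838 retained across 25 cities
calibration: beta=0.0033 (truth 0.0032), 10-tweet effect 3.34%
campaign: +21 clicks per 1000 impressions after optimization
```

Here community detection recovers the three planted blocks (N_c = 3), the
sensor retains the marker-bearing US-located fraction of the stream, and
the Poisson fit recovers the simulated awareness effect (β̂ = 0.0033
against a truth of 0.0032, i.e. ten extra organ-related tweets associate
with ≈ 3.3 % more registrations).

Other entry points: `donorsense simulate --config cfg.yaml`,
`donorsense gsn`, `donorsense sensor`, `donorsense calibrate`,
`donorsense campaign {simulate,summarize,fit,report}` — see `--help`.

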