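# liondens

Detecting lion (*Panthera leo*) parturition and denning events from GPS
collar telemetry, and testing what drives conception timing.

A lioness about to give birth is nearly impossible to observe directly,
but her collar betrays her: daily travel roughly halves, the monthly
50% core range collapses from a few km² to the size of a den site, and
she spends weeks — rather than the few days typical of a carcass —
within a 200 m radius of one spot. `liondens` is a library for turning
those movement signatures into inference:

- **trajectory** — step lengths, daily net displacement, residency
  clusters (maximal runs of consecutive fixes within 200 m of the
  running centroid), duration of stay;
- **homerange** — monthly 50% core / 90% total ranges via k-nearest-
  neighbour local convex hulls (k-LoCoh), with minimum-convex-polygon
  cross-checks and a local azimuthal-equidistant projection;
- **inference** — per-month denning scores, birth calls, conception
  backdating by the 3-month gestation, wet/dry season tallies and
  binomial GLMs for prey-pulse/season association;
- **stats** — AIC, small-sample AICc, Δi and Akaike weights
  (log-sum-exp stabilised), one-way ANOVA, Kruskal–Wallis, logistic
  GLMs with separation handling;
- **synth** — a seeded synthetic-telemetry generator reproducing the
  study system's structure (two regions, 4-h fixes with 10–15%
  failure, feeding stops, denning windows, wet-season conception
  bias), with full ground-truth logs;
- **io / pipeline / cli** — CSV/GeoJSON/YAML round-trips and an
  end-to-end driver (`liondens run-all`).

The model-selection core: candidate models with log-likelihood ℓ̂ and k
parameters on n observations are compared by

    AIC  = 2k − 2ℓ̂
    AICc = AIC + 2k(k+1)/(n − k − 1)
    Δi   = AICc_i − min_j AICc_j
    w_i  = exp(−Δi/2) / Σ_j exp(−Δj/2)

where w_i is the relative likelihood of model i within the candidate
set.

## Worked example

`examples/02_detect_denning.py` simulates a small two-region study and
runs the full detection chain for one pregnant female:

```
female S01 (south): monthly indicators around the birth

         core50_km2  total90_km2  displacement_km_day  residency_days
month
2011-09        4.25        20.22                 8.04            0.00
2011-10        2.08        14.91                 6.70            6.50
2011-11        0.04         6.91                 3.41           23.17
2011-12        4.21        19.78                 7.59           23.17

true birth month:      2011-11
top-ranked candidate:  2011-11 (score 6.26)
called birth, conception backdated to 2011-08
  displacement reduction: 53%
  longest residency:      23.2 days
```

In the birth month the core range contracts two orders of magnitude
(4 km² → 0.04 km²), daily travel halves, and a single residency spans
23 days; the detector ranks that month first, calls the birth, and
backdates conception to August — a wet-season-adjacent month, as the
seasonality analysis expects. The other examples cover the Akaike
tables (`01`), conception seasonality over a 600-female cohort (`03`),
and LoCoh isopleths with their MCP cross-check (`04`).

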