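# mastphen

Analysis toolkit for a question at the intersection of forest and bird
ecology: how does **masting** — the synchronous boom-and-bust seed
production of a conifer like Sitka spruce (*Picea sitchensis*) — drive the
**phenology, diet and demography** of a seed-specialist songbird, the
Eurasian siskin (*Spinus spinus*)?  The package is written for ringers and
quantitative ecologists who hold the typical raw materials of such a study:
mist-net capture records spanning many seasons, an annual 0–10 cone-crop
score, daily rainfall, fledgling-feather stable isotopes, and cone
dissection counts.

## What it computes

All cross-season inferences regress a season-level metric on the autumn
cone-crop score *c* by ordinary least squares, reported as slope, ANOVA
F(1, n−2), p and R².  The season metrics are:

* **Arrival** — first capture date, expressed as days after 31 Oct of the
  crop's ripening year (each season runs 1 Oct → 30 Sep).
* **Breeding onset** — the day of year *m* at which a logistic fit to
  brood-patch presence on adult females reaches P = 0.5, using only the
  ascending phase (≤ day 181, before post-breeding re-feathering).
* **Curve registration** ("knotted function analysis") — a pooled natural
  cubic spline *f(t)* is fit to a composition ratio vs day of year across
  all seasons (female share of sexed adults, or fledgling share of aged
  birds; sessions with < 15 valid birds or day > 220 excluded), and each
  season's rigid horizontal shift *s_y* = argmin Σᵢ (rᵢ − f(tᵢ − s))² is its
  earliness metric.
* **Rainfall response** — Pearson r of adult catch vs rainfall in the three
  preceding days, within each season's period of abundance, combined across
  seasons by an exact one-sided binomial sign test.
* **Diet** — feather δ¹⁵N/δ¹³C vs cone score; Welch t against other
  passerine fledglings; consistency with the pure-seed-diet prediction
  δ¹⁵N(feather) = δ¹⁵N(seed) + Δ_N with Δ_N ≈ 4 ‰.
* **Demography** — June–July fledgling proportion, adult abundance with a
  year covariate, monthly juvenile mass/wing vs cone score, and the
  carry-over test of first-year adult share vs the previous autumn's score.

A synthetic-study generator (`mastphen.simulate`) produces complete input
bundles with all of these structures injected at known parameter values, so
the full pipeline is testable end to end and its estimators can be checked
by parameter recovery.

## Worked example

`examples/arrival_from_published_table.py` regresses the bundled published
season summary (16 cone years of the Argyll study) and prints:

```
arrival ~ cone score: slope -5.56 d/point, F(1,14) = 7.18, p = 0.0180, R^2 = 0.339
rain-catch correlation positive in 13/16 seasons; exact one-sided sign test p = 0.01064
```

i.e. siskins return about 5–6 days earlier per cone-score point (the
printed dates are day-rounded summaries, so this sits near, not on, the
raw-data slope of −5.8), and catches rise after rain in 13 of 16 seasons —
far more often than a fair coin would allow.  The other example scripts
simulate a full study and recover the generator's slopes, demonstrate shift
registration, and walk through the isotope diet logic.

A thin CLI covers batch use:

```
mastphen simulate --seed 1 --out-dir data/
mastphen report --captures data/captures.csv --rainfall data/rainfall.csv \
    --cone-scores data/cone_scores.csv --isotopes data/isotopes.csv \
    --out-dir out/
```

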