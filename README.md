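# taxalag

How long does it take to describe a species after its first specimen is
collected?  `taxalag` turns type-series metadata — the collection dates of
the holotype and paratypes plus the publication date of the description —
into a reproducible analysis of the taxonomic "shelf life" of new species,
built around the kind of dataset assembled for recently described tropical
frogs (four regions, ~900 species described 2000–2023).

It is a library for biodiversity scientists and taxonomists who want the
whole chain — from messy verbatim date strings to mixed-model inference —
as tested, composable functions, with a synthetic-data generator so every
stage can be exercised (and its statistics calibrated) without any
external download.

## The quantities it computes

Each species' timeline is split into three periods (in years, day counts
divided by 365.25):

* **overall** — first type-specimen collection → publication,
* **collection** — first → last type-specimen collection,
* **description** (*sensu stricto*) — last collection → publication,

so `overall = collection + description` exactly.  Imprecise collection
dates ("5–7 December 2008", "February 2007", "1925") resolve to the floor
midpoint of their interval; same-day specimens count once; collection
events more than 30 days apart belong to different field trips.

On top of the lag table the package computes:

* the full distributional battery per region and period (min, mean, SD,
  10% trimmed mean, median, scaled MAD, max, range, skewness, excess
  kurtosis, SE, normal-theory 95% CI);
* month × year seasonality matrices and a 40%-of-peak evenness criterion;
* Gaussian mixed models for log description time,
  `log(description_y) ~ genetics + n_authors + n_types +
  n_species_in_paper + n_trips + genus_richness + (1|genus) + (1|region)`,
  fitted by maximum likelihood, with a 70% collinearity screen, Type-II
  Wald tests, a likelihood-ratio/AIC comparison against the
  random-effects-only null, and simulation-based scaled-residual
  diagnostics (uniformity, dispersion, outliers);
* yearly trend series for ten variables, each fitted by OLS-on-year and a
  penalized cubic-spline GAM with the better R² kept, plus a degree-2
  tricube LOESS smoother for presentation.

## Worked example

```python
from taxalag import GeneratorConfig, generate, lag_table, cumulative_within

records, truth = generate(GeneratorConfig(seed=1))
lag = lag_table(records)
print(len(lag), lag.overall_y.mean(), lag.overall_y.median())
```

Running `python examples/02_simulate_and_compute_lags.py` prints:

```
species: 896, unique collection dates: 4203
mean overall lag    :   9.35 y (median 6.83)
mean collection     :   2.32 y (median 0.14)
mean description    :   7.04 y (median 4.51)
described within 5 y: 36.2%   within 10 y: 68.1%
single field trip   : 54.6% of species
```

Medians far below the means are the signature of the right-skewed lag
distribution: most species are described within a few years of first
collection, while a long tail sits on museum shelves for decades.  The
other example scripts walk through date parsing (`01`), summary tables and
seasonality (`03`), the mixed model (`04`) and temporal trends (`05`).

Real data enter through `read_records` (CSV or XLSX, long or wide layout,
with an optional column-name mapping), which validates every row and logs
each excluded species with a single reason, so
`retained + excluded = input` always holds.  A thin CLI mirrors the
stages: `taxalag simulate`, `ingest`, `lags`, `summarize`, `model`,
`trends`, `run-all`.

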