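# lagturn

Tools for detecting **long-term change in short-term species turnover** in
community survey time series, together with a Lotka-Volterra community
simulator that explains how turnover can *slow down* even while the
environment changes faster.

`lagturn` is aimed at community ecologists working with BioTIME-shaped
presence/absence survey data — long tables of (study, community, year,
sample, species) records — who want a turnover measure that is robust to the
two classic nuisances of heterogeneous survey collections: variable sampling
effort and false-negative detections (pseudo-turnover).

## The method

Compositional similarity between two surveys is measured with the **Ochiai
index**

```
Ochiai = a / sqrt((a + b)(a + c))
```

where `a` is the number of species shared and `b`, `c` the numbers unique to
either survey. Sampling effort is equalised by *rarefaction*: every survey
year is repeatedly sub-sampled down to the series-wide minimum number of
within-year samples (100 sub-samples by default) and the index averaged.

The **turnover rate** of a community over a period is the (negated) OLS
slope of mean similarity against time lag, regressed over lags of 1-5 years.
Regressing over non-zero lags deliberately bypasses the large drop from
lag 0 (similarity 1 by construction) to lag 1, which is dominated by
detection failures that bias all non-zero lags about equally.

For a hypothesised **breakpoint year**, every community time series that
starts more than 5 years before and ends at least 5 years after it
contributes the difference `Δ = rate_since − rate_before`. The differences
are summarised by their median with a distribution-free **exact confidence
interval** from order statistics of the binomial(n, ½) distribution — the
inversion of the two-sided exact sign test, so a CI entirely below zero
means significantly more communities decelerated than accelerated. Scans
over a range of breakpoint years, per-taxon stratification, Sørensen/Jaccard
alternatives and longer lags are supported.

Two further components round out the package:

* `climate_filter` — the recursive delayed/smoothed transform
  `y_t = e^(−1/d) y_{t−1} + (1 − e^(−1/d)) x_t` of an annual
  global-temperature series, used to motivate candidate breakpoint years;
* `lv_sim` — a Lotka-Volterra competition model with a moving environmental
  optimum (shift rate `v`), a uniform growth-rate reduction (degradation
  `d`), and a minute propagule rain, whose simulated presence series are fed
  through *the same* turnover estimator; includes the full-factorial
  experiment and AIC-selected polynomial response surfaces.

A `synthetic_data` module generates survey ensembles with a known Markov
replacement process (and a closed-form expected-similarity oracle), so the
entire pipeline is testable without any database access.

## Worked example

Generate a 400-community ensemble (here trimmed to 100 communities) whose
true replacement rate drops by one third at 1975, and ask whether the
breakpoint analysis detects the slowdown:

```python
import lagturn as lt

cfg = lt.SyntheticConfig(n_communities=100, seed=7)   # rates 0.06 -> 0.04 at 1975
series, ledger = lt.generate_series(cfg)
summary = lt.analyze_breakyear(series, breakyear=1975)
```

This prints (via the fields of `summary`):

```
communities analysed : 100
median turnover change: -0.01452 per year
95% exact CI          : [-0.01730, -0.01269]
sign test p           : 3.21e-19
accelerated / decelerated: 8 / 92
true change (oracle)  : -0.01396 per year
```

The median change in turnover rate is negative (a deceleration), its exact
CI excludes zero, and the estimate brackets the generator's closed-form
truth of −0.01396 similarity-units per year.

The same pipeline is available from the shell:

```
lagturn synth --config cfg.yaml --out data/
lagturn ingest --input data/survey.csv --out work/
lagturn breakpoint-scan --input work/ --breakyears 1960:1990 --out scan.csv
lagturn simulate --reduced --seed 0 --out sim/
```

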