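# Methods

This note documents the statistical procedure, the simulation model, the
synthetic-data generator, and the numerical and design choices behind
`lagturn`. It states no empirical result beyond what the test suite and
`scripts/acceptance.py` themselves compute.

## Similarity and rarefaction

Surveys are compared on year-level presence/absence: species are pooled
across the within-year samples retained for a comparison. The Ochiai index
`a/sqrt((a+b)(a+c))` is the default because, for false-negative detection
rates below roughly 2/3 and slowly declining similarity, the coefficient of
variation of a between-lag similarity difference is smaller for Ochiai than
for Sørensen; the package checks this ordering by Monte Carlo
(`similarity.cv_robustness_mc`) on paired detection draws rather than by
computer algebra. Sørensen and Jaccard are available for robustness
analyses. Pairs with an empty species set on either side are undefined and
skipped, never scored 0.

Unequal effort is handled by rarefaction: the minimum number of samples `m`
over all survey years of a series is computed once, and each of 100
sub-samples retains exactly `m` uniformly chosen samples per year. When
every year already has `m` samples the sub-sampling is the identity and a
single exact evaluation is used, so the rarefaction-identity property holds
exactly, not just in expectation. Each community's rarefaction RNG is seeded
from a master seed mixed with a stable hash of the community id, making
results independent of processing order.

## Turnover rates and breakpoint comparison

The turnover rate over a period is the negated OLS slope of mean similarity
against lag over lags 1-5 (positive rate = declining similarity, units:
similarity per year). Lags with no available year pair are simply absent;
with fewer than two lag points the community is excluded, and the nominal
OLS slope SE is reported only with three or more points. The regression is
unweighted by pair counts (a weighted variant is a config flag) and always
estimates an intercept: detection failures scale every non-zero-lag
similarity by about the same factor, so pinning the intercept at the lag-0
value of 1 would contaminate the slope with pseudo-turnover.

On the pseudo-turnover bias more precisely: with year-level detection
probability `1 − f`, the expected observed Ochiai similarity at lag `l > 0`
is approximately `(1 − f)·s(l)`. The bias therefore loads almost entirely on
the intercept; the induced slope change is proportional to `f` times the
per-lag decline, second-order when similarity declines slowly. In the
regime where true composition is static the statement is exact: the fitted
slope stays zero in expectation while the intercept drops to `1 − f`. The
acceptance tests exercise exactly this regime.

For a breakpoint year `B`, a series is eligible if it starts strictly more
than `max_lag` years before `B` and ends at least `max_lag` years after.
The breakyear itself belongs to the "since" period (a convention; the
alternative is a flag), and year pairs straddling the split count toward
neither period, so each period's schedule reflects only within-period
dynamics. Rarefied pair similarities are computed once per community over
the full series and re-partitioned for every breakyear of a scan.
Communities whose since-minus-before difference is exactly zero (identical
discrete schedules, typically species-poor series with no recorded turnover)
are discarded and counted; the comparison is exact equality by default,
with an optional tolerance.

The median difference is reported with the distribution-free exact CI
`(x_(k), x_(n−k+1))`, where `k` is the largest integer with
`P(Bin(n, ½) ≤ k−1) ≤ (1−confidence)/2` — conservative, with at least
nominal coverage. When even `k = 1` would over-cover (n ≤ 5 at 95%), the
interval is reported as unbounded rather than pretending precision. This CI
and the two-sided exact sign test are inversions of the same binomial
statement, so "CI excludes zero" and "sign test rejects" coincide; the test
suite verifies this over every sign pattern up to n = 12 and verifies
coverage on 10,000 simulated samples.

## Data handling

Input surveys are long-format CSVs mapped onto canonical columns through a
configurable dialect (defaults follow BioTIME public export names). Records
from survey years before 1927 are dropped (the cutoff year itself is kept).
Studies whose coordinate bounding box exceeds 96 km² are split into local
communities on a locally projected fixed-size km grid (default 10 km,
spherical-Earth approximation) — a documented, simplified stand-in for more
elaborate published partitioning protocols, whose exact parameters are not
reproduced here. Presence means at least one record of the species in a
(year, sample); abundances are ignored.

## Synthetic-data generator

Each community holds exactly `R` of `P` pool species; every year each
resident is independently replaced with probability ρ (era-specific, the
change at the configured breakyear), the incoming species drawn uniformly
without replacement from the current absentees. Richness is constant by
construction, so the generator produces pure replacement with no nestedness
component, mirroring the weak richness trends the analysis assumes.
Observation adds within-year samples (a configurable count or range),
independent per-(species, sample) false negatives, and missing survey years
(removed after generation, so truth ledgers stay complete). The generator is
bit-reproducible from its seed, with per-community seed streams.

Because replacement keeps richness fixed, the marginal presence of a species
is an exact two-state Markov chain with stay probability `1 − ρ` and entry
probability `β = ρR/(P − R)`, giving the exact expected Ochiai (= Sørensen)
similarity at lag `l`:

```
E[s(l)] = π + (1 − π) (1 − ρ − β)^l,   π = R/P
```

This closed form is the oracle for estimator-recovery tests (cross-checked
against direct Monte Carlo). Jaccard is provided as a first-order plug-in
only, and detection noise is not part of the oracle.

Default conditions: 400 communities, survey years 1955-1995, breakyear 1975,
replacement rates 0.06 before and 0.04 since (a one-third slowdown, the
effect size the breakpoint analysis is designed to resolve), richness 40
from a pool of 160 (stationary occupancy ¼), one sample per year, no
detection failures or missing years unless a test exercises them. The
replacement rates are larger than typical empirical similarity-decline
slopes so that single-community estimates are resolvable over ~20-year
periods at this richness; the detection-power property is about the *ratio*
of rates, which matches the empirical effect size. What passing tests show
is therefore that the pipeline recovers known replacement dynamics of the
assumed form — not that real survey data satisfy those assumptions
(constant richness, era-wise-constant rates, independent detections).

## Climate filter

The delay filter is implemented in incremental form
`y_t = y_{t−1} + (1 − e^(−1/d))(x_t − y_{t−1})`, algebraically identical to
the textbook recursion but exactly fixed at a constant input in floating
point. Initialisation is unstated in the underlying method; the default
starts at the first observed value, with a "pre-mean" alternative (mean of
the first ⌈d⌉ values). Transients decay within a few multiples of `d`.

## Lotka-Volterra simulator

The model integrates, for `i = 1..S`,

```
dB_i/dt = B_i [ r_i f(x_i − E(t)) − d − Σ_j A_ij B_j ] + ε
```

with `f(u) = cos²(πu)` (periodic on the unit niche circle, so no boundary
effects; an optional width exponent `f^γ`, default γ = 1, narrows the
niche), growth rates `r_i ~ Normal(1, 0.25)` (untruncated — few negatives),
evenly spaced niches `x_i = i/S`, competition coefficients 0.4 with
probability 0.4 and 0 otherwise (diagonal 1), degradation `d` entering as a
uniform growth-rate reduction, and propagule rain `ε = 10⁻²⁰` permitting
re-invasion. The structural-instability threshold of this coefficient
ensemble, `(1 − m)²/s²` with `m = 0.16`, `s² = 0.0384`, is 18.375 species;
the reference pool is 80 times that, S = 1470.

Time scale of the environmental shift: the model text gives `v` a numeric
range (0-0.6) but no time unit. Here `E(t) = v·t/T₀` with `T₀ = 4000` unit
times — `v` is the total niche displacement over the nominal experiment
duration. This keeps the environmental shift slow relative to demographic
time scales (as in the empirical setting of decadal climate change versus
yearly surveys); had `v` been interpreted as niche units per sampled 'year',
compositions would decorrelate within a single lag at the upper end of the
range and the lag regression would saturate, destroying the monotone
`v`-response the experiment is designed to exhibit. The scale is exposed as
`env_period`.

Runs last 4000 unit times with a 400-unit burn-in; biomasses are sampled
every 25 unit times (one model 'year') and species with `B_i > 0.01` are
classified present. Initial biomasses are uniform in (0, 1] (unstated in
the source; transients are discarded by the burn-in). Integration uses
SciPy's adaptive stiff-capable LSODA with an analytic Jacobian, rtol 1e-6
and atol 1e-14; biomass is clamped at zero inside the RHS and in sampled
output, guarding against round-off below tolerance (the exact solution is
strictly positive because of ε). Note that atol effectively floors extinct
species above the 10⁻²⁰ propagule level, shortening re-invasion delays by
roughly a third relative to exact arithmetic; this affects timing, not the
direction of effects.

Simulated turnover is computed by exporting the presence series as a survey
time series and running the *identical* similarity/turnover code used for
field data (a code-path equality test enforces this). The full factorial
design is 20 degradation levels in [0, 0.5] × 20 shift-rate levels in
[0, 0.6] × 20 replicates = 8000 runs; replicate seeds derive from
(master, cell_i, cell_j, replicate) so any run can be recomputed in
isolation, and failed runs are recorded, not dropped. Response surfaces are
full bivariate polynomials of order 2-4 fitted by OLS to the same rows, with
the order selected by AIC.

In this reconstruction the deterministic dynamics settle into uninvadable
equilibria at `v = 0`, so baseline intrinsic turnover is near zero at the
scaled-down pool sizes tested (the perpetual intrinsic turnover of larger
assembly models is not reproduced at desk scale). The directional claims
are therefore tested statistically on Monte-Carlo output: turnover must
increase significantly with `v` at `d = 0` (one-sided rank correlation),
must show *no significant increase* with `d` at `v = 0` (rank correlation
plus a two-standard-error bound on the end-level means — the sound reading
of a "non-increasing" constraint on noisy simulation output), and must be
slower for smaller pools at fixed moderate shift. Directionality runs use
S = 245 species and 2000 unit times on a 4×4 grid with 5 replicates; these
sizes were chosen to make the factorial experiment routinely repeatable
while staying an order of magnitude above the structural-instability
threshold.

## Known limitations

- The grid partitioner is a simplified stand-in; it does not reproduce any
  specific published partitioning protocol.
- The expected-similarity oracle covers the noiseless replacement process;
  under detection noise it is first-order only.
- The exact CI is conservative (discrete coverage ≥ nominal), so breakpoint
  scans are slightly under-powered at very small n, and unbounded intervals
  are reported for n ≤ 5 at 95%.
- The simulator's niche width, `v` time scale and initial conditions are
  reconstructions of an incompletely specified model; all are exposed as
  configuration, and only directional (not numeric) surface properties are
  asserted.
- Empirical headline numbers from large survey databases are out of scope:
  nothing here downloads or reproduces BioTIME results.
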