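"""Survey-shaped synthetic ensembles with known turnover ground truth.

The generator emulates the statistical structure the empirical pipeline
assumes, without attempting realism: each community holds a constant number
of resident species drawn from a regional pool, and each year every resident
is independently replaced, with an era-specific probability, by a species
drawn uniformly from the pool members not currently resident (directionless
replacement, no nestedness component).  Observation adds the classic
nuisances: a configurable number of within-year samples, independent
per-(species, sample) false-negative detection failures (pseudo-turnover),
and randomly missing survey years.

Because replacement keeps richness fixed, the marginal presence of any single
species is an exact two-state Markov chain, which yields a closed-form
expected Ochiai similarity at every lag (:func:`expected_similarity_by_lag`)
— the oracle against which turnover-rate recovery is tested.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .biotime_io import CommunityTimeSeries
from .similarity import SimilaritySchedule
from .turnover import turnover_rate


@dataclass
class SyntheticConfig:
    """Ground-truth parameters of a synthetic survey ensemble.

    Replacement rates are per-year probabilities that a resident species is
    replaced; the era switches at ``breakyear`` (the breakyear itself uses the
    "after" rate).  The default "after" rate is two thirds of the "before"
    rate, a one-third slowdown of the kind the breakpoint analysis is meant
    to detect.
    """

    n_communities: int = 400
    years: tuple[int, int] = (1955, 1995)  # inclusive span of survey years
    breakyear: int = 1975
    replacement_rate_before: float = 0.06
    replacement_rate_after: float = 0.04
    pool_size: int = 160
    community_richness: int = 40
    false_negative_rate: float = 0.0
    samples_per_year: tuple[int, int] | int = 1  # inclusive range (or fixed count)
    missing_year_prob: float = 0.0
    taxon_labels: tuple[str, ...] = ("birds", "fish", "benthos", "all")
    n_studies: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        for rate in (self.replacement_rate_before, self.replacement_rate_after,
                     self.false_negative_rate, self.missing_year_prob):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.community_richness > self.pool_size:
            raise ValueError("community_richness must not exceed pool_size")

    def rate_for_year(self, year: int) -> float:
        return self.replacement_rate_after if year >= self.breakyear else self.replacement_rate_before


def _sample_range(cfg: SyntheticConfig) -> tuple[int, int]:
    s = cfg.samples_per_year
    return (s, s) if isinstance(s, int) else (int(s[0]), int(s[1]))


def _evolve_composition(cfg: SyntheticConfig, rng: np.random.Generator) -> dict[int, np.ndarray]:
    """True resident sets (arrays of pool indices) for every calendar year."""
    y0, y1 = cfg.years
    pool = np.arange(cfg.pool_size)
    residents = rng.choice(pool, size=cfg.community_richness, replace=False)
    comps = {y0: np.sort(residents)}
    present = np.zeros(cfg.pool_size, dtype=bool)
    present[residents] = True
    for year in range(y0 + 1, y1 + 1):
        rho = cfg.rate_for_year(year)
        residents = np.flatnonzero(present)
        leave = rng.random(residents.size) < rho
        k = int(leave.sum())
        if k:
            absent = np.flatnonzero(~present)
            incoming = rng.choice(absent, size=k, replace=False)
            present[residents[leave]] = False
            present[incoming] = True
        comps[year] = np.flatnonzero(present).copy()
    return comps


def generate_series(cfg: SyntheticConfig) -> tuple[list[CommunityTimeSeries], dict]:
    """Generate community time series plus a complete truth ledger.

    The ledger records, per community, the true yearly compositions (before
    missing-year thinning, so truth stays complete), the era replacement
    rates, and all record counts; the top level reconciles total record
    counts, including how many fall before the 1927 cutoff.
    """
    y0, y1 = cfg.years
    lo, hi = _sample_range(cfg)
    detect = 1.0 - cfg.false_negative_rate
    series_list: list[CommunityTimeSeries] = []
    ledger: dict = {
        "config": asdict(cfg),
        "n_records": 0,
        "n_pre_cutoff": 0,
        "communities": {},
    }
    for c in range(cfg.n_communities):
        rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), c]))
        cid = f"C{c:04d}"
        study = f"S{c % cfg.n_studies + 1:02d}"
        taxon = cfg.taxon_labels[c % len(cfg.taxon_labels)]
        comps = _evolve_composition(cfg, rng)
        observed_years = [
            y for y in range(y0, y1 + 1) if rng.random() >= cfg.missing_year_prob
        ]
        presence: dict[tuple[int, str], frozenset[str]] = {}
        n_records = 0
        for year in observed_years:
            true_set = comps[year]
            n_samples = int(rng.integers(lo, hi + 1)) if hi > lo else lo
            for s in range(n_samples):
                if detect >= 1.0:
                    seen = true_set
                else:
                    seen = true_set[rng.random(true_set.size) < detect]
                if seen.size == 0:
                    continue  # sample recorded nothing: it leaves no records
                presence[(year, f"smp{s + 1}")] = frozenset(f"sp{j:04d}" for j in seen)
                n_records += seen.size
        if not presence:
            continue  # community unobserved end to end (possible at extreme settings)
        series_list.append(
            CommunityTimeSeries(community_id=cid, presence=presence, taxon_group=taxon)
        )
        n_pre = sum(
            len(sp) for (year, _), sp in presence.items() if year < 1927
        )
        ledger["communities"][cid] = {
            "study_id": study,
            "taxon_group": taxon,
            "observed_years": observed_years,
            "n_records": n_records,
            "n_pre_cutoff": n_pre,
            "richness": cfg.community_richness,
            "true_rate_before": cfg.replacement_rate_before,
            "true_rate_after": cfg.replacement_rate_after,
            "true_compositions": {int(y): [f"sp{j:04d}" for j in comp] for y, comp in comps.items()},
        }
        ledger["n_records"] += n_records
        ledger["n_pre_cutoff"] += n_pre
    return series_list, ledger


def generate_ensemble(cfg: SyntheticConfig) -> tuple[pd.DataFrame, dict]:
    """Long-format survey records (canonical columns) plus the truth ledger.

    Each study gets a fixed random centroid and its communities scatter within
    a small box around it, so the default ensemble stays below the spatial
    partitioning threshold.
    """
    series_list, ledger = generate_series(cfg)
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 10**6]))
    study_centers = {
        f"S{k + 1:02d}": (float(rng.uniform(-55, 65)), float(rng.uniform(-170, 170)))
        for k in range(cfg.n_studies)
    }
    rows = []
    for series in series_list:
        meta = ledger["communities"][series.community_id]
        lat0, lon0 = study_centers[meta["study_id"]]
        lat = lat0 + float(rng.uniform(-0.01, 0.01))
        lon = lon0 + float(rng.uniform(-0.01, 0.01))
        meta["latitude"], meta["longitude"] = lat, lon
        for (year, sample), species in sorted(series.presence.items()):
            for sp in sorted(species):
                rows.append(
                    (meta["study_id"], series.community_id, year, sample, sp,
                     lat, lon, series.taxon_group)
                )
    df = pd.DataFrame(
        rows,
        columns=["study_id", "community_id", "year", "sample_id", "species_id",
                 "latitude", "longitude", "taxon_group"],
    )
    return df, ledger


def presence_markov_params(rho: float, richness: int, pool_size: int):
    """Exact per-species presence Markov chain under slot replacement.

    A resident stays with probability 1 - rho.  An absent species enters with
    probability E[replacements]/(pool - richness) = rho*R/(P - R), exact by
    linearity because the incoming species are drawn uniformly without
    replacement from the current absentees.  Returns (stationary presence
    probability pi, autocorrelation decay lambda per year).
    """
    if pool_size <= richness:
        raise ValueError("pool must exceed community richness")
    beta = rho * richness / (pool_size - richness)
    pi = richness / pool_size
    lam = 1.0 - rho - beta
    return pi, lam


def expected_similarity_by_lag(
    cfg: SyntheticConfig, lag: int, period: str = "before", index: str = "ochiai"
) -> float:
    """Closed-form expected similarity between true compositions ``lag`` years apart.

    With richness pinned at R on both sides, Ochiai and Sørensen both reduce
    to a/R, whose expectation is exactly pi + (1 - pi) * lambda**lag from the
    per-species Markov chain.  Jaccard is returned as the plug-in a/(2R - a)
    at the expected shared count (a first-order approximation).  Detection
    noise is not included: the oracle describes the noiseless replacement
    process.
    """
    if lag < 0:
        raise ValueError("lag must be >= 0")
    rho = cfg.replacement_rate_before if period == "before" else cfg.replacement_rate_after
    pi, lam = presence_markov_params(rho, cfg.community_richness, cfg.pool_size)
    s = pi + (1.0 - pi) * lam ** lag
    if index in ("ochiai", "sorensen"):
        return float(s)
    if index == "jaccard":
        r = cfg.community_richness
        return float(s * r / (2 * r - s * r))
    raise ValueError(f"no closed form for index {index!r}")


def expected_turnover_rate(
    cfg: SyntheticConfig, lags=range(1, 6), period: str = "before"
) -> float:
    """Turnover rate the estimator should recover: the same lag regression
    applied to the exact expected similarities."""
    sched = SimilaritySchedule(
        means={l: expected_similarity_by_lag(cfg, l, period=period) for l in lags},
        npairs={l: 1 for l in lags},
    )
    est = turnover_rate(sched, lags=lags)
    assert est is not None
    return est.rate
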