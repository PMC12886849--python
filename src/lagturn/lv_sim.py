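"""Lotka-Volterra community model of species turnover under environmental change.

A pool of S competing species with evenly spaced preferred niche positions
x_i on the unit circle follows

    dB_i/dt = B_i * [ r_i * f(x_i - E(t)) - d - sum_j A_ij B_j ] + epsilon

where f(u) = cos^2(pi*u) is a periodic niche-suitability profile (a squared
sinusoid is used to avoid boundary effects at x = 0, 1), E(t) is the moving
environmental optimum, ``d`` is a uniform environmental degradation that
depresses all intrinsic growth rates equally, and a minute propagule rain
``epsilon`` keeps re-invasion possible after effective local extinction.
Intrinsic growth rates r_i are Gaussian with mean 1 and standard deviation
0.25; interspecific competition coefficients are 0.4 with probability 0.4 and
0 otherwise, intraspecific coefficients are 1.

Presence/absence 'surveys' are read off the trajectory every 25 unit times
(one model 'year') after a 400-unit burn-in, classifying species with biomass
above 0.01 as present, and the turnover rate of a run is computed with the
very same lag-regression machinery used for empirical data.

The species richness at which such a random competition community becomes
ecologically structurally unstable is S_ESI = (1 - m)^2 / s^2 with m, s^2 the
mean and variance of the off-diagonal competition coefficients; for the
ensemble above S_ESI = 18.375, and the reference pool size is 80 * S_ESI =
1470 species.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .biotime_io import CommunityTimeSeries
from .similarity import mean_similarity_by_lag, rarefied_pair_similarities
from .turnover import DEFAULT_LAGS, TurnoverEstimate, turnover_rate

#: off-diagonal competition ensemble: value 0.4 with probability 0.4, else 0
A_VALUE = 0.4
A_PROB = 0.4


def competition_moments(value: float = A_VALUE, prob: float = A_PROB) -> tuple[float, float]:
    """Mean and variance of off-diagonal coefficients drawn as value*Bernoulli(prob)."""
    mean = prob * value
    var = prob * (1.0 - prob) * value**2
    return mean, var


def s_esi(mean_offdiag: float, var_offdiag: float) -> float:
    """Ecological structural-instability richness threshold (1 - m)^2 / s^2."""
    if var_offdiag <= 0:
        raise ValueError("off-diagonal variance must be positive")
    if mean_offdiag >= 1:
        raise ValueError("mean off-diagonal competition must be below 1")
    return (1.0 - mean_offdiag) ** 2 / var_offdiag


@dataclass
class LVParams:
    """Full parameterisation of one model run."""

    S: int
    r: np.ndarray  # intrinsic growth rates, mean 1 sd 0.25
    x: np.ndarray  # preferred niches, evenly spaced in [0, 1)
    A: np.ndarray  # competition matrix, diag 1, off-diag in {0, 0.4}
    d: float = 0.0  # environmental degradation (uniform growth-rate reduction)
    v: float = 0.0  # environmental rate of change (niche units per env_period)
    epsilon: float = 1e-20
    t_total: float = 4000.0
    t_burnin: float = 400.0
    dt_sample: float = 25.0  # one model 'year'
    presence_threshold: float = 0.01
    env_period: float = 4000.0  # time over which E advances by v
    niche_exponent: float = 1.0
    b0: np.ndarray | None = None  # initial biomasses; uniform (0, 1] if None
    seed: int | tuple = 0


def sample_params(S: int, seed=0, d: float = 0.0, v: float = 0.0, **overrides) -> LVParams:
    """Draw one random parameterisation of the S-species community."""
    if S < 1:
        raise ValueError("S must be >= 1")
    seq = np.random.SeedSequence([seed] if isinstance(seed, int) else list(seed))
    rng = np.random.default_rng(seq)
    r = rng.normal(1.0, 0.25, size=S)  # untruncated: few negatives by design
    x = np.arange(S) / S
    A = np.where(rng.random((S, S)) < A_PROB, A_VALUE, 0.0)
    np.fill_diagonal(A, 1.0)
    b0 = 1.0 - rng.random(S)  # uniform in (0, 1]
    return LVParams(S=S, r=r, x=x, A=A, d=d, v=v, b0=b0, seed=seed, **overrides)


def suitability(x, E, exponent: float = 1.0):
    """Periodic niche suitability cos^2(pi*(x - E)), peak 1 at x = E."""
    f = np.cos(np.pi * (np.asarray(x) - E)) ** 2
    return f if exponent == 1.0 else f**exponent


@dataclass
class LVTrajectory:
    """Sampled biomasses and derived presence series of one run."""

    params: LVParams
    times: np.ndarray  # sample times (after burn-in)
    biomass: np.ndarray  # shape (n_years, S), nonnegative

    @property
    def presence_sets(self) -> list[frozenset[int]]:
        thr = self.params.presence_threshold
        return [frozenset(np.flatnonzero(row > thr).tolist()) for row in self.biomass]

    def to_series(self, community_id: str = "lv-run") -> CommunityTimeSeries | None:
        """Export as a survey time series: one sample per 'year', presence by
        biomass threshold.  Years with no species above threshold become gap
        years.  Returns None if every year is empty."""
        presence = {}
        for year, species in enumerate(self.presence_sets):
            if species:
                presence[(year, "smp1")] = frozenset(f"sp{i:04d}" for i in species)
        if not presence:
            return None
        return CommunityTimeSeries(community_id=community_id, presence=presence)


def integrate(params: LVParams, method: str = "LSODA", rtol: float = 1e-6,
              atol: float = 1e-14) -> LVTrajectory:
    """Integrate the model and sample yearly biomasses after burn-in.

    An adaptive stiff-capable solver is used; biomasses are clamped at zero
    inside the right-hand side and in the sampled output (the propagule rain
    keeps the exact solution strictly positive, clamping only guards against
    solver round-off below the absolute tolerance).
    """
    p = params
    r, x, A = p.r, p.x, p.A
    scale = p.v / p.env_period

    def env(t):
        return scale * t

    def rhs(t, B):
        Bp = np.maximum(B, 0.0)
        f = suitability(x, env(t), p.niche_exponent)
        return Bp * (r * f - p.d - A @ Bp) + p.epsilon

    def jac(t, B):
        Bp = np.maximum(B, 0.0)
        f = suitability(x, env(t), p.niche_exponent)
        g = r * f - p.d - A @ Bp
        return np.diag(g) - Bp[:, None] * A

    b0 = p.b0 if p.b0 is not None else np.full(p.S, 0.5)
    t_eval = np.arange(p.t_burnin + p.dt_sample, p.t_total + 0.5 * p.dt_sample, p.dt_sample)
    kwargs = {"jac": jac} if method in ("LSODA", "BDF", "Radau") else {}
    sol = solve_ivp(
        rhs, (0.0, p.t_total), np.asarray(b0, dtype=float), method=method,
        t_eval=t_eval, rtol=rtol, atol=atol, **kwargs,
    )
    if not sol.success:
        raise RuntimeError(
            f"integration failed (S={p.S}, d={p.d}, v={p.v}): {sol.message}"
        )
    return LVTrajectory(params=p, times=sol.t, biomass=np.maximum(sol.y.T, 0.0))


def sim_turnover(trajectory: LVTrajectory, lags=DEFAULT_LAGS, index: str = "ochiai") -> TurnoverEstimate | None:
    """Turnover rate of a simulated run, via the empirical-data machinery.

    The trajectory's presence series is exported as a survey time series and
    pushed through the same similarity-schedule and lag-regression code used
    for field data; no separate implementation exists.
    """
    series = trajectory.to_series()
    if series is None:
        return None
    max_lag = max(lags)
    pair_sims = rarefied_pair_similarities(series, index=index, max_lag=max_lag)
    schedule = mean_similarity_by_lag(pair_sims, max_lag=max_lag)
    return turnover_rate(schedule, lags=lags)


def factorial_plan(
    d_steps: int = 20, v_steps: int = 20, replicates: int = 20,
    d_max: float = 0.5, v_max: float = 0.6,
) -> pd.DataFrame:
    """Enumerate the full-factorial design (one row per model run, no integration).

    The reference design varies degradation d over 20 steps in [0, 0.5] and
    shift rate v over 20 steps in [0, 0.6] with 20-fold replication: 8000 runs.
    """
    d_grid = np.linspace(0.0, d_max, d_steps)
    v_grid = np.linspace(0.0, v_max, v_steps)
    rows = [
        dict(cell_i=i, cell_j=j, replicate=k, d=float(dv), v=float(vv))
        for (i, dv), (j, vv), k in itertools.product(
            enumerate(d_grid), enumerate(v_grid), range(replicates)
        )
    ]
    return pd.DataFrame(rows)


def factorial_experiment(
    S: int,
    plan: pd.DataFrame | None = None,
    seed: int = 0,
    lags=DEFAULT_LAGS,
    index: str = "ochiai",
    **param_overrides,
) -> pd.DataFrame:
    """Run the factorial design and attach the turnover rate of every run.

    Replicate k of grid cell (i, j) derives its seed as (master, i, j, k), so
    any single run can be recomputed in isolation.  Failed runs are recorded
    with a NaN rate and the error message, never silently dropped.
    """
    plan = factorial_plan() if plan is None else plan.copy()
    rates, errors = [], []
    for row in plan.itertuples(index=False):
        run_seed = (int(seed), int(row.cell_i), int(row.cell_j), int(row.replicate))
        try:
            params = sample_params(S, seed=run_seed, d=row.d, v=row.v, **param_overrides)
            est = sim_turnover(integrate(params), lags=lags, index=index)
            rates.append(est.rate if est is not None else np.nan)
            errors.append("" if est is not None else "insufficient lags")
        except RuntimeError as exc:  # integrator failure: keep the row
            rates.append(np.nan)
            errors.append(str(exc))
    plan["turnover_rate"] = rates
    plan["error"] = errors
    return plan


@dataclass
class SurfaceFit:
    """Full bivariate polynomial response surface in (d, v)."""

    order: int
    coefficients: dict[str, float]
    aic: float
    nobs: int


def _design(d, v, order: int):
    names, cols = [], []
    for total in range(order + 1):
        for i in range(total + 1):
            j = total - i
            names.append(f"d^{i} v^{j}")
            cols.append(d**i * v**j)
    return names, np.column_stack(cols)


def fit_surface(table: pd.DataFrame, orders=(2, 3, 4)) -> tuple[dict[int, SurfaceFit], int]:
    """Least-squares polynomial surfaces of turnover rate over (d, v) with AIC.

    Fits a full bivariate polynomial of each order to the same rows (NaN rates
    dropped once for all orders, keeping the AICs comparable) and selects the
    order with minimum AIC.
    """
    import statsmodels.api as sm

    data = table.dropna(subset=["turnover_rate"])
    d = data["d"].to_numpy(float)
    v = data["v"].to_numpy(float)
    y = data["turnover_rate"].to_numpy(float)
    fits: dict[int, SurfaceFit] = {}
    for order in orders:
        names, X = _design(d, v, order)
        if len(y) < X.shape[1]:
            raise ValueError(f"too few rows ({len(y)}) for order-{order} surface")
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError(f"rank-deficient design for order-{order} surface")
        res = sm.OLS(y, X).fit()
        fits[order] = SurfaceFit(
            order=order,
            coefficients=dict(zip(names, map(float, res.params))),
            aic=float(res.aic),
            nobs=int(res.nobs),
        )
    selected = min(fits, key=lambda o: fits[o].aic)
    return fits, selected
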