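"""Schaefer surplus-production simulator with a single regime change.

Biomass follows the discrete logistic (Schaefer) recursion

    B_t = B_{t-1} + r_i B_{t-1} (1 - B_{t-1}/K) - C_{t-1},

with yearly catch C_t = q_i B_t E_t exp(eps_t), effort E_t ~ Poisson(lambda)
in metres of net, and lognormal catch noise eps_t with standard deviation
sqrt(catch_noise_var).  Analyzed years are labelled 1..T; the growth rate
and catchability switch from (r1, q1) to (r2, q2) after ``change_year``
(year ``change_year`` is the last year of the first regime).  A
stabilization burn-in run under (r1, q1) precedes the analyzed horizon so
the population starts near its harvested equilibrium; the analyzed series'
initial biomass is the final burn-in biomass and the clock restarts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "PopulationParameters",
    "SimulatedSeries",
    "R1_SET",
    "R2_SET",
    "Q1_SET",
    "Q2_SET",
    "sample_parameters",
    "simulate_series",
    "read_series_csv",
    "write_series_csv",
]

# Finite design sets the generative parameters are drawn from.
R1_SET = (0.55, 0.60, 0.65, 0.70, 0.75, 0.80, 0.85, 0.90)
R2_SET = (0.20, 0.25, 0.30, 0.35, 0.40, 0.45, 0.50, 0.55)
Q1_SET = (1.0e-5, 1.5e-5, 2.0e-5, 2.5e-5)
Q2_SET = (2.0e-5, 2.5e-5, 3.0e-5)


@dataclass(frozen=True)
class PopulationParameters:
    """True generative parameters of one simulated population.

    r1/r2 are yearly intrinsic growth rates before/after the change,
    q1/q2 the catchability coefficients (per metre of net), K the carrying
    capacity and B0 the initial biomass (both in biomass units).
    ``change_year`` is the last analyzed year (1-based label) governed by
    the first regime; the second regime starts the following year.
    """

    r1: float
    r2: float
    q1: float
    q2: float
    K: float = 2_000_000.0
    B0: float = 1_500_000.0
    change_year: int = 32
    effort_mean: float = 10_000.0
    catch_noise_var: float = 0.01
    stabilization_years: int = 32

    def __post_init__(self) -> None:
        if not (self.r1 >= self.r2 > 0):
            raise ValueError(f"need r1 >= r2 > 0, got r1={self.r1}, r2={self.r2}")
        if self.q1 <= 0 or self.q2 <= 0:
            raise ValueError("catchabilities must be positive")
        if self.K <= 0 or not (0 < self.B0 <= self.K):
            raise ValueError("need K > 0 and 0 < B0 <= K")
        if self.effort_mean <= 0:
            raise ValueError("effort_mean must be positive")
        if self.catch_noise_var < 0:
            raise ValueError("catch_noise_var must be nonnegative")
        if self.change_year != int(self.change_year) or self.change_year <= 0:
            raise ValueError("change_year must be a positive integer")

    @property
    def delta_r(self) -> float:
        return self.r1 - self.r2

    @property
    def delta_q(self) -> float:
        return self.q1 - self.q2

    def replace(self, **kwargs) -> "PopulationParameters":
        return replace(self, **kwargs)


@dataclass
class SimulatedSeries:
    """Yearly biomass, effort, catch and CPUE for the analyzed horizon."""

    year: np.ndarray
    biomass: np.ndarray
    effort: np.ndarray
    catch: np.ndarray
    cpue: np.ndarray
    params: PopulationParameters | None = None
    #: burn-in segment (same columns), kept for diagnostics only
    stabilization: pd.DataFrame | None = None
    #: number of years where catch hit the positivity clamp
    n_clamped: int = 0

    def __len__(self) -> int:
        return len(self.year)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "year": self.year,
                "biomass": self.biomass,
                "effort": self.effort,
                "catch": self.catch,
                "cpue": self.cpue,
            }
        )

    def to_csv(self, path) -> None:
        write_series_csv(self, path)


def sample_parameters(rng: np.random.Generator, **overrides) -> PopulationParameters:
    """Draw one parameter set uniformly from the finite design sets.

    r1 ~ U{0.55..0.90 by .05}, r2 ~ U{0.20..0.55 by .05},
    q1 ~ U{1.0, 1.5, 2.0, 2.5}e-5, q2 ~ U{2.0, 2.5, 3.0}e-5; the set
    construction guarantees r1 >= r2.  K, B0, effort mean, noise variance
    and change year keep their defaults unless overridden.
    """
    draws = dict(
        r1=float(rng.choice(R1_SET)),
        r2=float(rng.choice(R2_SET)),
        q1=float(rng.choice(Q1_SET)),
        q2=float(rng.choice(Q2_SET)),
    )
    draws.update(overrides)
    return PopulationParameters(**draws)


def _regime_arrays(params: PopulationParameters, n_years: int):
    """(r_t, q_t) over burn-in + analyzed horizon; regime 2 starts the year
    after analyzed year ``change_year`` (array position ``change_year``)."""
    total = params.stabilization_years + n_years
    switch = params.stabilization_years + params.change_year
    r = np.where(np.arange(total) < switch, params.r1, params.r2)
    q = np.where(np.arange(total) < switch, params.q1, params.q2)
    return r, q


def simulate_series(
    params: PopulationParameters,
    rng: np.random.Generator,
    n_years: int = 64,
    effort: np.ndarray | None = None,
    keep_stabilization: bool = False,
) -> SimulatedSeries:
    """Simulate one population/catch/effort/CPUE trajectory.

    Within each year the order of operations is: biomass updates from last
    year's biomass and catch; effort is drawn Poisson(effort_mean); catch is
    q_i * B_t * E_t * exp(eps_t); CPUE = catch/effort.  If a realized catch
    would drive next year's biomass to zero or below it is truncated to 99%
    of the maximum sustainable removal for that year (counted in
    ``n_clamped``).  Only the ``n_years`` analyzed years are returned unless
    ``keep_stabilization`` is set.

    ``effort`` may be a length ``stabilization_years + n_years`` array to
    override the Poisson draws (used for deterministic checks).
    """
    if params.change_year >= n_years:
        raise ValueError("change_year must lie inside the analyzed horizon")
    total = params.stabilization_years + n_years
    r_t, q_t = _regime_arrays(params, n_years)
    if effort is None:
        eff = rng.poisson(params.effort_mean, size=total).astype(float)
    else:
        eff = np.asarray(effort, dtype=float)
        if eff.shape != (total,) or (eff < 0).any():
            raise ValueError("effort override must be nonnegative with one value per year")
    sd = float(np.sqrt(params.catch_noise_var))
    eps = rng.normal(0.0, 1.0, size=total) * sd if sd > 0 else np.zeros(total)

    B = np.empty(total)
    C = np.empty(total)
    n_clamped = 0
    b = params.B0
    K = params.K
    for t in range(total):
        if t > 0:
            b = b + r_t[t] * b * (1.0 - b / K) - C[t - 1]
        if not np.isfinite(b) or b <= 0:
            raise FloatingPointError(
                f"biomass left the positive domain at year {t} (B={b!r}); "
                "check growth-rate/catch configuration"
            )
        B[t] = b
        c = q_t[t] * b * eff[t] * np.exp(eps[t])
        # positivity clamp: next year's surplus production must exceed removals
        r_next = r_t[min(t + 1, total - 1)]
        c_max = b + r_next * b * (1.0 - b / K)
        if c >= c_max:
            c = 0.99 * c_max
            n_clamped += 1
        C[t] = c

    with np.errstate(divide="ignore", invalid="ignore"):
        cpue = np.where(eff > 0, C / np.maximum(eff, 1.0), np.nan)
        cpue[eff == 0] = np.nan

    s = params.stabilization_years
    stab = None
    if keep_stabilization:
        stab = pd.DataFrame(
            {
                "year": np.arange(-s + 1, 1),
                "biomass": B[:s],
                "effort": eff[:s],
                "catch": C[:s],
                "cpue": cpue[:s],
            }
        )
    return SimulatedSeries(
        year=np.arange(1, n_years + 1),
        biomass=B[s:],
        effort=eff[s:],
        catch=C[s:],
        cpue=cpue[s:],
        params=params,
        stabilization=stab,
        n_clamped=n_clamped,
    )


def write_series_csv(series: SimulatedSeries, path) -> None:
    series.to_frame().to_csv(path, index=False)


def read_series_csv(path) -> pd.DataFrame:
    """Read a yearly series CSV (year, [biomass], effort, catch, cpue).

    The biomass column is optional (observed data never has it); cpue is
    recomputed as catch/effort when absent.
    """
    df = pd.read_csv(path)
    required = {"year", "effort", "catch"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"series CSV missing columns: {sorted(missing)}")
    if "cpue" not in df.columns:
        with np.errstate(divide="ignore", invalid="ignore"):
            df["cpue"] = df["catch"] / df["effort"]
    df.loc[df["effort"] <= 0, "cpue"] = np.nan
    return df
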