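"""Gompertz-Makeham and constant-hazard mortality models.

The Gompertz-Makeham law puts the per-day hazard at age t (measured here on
the post-maturity clock) at

    h(t) = alpha * exp(beta * t) + gamma

where alpha scales the intrinsic (Gompertzian) component, beta is the
rate-of-aging (ln 2 / beta is the hazard doubling time) and gamma is a
constant extrinsic (Makeham) floor.  With beta = 0 or alpha = 0 the law
degenerates to a constant hazard, under which lifespan decays exponentially
and the natural summary is a demographic half-life, ln 2 / lambda, rather
than a maximal lifespan.

Maximum-likelihood fitting uses the continuous survival function with right
censoring.  Life tables (deaths and at-risk per age interval) from other
species are ingested for cross-species comparison, with survival rebuilt by
iterative multiplication of the per-interval survival fractions starting at
each species' age of reproductive maturity (T_sex); hazard trajectories can
be re-scaled onto a T_sex-multiples age axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .records_io import Event, LifespanObservation
from .survival_hazard import LifespanSummary, lifespan_summary, wilson_interval

DAYS_PER_YEAR = 365.25

_EXP_GUARD = 700.0  # beyond this, exp overflows double precision


@dataclass(frozen=True)
class GompertzParams:
    """Parameters of h(t) = alpha*exp(beta*t) + gamma, all per-day."""

    alpha: float
    beta: float
    gamma: float = 0.0

    def __post_init__(self):
        if self.alpha < 0 or self.gamma < 0:
            raise ValueError("alpha and gamma must be non-negative")

    @property
    def is_constant(self) -> bool:
        return self.alpha == 0.0 or self.beta == 0.0

    @property
    def doubling_time(self) -> float:
        """Hazard doubling time in days (inf for non-aging hazards)."""
        if self.beta <= 0 or self.alpha == 0:
            return math.inf
        return math.log(2.0) / self.beta


def hazard_at(params: GompertzParams, t) -> np.ndarray:
    """Evaluate the Gompertz-Makeham hazard at age(s) t >= 0 (days)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    bt = params.beta * t
    if np.any(bt > _EXP_GUARD):
        raise OverflowError("beta * t too large: hazard would overflow")
    return params.alpha * np.exp(bt) + params.gamma


def cumulative_hazard(params: GompertzParams, t) -> np.ndarray:
    """Integrated hazard H(t) = alpha/beta*(exp(beta t)-1) + gamma t."""
    t = np.asarray(t, dtype=float)
    bt = params.beta * t
    if np.any(bt > _EXP_GUARD):
        raise OverflowError("beta * t too large")
    if params.beta == 0.0:
        gomp = params.alpha * t
    else:
        gomp = params.alpha * np.expm1(bt) / params.beta
    return gomp + params.gamma * t


def constant_hazard_survival(
    lam: float, from_day: float, to_day: float,
    form: Literal["geometric", "continuous"] = "geometric",
) -> float:
    """Survival probability over [from_day, to_day] at constant per-day hazard.

    The default geometric form multiplies (1 - lam) once per day, matching a
    daily-Bernoulli death process; the continuous form is exp(-lam * dt).
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lam must be in [0, 1]")
    dt = to_day - from_day
    if dt < 0:
        raise ValueError("to_day must be >= from_day")
    if form == "geometric":
        return float((1.0 - lam) ** dt)
    if form == "continuous":
        return float(math.exp(-lam * dt))
    raise ValueError(f"unknown form {form!r}")


def constant_hazard_median(
    lam: float, form: Literal["continuous", "geometric"] = "continuous"
) -> float:
    """Demographic half-life (median lifespan) under constant hazard.

    Continuous form ln(2)/lam (the default, and what is reported throughout);
    geometric form ln(0.5)/ln(1-lam), the median of the daily-Bernoulli
    process.  lam = 0 gives +inf.
    """
    if lam < 0 or lam > 1:
        raise ValueError("lam must be in [0, 1]")
    if lam == 0.0:
        return math.inf
    if form == "continuous":
        return math.log(2.0) / lam
    if form == "geometric":
        if lam == 1.0:
            return 1.0
        return math.log(0.5) / math.log1p(-lam)
    raise ValueError(f"unknown form {form!r}")


@dataclass
class MortalityFit:
    """Result of a maximum-likelihood mortality-model fit."""

    model: str
    params: GompertzParams
    log_likelihood: float
    n: int
    n_deaths: int
    converged: bool
    beta_near_zero: bool = False  # |beta| within numerical tolerance of 0
    message: str = ""


def _durations(observations: Sequence[LifespanObservation]) -> tuple[np.ndarray, np.ndarray]:
    t = np.array([o.exit_day - o.entry_day for o in observations], dtype=float)
    died = np.array([o.event is Event.DEATH for o in observations])
    return t, died


def _gm_loglik(t: np.ndarray, died: np.ndarray, p: GompertzParams) -> float:
    H = cumulative_hazard(p, t)
    h = hazard_at(p, t[died])
    if np.any(h <= 0):
        return -np.inf
    return float(np.sum(np.log(h)) - np.sum(H))


def fit_mortality_model(
    observations: Sequence[LifespanObservation],
    model: Literal["constant", "gompertz", "gompertz_makeham"] = "constant",
    beta_zero_tol: float = 1e-8,
) -> MortalityFit:
    """Censoring-aware maximum-likelihood fit on the post-entry clock.

    ``constant`` has the analytic MLE lambda = deaths / total observed days.
    ``gompertz`` fits (alpha, beta) with gamma = 0; ``gompertz_makeham`` fits
    all three with alpha, gamma >= 0.  The log-likelihood supports nested
    likelihood-ratio comparison.  Raises when the data contain no deaths.
    """
    t, died = _durations(observations)
    D = int(died.sum())
    if D == 0:
        raise ValueError("cannot fit a mortality model with zero deaths")
    total_days = float(t.sum())
    if total_days <= 0:
        # all events at entry: degenerate, but constant MLE is still defined
        raise ValueError("zero total observation time")

    lam_hat = D / total_days
    ll_const = _gm_loglik(t, died, GompertzParams(alpha=lam_hat, beta=0.0))
    if model == "constant":
        return MortalityFit("constant", GompertzParams(lam_hat, 0.0, 0.0),
                            ll_const, len(t), D, True, beta_near_zero=True)

    def neg_ll(x: np.ndarray) -> float:
        if model == "gompertz":
            p = GompertzParams(alpha=math.exp(x[0]), beta=x[1], gamma=0.0)
        else:
            p = GompertzParams(alpha=math.exp(x[0]), beta=x[1], gamma=math.exp(x[2]))
        try:
            return -_gm_loglik(t, died, p)
        except OverflowError:
            return np.inf

    t_max = max(float(t.max()), 1.0)
    beta_bounds = (-_EXP_GUARD / t_max * 0.5, _EXP_GUARD / t_max * 0.5)
    starts = []
    for beta0 in (1e-6, 1e-3, 5e-3):
        if model == "gompertz":
            starts.append([math.log(lam_hat), beta0])
        else:
            starts.append([math.log(lam_hat / 2), beta0, math.log(lam_hat / 2)])
    bounds = [(-60, 0), beta_bounds] + ([(-60, 0)] if model == "gompertz_makeham" else [])

    best = None
    for x0 in starts:
        res = minimize(neg_ll, x0, method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    assert best is not None
    if model == "gompertz":
        p = GompertzParams(math.exp(best.x[0]), float(best.x[1]), 0.0)
    else:
        p = GompertzParams(math.exp(best.x[0]), float(best.x[1]), math.exp(best.x[2]))
    return MortalityFit(
        model, p, -float(best.fun), len(t), D, bool(best.success),
        beta_near_zero=abs(p.beta) < beta_zero_tol,
        message=str(best.message),
    )


def likelihood_ratio(null_fit: MortalityFit, alt_fit: MortalityFit) -> float:
    """2 * (ll_alt - ll_null); non-negative for correctly nested fits."""
    return 2.0 * (alt_fit.log_likelihood - null_fit.log_likelihood)


def sample_gompertz_lifetimes(
    params: GompertzParams, n: int, rng: np.random.Generator,
    censor_at: Optional[float] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw continuous lifetimes (post-entry days) from a Gompertz-Makeham law.

    Uses inverse-CDF sampling of the Gompertz component plus an independent
    exponential Makeham component (hazards add, so the minimum of the two is
    exact).  Returns (durations, died) with administrative censoring at
    *censor_at* when given.
    """
    u = rng.random(n)
    if params.alpha == 0.0:
        t_g = np.full(n, np.inf)
    elif params.beta == 0.0:
        t_g = -np.log1p(-u) / params.alpha
    else:
        # H(t) = alpha/beta * (exp(beta t) - 1) = -ln(1-u)
        t_g = np.log1p(-params.beta * np.log1p(-u) / params.alpha) / params.beta
    if params.gamma > 0:
        t_m = rng.exponential(1.0 / params.gamma, size=n)
        t = np.minimum(t_g, t_m)
    else:
        t = t_g
    died = np.ones(n, dtype=bool)
    if censor_at is not None:
        died = t < censor_at
        t = np.minimum(t, censor_at)
    return t, died


# ---------------------------------------------------------------------------
# Life tables and cross-species comparison


@dataclass
class SpeciesConfig:
    """Species name, age of reproductive maturity, and its time unit."""

    name: str
    t_sex: float
    unit: Literal["days", "years"] = "days"

    def __post_init__(self):
        if self.t_sex <= 0:
            raise ValueError("t_sex must be positive")

    @property
    def t_sex_days(self) -> float:
        return self.t_sex if self.unit == "days" else self.t_sex * DAYS_PER_YEAR


#: Reproductive-maturity ages used for cross-species hazard comparison.
SPECIES = {
    "naked_mole_rat": SpeciesConfig("naked_mole_rat", 183, "days"),
    "mouse": SpeciesConfig("mouse", 42, "days"),
    "human_female": SpeciesConfig("human_female", 16, "years"),
    "horse": SpeciesConfig("horse", 3, "years"),
}


@dataclass
class LifeTable:
    """Per-age-interval death counts / at-risk counts and derived hazard.

    ``table`` columns: age_start, age_end (in ``unit``), plus either
    deaths & at_risk (hazard derived) or a precomputed hazard column.
    """

    table: pd.DataFrame
    unit: Literal["days", "years"] = "years"

    def __post_init__(self):
        df = self.table
        required = {"age_start", "age_end"}
        if not required.issubset(df.columns):
            raise ValueError("life table needs age_start and age_end columns")
        if "hazard" not in df.columns:
            if not {"deaths", "at_risk"}.issubset(df.columns):
                raise ValueError("life table needs hazard or deaths+at_risk columns")
            with np.errstate(invalid="ignore", divide="ignore"):
                df = df.assign(hazard=df["deaths"] / df["at_risk"])
            self.table = df
        h = df["hazard"].to_numpy(dtype=float)
        if np.any((h < 0) | (h > 1)):
            raise ValueError("per-interval hazard must lie in [0, 1]")
        starts = df["age_start"].to_numpy(dtype=float)
        ends = df["age_end"].to_numpy(dtype=float)
        if np.any(ends <= starts) or np.any(np.diff(starts) <= 0):
            raise ValueError("intervals must be ordered and non-degenerate")
        if np.any(starts[1:] != ends[:-1]):
            raise ValueError("intervals must be contiguous")

    @property
    def hazard(self) -> np.ndarray:
        return self.table["hazard"].to_numpy(dtype=float)


def life_table_hazard(
    sources: Union[str, Path, pd.DataFrame, Iterable[Union[str, Path, pd.DataFrame]]],
    combine: bool = False,
    unit: Literal["days", "years"] = "years",
) -> LifeTable:
    """Build a LifeTable from CSV path(s) or DataFrame(s).

    With ``combine``, tables are pooled by summing deaths and at-risk counts
    over identical age intervals (hazard = total dead / total at risk), the
    convention for merging insurance tables.  Mismatched intervals are fatal.
    """
    if isinstance(sources, (str, Path, pd.DataFrame)):
        sources = [sources]
    frames = [
        src.copy() if isinstance(src, pd.DataFrame) else pd.read_csv(src)
        for src in sources
    ]
    if len(frames) == 1:
        return LifeTable(frames[0], unit=unit)
    if not combine:
        raise ValueError("multiple tables require combine=True")
    base = frames[0][["age_start", "age_end"]].reset_index(drop=True)
    deaths = np.zeros(len(base))
    at_risk = np.zeros(len(base))
    for f in frames:
        f = f.reset_index(drop=True)
        if not {"deaths", "at_risk"}.issubset(f.columns):
            raise ValueError("combining requires deaths and at_risk columns")
        if len(f) != len(base) or not (
            f["age_start"].equals(base["age_start"]) and f["age_end"].equals(base["age_end"])
        ):
            raise ValueError("cannot combine life tables with mismatched age intervals")
        deaths += f["deaths"].to_numpy(dtype=float)
        at_risk += f["at_risk"].to_numpy(dtype=float)
    pooled = base.assign(deaths=deaths, at_risk=at_risk)
    return LifeTable(pooled, unit=unit)


def survival_from_life_table(
    table: LifeTable, t_sex: float
) -> tuple[pd.DataFrame, LifespanSummary]:
    """Survival by iterative multiplication of (1 - hazard), starting at T_sex.

    Returns a frame (age_end, survival) over intervals at or after *t_sex*
    (in the table's unit) and the percentile summary; percentiles the table
    does not reach are reported as not achieved.
    """
    df = table.table
    mask = df["age_start"].to_numpy(dtype=float) >= t_sex
    if not mask.any():
        raise ValueError("t_sex is beyond the end of the life table")
    sub = df.loc[mask]
    s = np.cumprod(1.0 - sub["hazard"].to_numpy(dtype=float))
    ages = sub["age_end"].to_numpy(dtype=float)
    curve = pd.DataFrame({"age_end": ages, "survival": s})
    summary = lifespan_summary(ages, s, t_sex)
    return curve, summary


def annual_to_daily_hazard(
    q: float, method: Literal["compound", "simple"] = "compound"
) -> float:
    """Convert an annual death probability to a per-day hazard.

    Compound (default): (1-q) = (1-h)^365.25; simple: h = q/365.25.
    """
    if not 0 <= q <= 1:
        raise ValueError("annual probability must be in [0, 1]")
    if method == "compound":
        return 1.0 - (1.0 - q) ** (1.0 / DAYS_PER_YEAR)
    if method == "simple":
        return q / DAYS_PER_YEAR
    raise ValueError(f"unknown method {method!r}")


def rescale_by_tsex(series: pd.DataFrame, species: SpeciesConfig,
                    age_column: str = "age") -> pd.DataFrame:
    """Re-express a hazard series' age axis in multiples of T_sex.

    Ages must be in the same unit as ``species.unit``; hazard values are
    untouched.
    """
    out = series.copy()
    out["tsex_multiple"] = out[age_column] / species.t_sex
    return out
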