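"""Per-day stochastic cohort lifespan simulation.

Each simulated individual belongs to a stratum (breeder or non-breeder) that
carries age-binned per-day probabilities of censorship and of death.  On
every day of life from the start day, each surviving, uncensored individual
is first tested against the censorship probability and, if not censored,
against the death probability; survivors at the global end day (default
day 12,000) are censored there.  The same mechanics drive the hidden-breeder
mixture experiment: a population in which some unlabeled fraction is secretly
simulated under the breeder (lower-hazard) model.

Ensembles of simulations are summarised as per-day envelopes (median,
quartiles, 5th/95th percentiles of simulated survival), against which an
observed Kaplan-Meier curve can be scored for coverage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

import numpy as np

from .records_io import Event, LifespanObservation, Sex, T_SEX_DAYS, Tier
from .survival_hazard import HazardEstimate, KMCurve, km_estimate

DEFAULT_END_DAY = 12_000

Stratum = Literal["non_breeder", "breeder"]


@dataclass(frozen=True)
class ModelBin:
    """One age bin [start_day, end_day) with per-day event probabilities."""

    start_day: int
    end_day: int
    p_death: float
    p_censor: float
    source: str = "package_default"  # provenance: e.g. female-only vs both-sex

    def __post_init__(self):
        if not (0 <= self.p_death <= 1 and 0 <= self.p_censor <= 1):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.end_day <= self.start_day:
            raise ValueError("empty model bin")


@dataclass
class SimulationModel:
    """Age-binned per-day death/censorship probabilities per stratum."""

    strata: dict[str, list[ModelBin]]
    start_day: int = T_SEX_DAYS
    end_day: int = DEFAULT_END_DAY

    def __post_init__(self):
        for name, bins in self.strata.items():
            bins.sort(key=lambda b: b.start_day)
            if bins[0].start_day != self.start_day or bins[-1].end_day < self.end_day:
                raise ValueError(f"stratum {name!r} does not cover [{self.start_day}, {self.end_day})")
            for a, b in zip(bins, bins[1:]):
                if b.start_day != a.end_day:
                    raise ValueError(f"stratum {name!r} has a gap/overlap at day {b.start_day}")

    def daily_arrays(self, stratum: str) -> tuple[np.ndarray, np.ndarray]:
        """(p_death, p_censor) indexed by day offset from start_day."""
        n_days = self.end_day - self.start_day
        pd_ = np.zeros(n_days)
        pc = np.zeros(n_days)
        for b in self.strata[stratum]:
            lo = max(b.start_day, self.start_day) - self.start_day
            hi = min(b.end_day, self.end_day) - self.start_day
            pd_[lo:hi] = b.p_death
            pc[lo:hi] = b.p_censor
        return pd_, pc

    @classmethod
    def constant(
        cls,
        p_death_nonbreeder: float,
        p_death_breeder: float,
        p_censor: float = 0.0,
        start_day: int = T_SEX_DAYS,
        end_day: int = DEFAULT_END_DAY,
    ) -> "SimulationModel":
        """Single-bin model with flat probabilities per stratum."""
        return cls(
            strata={
                "non_breeder": [ModelBin(start_day, end_day, p_death_nonbreeder, p_censor)],
                "breeder": [ModelBin(start_day, end_day, p_death_breeder, p_censor)],
            },
            start_day=start_day,
            end_day=end_day,
        )


def default_model(start_day: int = T_SEX_DAYS, end_day: int = DEFAULT_END_DAY) -> SimulationModel:
    """Package-default constant-hazard colony model.

    Non-breeders die at 1e-4/day (2e-4/day in the elevated early bin
    [183, 400)); breeders at 1e-5/day.  Censorship has a low baseline plus a
    strong pulse in the 2250-2500-day bin mimicking a cohort-entry wave being
    compiled ~6 years later, and a higher killed-for-research rate for
    non-breeders than breeders.  All values are package defaults meant to be
    overridden from a config when exact model parameters are available.
    """
    nb_censor = 3e-4
    br_censor = 1e-4
    pulse = (2250, 2500)
    def bins(p_young, p_adult, p_cens):
        return [
            ModelBin(start_day, 400, p_young, p_cens, "package_default"),
            ModelBin(400, pulse[0], p_adult, p_cens, "package_default"),
            ModelBin(pulse[0], pulse[1], p_adult, 2e-3, "package_default"),
            ModelBin(pulse[1], end_day, p_adult, p_cens, "package_default"),
        ]
    return SimulationModel(
        strata={
            "non_breeder": bins(2e-4, 1e-4, nb_censor),
            "breeder": bins(2e-5, 1e-5, br_censor),
        },
        start_day=start_day,
        end_day=end_day,
    )


def build_simulation_model(
    death_tables: dict[str, Sequence[HazardEstimate]],
    censor_tables: dict[str, Sequence[HazardEstimate]],
    start_day: int = T_SEX_DAYS,
    end_day: int = DEFAULT_END_DAY,
    death_source: str = "female_only",
    censor_source: str = "both_sex",
) -> SimulationModel:
    """Assemble a SimulationModel from estimated hazard tables per stratum.

    ``death_tables`` / ``censor_tables`` map stratum name to interval-hazard
    estimates (from :func:`nmrsurv.survival_hazard.interval_hazard`).  The
    source policy strings are recorded as per-bin provenance.  Bins must
    jointly cover [start_day, end_day); gaps are fatal and listed.
    """
    strata: dict[str, list[ModelBin]] = {}
    for stratum in death_tables:
        death = sorted(death_tables[stratum], key=lambda h: h.start_day)
        censor = {(h.start_day, h.end_day): h for h in censor_tables[stratum]}
        bins = []
        gaps = []
        cursor = start_day
        for h in death:
            if h.start_day > cursor:
                gaps.append((cursor, h.start_day))
            c = censor.get((h.start_day, h.end_day))
            if h.hazard is None or c is None or c.hazard is None:
                gaps.append((h.start_day, h.end_day))
                cursor = max(cursor, h.end_day)
                continue
            bins.append(
                ModelBin(h.start_day, min(h.end_day, end_day), h.hazard, c.hazard,
                         source=f"death:{death_source};censor:{censor_source}")
            )
            cursor = max(cursor, h.end_day)
        if cursor < end_day:
            gaps.append((cursor, end_day))
        if gaps:
            raise ValueError(f"stratum {stratum!r} has uncovered bins: {gaps}")
        strata[stratum] = bins
    return SimulationModel(strata=strata, start_day=start_day, end_day=end_day)


@dataclass
class SimulatedCohortResult:
    """Exit day and event per simulated individual, plus the derived KM curve."""

    strata: np.ndarray  # per-individual stratum label
    exit_day: np.ndarray
    event: np.ndarray  # "death" or "censor"
    start_day: int
    end_day: int
    termination: Literal["exhausted", "reached_end_day"]

    def to_observations(self) -> list[LifespanObservation]:
        return [
            LifespanObservation(
                animal_id=f"sim{i:06d}",
                entry_day=self.start_day,
                exit_day=int(d),
                event=Event.DEATH if e == "death" else Event.CENSOR,
                sex=Sex.UNKNOWN,
                breeder=(s == "breeder"),
                tier=Tier.DAY,
            )
            for i, (s, d, e) in enumerate(zip(self.strata, self.exit_day, self.event))
        ]

    def km(self) -> KMCurve:
        return km_estimate(self.to_observations())


def simulate_population(
    model: SimulationModel,
    n_nonbreeders: int,
    n_breeders: int,
    seed: int | np.random.SeedSequence,
) -> SimulatedCohortResult:
    """Simulate one population of independent individuals day by day.

    Each day, every surviving individual draws first against its stratum's
    censorship probability, then (if not censored) against the death
    probability.  Survivors at the model's end day are censored there.
    Identical model + seed give identical output.
    """
    rng = np.random.default_rng(seed)
    labels = np.array(["non_breeder"] * n_nonbreeders + ["breeder"] * n_breeders)
    n = len(labels)
    exit_day = np.full(n, model.end_day, dtype=int)
    event = np.full(n, "censor", dtype=object)
    if n == 0:
        return SimulatedCohortResult(labels, exit_day, event, model.start_day,
                                     model.end_day, "exhausted")

    strat_names = list(model.strata)
    arrays = {s: model.daily_arrays(s) for s in strat_names}
    pd_mat = np.stack([arrays[s][0] for s in strat_names])
    pc_mat = np.stack([arrays[s][1] for s in strat_names])
    sidx = np.array([strat_names.index(s) for s in labels])

    alive = np.arange(n)
    day = model.start_day
    while day < model.end_day and len(alive):
        off = day - model.start_day
        u_c = rng.random(len(alive))
        censored = u_c < pc_mat[sidx[alive], off]
        u_d = rng.random(len(alive))
        died = ~censored & (u_d < pd_mat[sidx[alive], off])
        exiting = censored | died
        if exiting.any():
            idx = alive[exiting]
            exit_day[idx] = day
            event[idx] = np.where(censored[exiting], "censor", "death")
            alive = alive[~exiting]
        day += 1
    termination = "reached_end_day" if len(alive) else "exhausted"
    return SimulatedCohortResult(labels, exit_day, event, model.start_day,
                                 model.end_day, termination)


@dataclass
class EnsembleEnvelope:
    """Percentile bands of simulated survival on an evaluation-day grid."""

    days: np.ndarray
    p5: np.ndarray
    q1: np.ndarray
    median: np.ndarray
    q3: np.ndarray
    p95: np.ndarray
    n_included: np.ndarray

    def __post_init__(self):
        stack = np.vstack([self.p5, self.q1, self.median, self.q3, self.p95])
        if np.any(np.diff(stack, axis=0) < -1e-12):
            raise AssertionError("envelope percentiles out of order")

    def median_at(self, day: float) -> float:
        i = int(np.searchsorted(self.days, day, side="right")) - 1
        return float(self.median[max(i, 0)])


@dataclass
class EnsembleResult:
    envelope: EnsembleEnvelope
    survival_matrix: np.ndarray  # n_sims x n_days survival values
    results: list[SimulatedCohortResult] = field(default_factory=list)


def simulate_ensemble(
    model: SimulationModel,
    n_nonbreeders: int,
    n_breeders: int,
    n_sims: int = 100,
    seed: int | np.random.SeedSequence = 0,
    grid_step: int = 50,
    keep_results: bool = False,
) -> EnsembleResult:
    """Run independent simulations and summarise survival percentiles per day.

    One master seed spawns an independent child stream per simulation.
    Populations that reach 0% survival keep contributing zeros to the
    envelope (every simulation is included at every day); per-day counts of
    simulations with any individual still under observation are reported.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    master = (seed if isinstance(seed, np.random.SeedSequence)
              else np.random.SeedSequence(seed))
    children = master.spawn(n_sims)
    grid = np.arange(model.start_day, model.end_day + 1, grid_step)
    surv = np.empty((n_sims, len(grid)))
    n_open = np.zeros(len(grid), dtype=int)
    results = []
    for i, child in enumerate(children):
        res = simulate_population(model, n_nonbreeders, n_breeders, child)
        curve = res.km()
        surv[i] = curve.survival_at(grid)
        # still "open": some individual remains under observation past this day
        n_open += grid <= res.exit_day.max(initial=model.start_day)
        if keep_results:
            results.append(res)
    envelope = EnsembleEnvelope(
        days=grid,
        p5=np.percentile(surv, 5, axis=0),
        q1=np.percentile(surv, 25, axis=0),
        median=np.percentile(surv, 50, axis=0),
        q3=np.percentile(surv, 75, axis=0),
        p95=np.percentile(surv, 95, axis=0),
        n_included=np.full(len(grid), n_sims),
    )
    return EnsembleResult(envelope=envelope, survival_matrix=surv, results=results)


def mixture_experiment(
    model: SimulationModel,
    n_total: int,
    n_hidden_breeders: int,
    n_sims: int = 100,
    seed: int | np.random.SeedSequence = 0,
    grid_step: int = 50,
) -> EnsembleResult:
    """Ensemble in which some individuals are secretly breeders.

    Simulates n_total - n_hidden_breeders under the non-breeder model and
    n_hidden_breeders under the breeder model; all are reported unlabeled, as
    when true breeding males are recorded as non-breeders.
    """
    if not 0 <= n_hidden_breeders <= n_total:
        raise ValueError("n_hidden_breeders must lie in [0, n_total]")
    return simulate_ensemble(
        model, n_total - n_hidden_breeders, n_hidden_breeders,
        n_sims=n_sims, seed=seed, grid_step=grid_step,
    )


def envelope_coverage(
    observed: KMCurve,
    envelope: EnsembleEnvelope,
    checkpoints: Sequence[float],
) -> float:
    """Fraction of checkpoint days where observed S is inside the 5-95% band."""
    checkpoints = np.asarray(checkpoints, dtype=float)
    if len(checkpoints) == 0:
        raise ValueError("checkpoints must be non-empty")
    s_obs = observed.survival_at(checkpoints)
    idx = np.clip(np.searchsorted(envelope.days, checkpoints, side="right") - 1,
                  0, len(envelope.days) - 1)
    lo = envelope.p5[idx]
    hi = envelope.p95[idx]
    inside = (s_obs >= lo - 1e-12) & (s_obs <= hi + 1e-12)
    return float(inside.mean())
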