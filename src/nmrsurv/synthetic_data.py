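"""Synthetic colony lifespan collections with known ground truth.

The generator emulates the structure of a real captive-colony record set:
colonies with one queen and one to three breeding males, stratum-specific
per-day hazards with an elevated early-adult bin, censorship from transfers
and research sacrifice ("KFR") at stratum-dependent rates, a birth-year
pulse that turns into a censorship pulse when living animals are censored at
the spreadsheet compile date, partial mislabeling of breeding males as
non-breeders, and stochastic degradation of recorded dates to month /
season / year / range / inequality resolution.

Observed records are drawn by the same per-day censor-then-death mechanics
as the cohort simulator, applied on the true (unlabeled-truth) strata.  The
ground truth (true dates, true events, true breeder status) is kept as a
sidecar table that the analysis path never reads.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .cohort_simulator import ModelBin, SimulationModel, simulate_population
from .records_io import (
    AnimalRecord,
    DateSpec,
    Disposition,
    Resolution,
    Sex,
    T_SEX_DAYS,
)

#: Compile dates of the three source spreadsheets being emulated.
DEFAULT_COMPILE_DATES = (
    dt.date(2016, 4, 14),
    dt.date(2016, 4, 20),
    dt.date(2016, 5, 17),
)

# season spans used when degrading a date to season+year resolution
_SEASONS = (
    ("winter", 1, 3),
    ("spring", 4, 6),
    ("summer", 7, 9),
    ("fall", 10, 12),
)


@dataclass
class SynthConfig:
    """Study-condition parameters of the synthetic colony collection."""

    n_colonies: int = 55
    colony_size_mean: float = 60.0  # Poisson mean, clipped to >= 4
    breeding_males_min: int = 1
    breeding_males_max: int = 3
    #: probability a true breeding male is recorded as a non-breeder
    male_breeder_mislabel_fraction: float = 0.68

    # per-day death probabilities by true stratum
    nonbreeder_hazard: float = 1e-4
    breeder_hazard: float = 1e-5
    #: elevated early-adult bin [183, 400) for non-breeders
    early_bin_hazard: float = 2e-4
    #: pre-maturity [0, 183) hazard, both strata
    juvenile_hazard: float = 5e-5
    #: optional Gompertz slope (per day); 0 keeps hazards constant with age
    gompertz_beta: float = 0.0

    # per-day censorship probabilities (transfers + research sacrifice)
    nonbreeder_censor_rate: float = 3e-4
    breeder_censor_rate: float = 1e-4
    #: share of pre-compile censorship events labeled KFR (rest sold/given away)
    kfr_share: float = 0.66

    # calendar structure
    birth_year_start: int = 1982
    birth_year_end: int = 2015
    #: cohort-entry pulse: extra probability mass on this birth year
    pulse_year: Optional[int] = 2010
    pulse_fraction: float = 0.17
    compile_dates: Sequence[dt.date] = DEFAULT_COMPILE_DATES

    #: fraction of rows whose birth date is blanked entirely
    missing_birth_fraction: float = 0.0
    #: date-degradation fractions by target resolution
    degrade_fractions: dict = field(default_factory=dict)

    seed: int = 0
    end_day: int = 12_000

    def __post_init__(self):
        fracs = list(self.degrade_fractions.values()) + [
            self.male_breeder_mislabel_fraction,
            self.missing_birth_fraction,
            self.pulse_fraction,
            self.kfr_share,
        ]
        if any(not 0 <= f <= 1 for f in fracs):
            raise ValueError("all fractions must lie in [0, 1]")
        if sum(self.degrade_fractions.values()) > 1:
            raise ValueError("degrade fractions must sum to <= 1")


def _lifecourse_model(cfg: SynthConfig) -> SimulationModel:
    """Per-day probability model on the day-of-life clock from birth."""
    if cfg.gompertz_beta > 0:
        # Gompertz option: approximate with 100-day steps of the rising hazard
        def bins(base, censor):
            out = [ModelBin(0, T_SEX_DAYS, cfg.juvenile_hazard, censor, "synthetic")]
            start = T_SEX_DAYS
            while start < cfg.end_day:
                end = min(start + 100, cfg.end_day)
                h = min(base * float(np.exp(cfg.gompertz_beta * (start - T_SEX_DAYS))), 1.0)
                out.append(ModelBin(start, end, h, censor, "synthetic"))
                start = end
            return out
        nb = bins(cfg.nonbreeder_hazard, cfg.nonbreeder_censor_rate)
        br = bins(cfg.breeder_hazard, cfg.breeder_censor_rate)
    else:
        nb = [
            ModelBin(0, T_SEX_DAYS, cfg.juvenile_hazard, cfg.nonbreeder_censor_rate, "synthetic"),
            ModelBin(T_SEX_DAYS, 400, cfg.early_bin_hazard, cfg.nonbreeder_censor_rate, "synthetic"),
            ModelBin(400, cfg.end_day, cfg.nonbreeder_hazard, cfg.nonbreeder_censor_rate, "synthetic"),
        ]
        br = [
            ModelBin(0, T_SEX_DAYS, cfg.juvenile_hazard, cfg.breeder_censor_rate, "synthetic"),
            ModelBin(T_SEX_DAYS, cfg.end_day, cfg.breeder_hazard, cfg.breeder_censor_rate, "synthetic"),
        ]
    return SimulationModel(strata={"non_breeder": nb, "breeder": br},
                           start_day=0, end_day=cfg.end_day)


def _draw_birth_date(cfg: SynthConfig, rng: np.random.Generator) -> dt.date:
    years = np.arange(cfg.birth_year_start, cfg.birth_year_end + 1)
    p = np.full(len(years), (1.0 - cfg.pulse_fraction) / len(years))
    if cfg.pulse_year is not None and cfg.birth_year_start <= cfg.pulse_year <= cfg.birth_year_end:
        p[years == cfg.pulse_year] += cfg.pulse_fraction
    p /= p.sum()
    year = int(rng.choice(years, p=p))
    start = dt.date(year, 1, 1)
    n_days = (dt.date(year + 1, 1, 1) - start).days
    return start + dt.timedelta(days=int(rng.integers(n_days)))


def generate_collection(config: SynthConfig) -> tuple[list[AnimalRecord], pd.DataFrame]:
    """Generate observed AnimalRecords plus the ground-truth table.

    Observed records may carry mislabeled breeder status and degraded or
    missing dates; the truth table retains true breeder status, true dates
    and the true event type for every animal.  The same seed always yields
    the same collection.
    """
    rng = np.random.default_rng(config.seed)

    # colony structure on the true strata
    true_breeder: list[bool] = []
    sexes: list[Sex] = []
    colony_of: list[int] = []
    for c in range(config.n_colonies):
        size = max(int(rng.poisson(config.colony_size_mean)), 4)
        n_bmales = int(rng.integers(config.breeding_males_min, config.breeding_males_max + 1))
        for k in range(size):
            colony_of.append(c)
            if k == 0:  # the queen
                sexes.append(Sex.FEMALE)
                true_breeder.append(True)
            elif k <= n_bmales:
                sexes.append(Sex.MALE)
                true_breeder.append(True)
            else:
                sexes.append(Sex.FEMALE if rng.random() < 0.5 else Sex.MALE)
                true_breeder.append(False)
    n = len(true_breeder)
    true_breeder_arr = np.array(true_breeder)

    # lifecourse via the cohort-simulator mechanics, breeders simulated last
    order = np.argsort(true_breeder_arr, kind="stable")
    model = _lifecourse_model(config)
    sim = simulate_population(
        model,
        n_nonbreeders=int((~true_breeder_arr).sum()),
        n_breeders=int(true_breeder_arr.sum()),
        seed=np.random.SeedSequence(entropy=(config.seed, 1)),
    )
    exit_day = np.empty(n, dtype=int)
    sim_event = np.empty(n, dtype=object)
    exit_day[order] = sim.exit_day
    sim_event[order] = sim.event

    compile_dates = list(config.compile_dates)
    colony_compile = [compile_dates[int(rng.integers(len(compile_dates)))]
                      for _ in range(config.n_colonies)]

    records: list[AnimalRecord] = []
    truth_rows = []
    for i in range(n):
        birth = _draw_birth_date(config, rng)
        compile_date = colony_compile[colony_of[i]]
        raw_end = birth + dt.timedelta(days=int(exit_day[i]))
        if raw_end >= compile_date:
            # still under observation at compile time -> censored there
            true_event = "censor"
            end = compile_date
            disposition = Disposition.ALIVE_AT_COMPILE
        elif sim_event[i] == "death":
            true_event = "death"
            end = raw_end
            disposition = Disposition.DEAD
        else:
            true_event = "censor"
            end = raw_end
            disposition = (Disposition.KFR if rng.random() < config.kfr_share
                           else Disposition.SOLD_GIVEN_AWAY)

        observed_breeder = bool(true_breeder[i])
        if (observed_breeder and sexes[i] is Sex.MALE
                and rng.random() < config.male_breeder_mislabel_fraction):
            observed_breeder = False

        animal_id = f"{100000000 + i:09d}"
        records.append(
            AnimalRecord(
                animal_id=animal_id,
                sex=sexes[i],
                breeder=observed_breeder,
                birth=DateSpec.from_date(birth),
                end=DateSpec.from_date(end),
                disposition=disposition,
                compile_date=compile_date,
            )
        )
        truth_rows.append(
            {
                "animal_id": animal_id,
                "colony": colony_of[i],
                "sex": sexes[i].value,
                "true_breeder": bool(true_breeder[i]),
                "observed_breeder": observed_breeder,
                "true_birth": birth.isoformat(),
                "true_end": end.isoformat(),
                "true_event": true_event,
                "true_lifespan_days": (end - birth).days,
                "disposition": disposition.value,
            }
        )
    truth = pd.DataFrame(truth_rows)

    if config.missing_birth_fraction > 0:
        blank = rng.random(n) < config.missing_birth_fraction
        for i in np.nonzero(blank)[0]:
            records[i].birth = DateSpec.missing("")
    if config.degrade_fractions:
        records = degrade_dates(records, config.degrade_fractions,
                                rng=np.random.default_rng(
                                    np.random.SeedSequence(entropy=(config.seed, 2))))
    return records, truth


def degrade_dates(
    records: Sequence[AnimalRecord],
    fractions: dict,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> list[AnimalRecord]:
    """Lower the resolution of recorded birth dates on a random subset.

    ``fractions`` maps target resolution names (``month``, ``season_year``,
    ``year``, ``range``, ``inequality``) to the probability that a record's
    birth date is rewritten in that form.  Every degraded form remains
    consistent with the true date (the true date lies within the month /
    season / year / range, or satisfies the inequality); inequality forms
    are unbounded on one side by construction.  Records whose birth is not
    day-resolution are left untouched.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    names = list(fractions)
    probs = np.array([fractions[k] for k in names], dtype=float)
    if probs.sum() > 1:
        raise ValueError("degrade fractions must sum to <= 1")
    out: list[AnimalRecord] = []
    for rec in records:
        rec = AnimalRecord(**{**rec.__dict__})
        if rec.birth.resolution is Resolution.DAY:
            u = rng.random()
            cum = 0.0
            for name, p in zip(names, probs):
                cum += p
                if u < cum:
                    rec.birth = _degrade(rec.birth.payload, name)
                    break
        out.append(rec)
    return out


def _degrade(d: dt.date, target: str) -> DateSpec:
    if target == "month":
        return DateSpec.parse(f"{d.year:04d}-{d.month:02d}")
    if target == "season_year":
        for name, m0, m1 in _SEASONS:
            if m0 <= d.month <= m1:
                return DateSpec.parse(f"{name.capitalize()} {d.year}")
        raise AssertionError("unreachable")
    if target == "year":
        return DateSpec.parse(f"{d.year}")
    if target == "range":
        return DateSpec.parse(f"{d.year - 1}..{d.year + 1}")
    if target == "inequality":
        return DateSpec.parse(f">{d.year - 1}")
    raise ValueError(f"unknown degradation target {target!r}")


_DISPOSITION_TOKEN = {
    Disposition.DEAD: "DEAD",
    Disposition.ALIVE_AT_COMPILE: "ALIVE",
    Disposition.SOLD_GIVEN_AWAY: "SOLD/GIVEN AWAY",
    Disposition.KFR: "KFR",
    Disposition.UNKNOWN_DEATH_DATE: "UNKNOWN",
}


def write_collection(
    records: Sequence[AnimalRecord],
    truth: pd.DataFrame,
    out_dir: Union[str, Path],
    config: Optional[SynthConfig] = None,
) -> Path:
    """Write the collection CSV, sidecar ground truth and config echo.

    The observed spreadsheet goes to ``<out_dir>/lifespans.csv``; the ground
    truth to ``<out_dir>/truth/ground_truth.csv`` (a directory the analysis
    path never reads); the config echo to ``<out_dir>/config.yaml``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "lifespans.csv"
    rows = []
    for r in records:
        end_raw = "" if r.disposition is Disposition.ALIVE_AT_COMPILE else r.end.raw_text
        rows.append(
            {
                "animal_id": r.animal_id,
                "sex": r.sex.value,
                "breeder": int(r.breeder),
                "date_of_birth": r.birth.raw_text,
                "date_of_end": end_raw,
                "disposition": _DISPOSITION_TOKEN[r.disposition],
                "compile_date": r.compile_date.isoformat() if r.compile_date else "",
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)

    truth_dir = out_dir / "truth"
    truth_dir.mkdir(exist_ok=True)
    truth.to_csv(truth_dir / "ground_truth.csv", index=False)

    if config is not None:
        import yaml

        echo = asdict(config)
        echo["compile_dates"] = [d.isoformat() for d in config.compile_dates]
        with open(out_dir / "config.yaml", "w") as fh:
            yaml.safe_dump(echo, fh, sort_keys=False)
    return path
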