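"""Shared test-data constructors."""

import itertools

import numpy as np

from nmrsurv.records_io import Event, LifespanObservation, Sex, T_SEX_DAYS, Tier

_counter = itertools.count()


def make_obs(exit_day, event, sex=Sex.FEMALE, breeder=False, entry=T_SEX_DAYS):
    return LifespanObservation(
        animal_id=f"a{next(_counter):06d}",
        entry_day=entry,
        exit_day=int(exit_day),
        event=event,
        sex=sex,
        breeder=breeder,
        tier=Tier.DAY,
    )


def obs_from_arrays(exits, died, **kw):
    return [
        make_obs(t, Event.DEATH if d else Event.CENSOR, **kw)
        for t, d in zip(exits, died)
    ]


def exponential_cohort(n, lam, seed, censor_at=None):
    """Uncensored (or administratively censored) exponential lifespans."""
    rng = np.random.default_rng(seed)
    durations = rng.exponential(1.0 / lam, size=n)
    died = np.ones(n, dtype=bool)
    if censor_at is not None:
        died = durations < censor_at
        durations = np.minimum(durations, censor_at)
    return obs_from_arrays(T_SEX_DAYS + np.floor(durations), died)
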