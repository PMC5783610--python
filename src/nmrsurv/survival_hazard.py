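"""Kaplan-Meier survival and exposure-day interval hazard estimation.

The hazard estimator divides the number of events of interest in an age bin
by the animal-days of observation within the bin (animals alive across a
whole bin contribute its full width; animals exiting within it contribute
the days up to and including the exit day).  Uncertainty uses the Wilson
score interval with continuity correction on the per-day event probability.
Either death or censorship can be the event of interest: censorship hazards
are estimated by exchanging the roles of the two event types.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

import numpy as np

from .records_io import Event, LifespanObservation, T_SEX_DAYS


@dataclass
class KMCurve:
    """Product-limit survival estimate on the day-of-life clock.

    ``times`` are the distinct days at which at least one death or censoring
    occurred; ``survival[i]`` is S(t) just after ``times[i]``.  ``at_risk[i]``
    counts animals at risk immediately before ``times[i]``.  Ties at a day are
    processed deaths-before-censorings.
    """

    entry_day: int
    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    deaths: np.ndarray
    censored: np.ndarray

    def survival_at(self, day) -> np.ndarray:
        """Step-function evaluation of S at one or more days-of-life."""
        day = np.asarray(day)
        idx = np.searchsorted(self.times, day, side="right")
        s = np.concatenate([[1.0], self.survival])
        return s[idx]

    def at_risk_at(self, day) -> np.ndarray:
        """Number still at risk just after one or more days."""
        day = np.asarray(day)
        idx = np.searchsorted(self.times, day, side="right")
        n0 = self.at_risk[0] if len(self.at_risk) else 0
        n_after = np.concatenate([[n0], self.at_risk - self.deaths - self.censored])
        return n_after[idx]


def km_estimate(observations: Sequence[LifespanObservation]) -> KMCurve:
    """Kaplan-Meier product-limit estimate for a common-entry cohort."""
    if not observations:
        raise ValueError("km_estimate requires at least one observation")
    entries = {o.entry_day for o in observations}
    if len(entries) != 1:
        raise ValueError(f"all observations must share one entry day, got {sorted(entries)}")
    entry = entries.pop()
    exits = np.array([o.exit_day for o in observations])
    is_death = np.array([o.event is Event.DEATH for o in observations])
    if np.any(exits < entry):
        raise ValueError("exit before entry day")

    times = np.unique(exits)
    d = np.array([int(np.sum(is_death & (exits == t))) for t in times])
    c = np.array([int(np.sum(~is_death & (exits == t))) for t in times])
    n = np.empty_like(d)
    alive = len(observations)
    surv = np.empty(len(times))
    s = 1.0
    for i, t in enumerate(times):
        n[i] = alive
        if d[i]:
            s *= 1.0 - d[i] / alive  # deaths processed before censorings at t
        surv[i] = s
        alive -= d[i] + c[i]
    return KMCurve(entry_day=entry, times=times, survival=surv, at_risk=n,
                   deaths=d, censored=c)


def wilson_interval(successes: int, trials: int, confidence: float = 0.95) -> tuple[float, float]:
    """Wilson score interval with continuity correction (Newcombe's form).

    Returns (low, high) clipped to [0, 1]; low is 0 when successes == 0 and
    high is 1 when successes == trials.
    """
    if trials <= 0:
        raise ValueError("trials must be positive")
    if not 0 <= successes <= trials:
        raise ValueError("successes must lie in [0, trials]")
    from scipy.stats import norm

    z = norm.ppf(0.5 + confidence / 2.0)
    n = float(trials)
    p = successes / n
    z2 = z * z
    denom = 2.0 * (n + z2)
    low_num = 2.0 * n * p + z2 - 1.0 - z * math.sqrt(
        max(0.0, z2 - 2.0 - 1.0 / n + 4.0 * p * (n * (1.0 - p) + 1.0))
    )
    high_num = 2.0 * n * p + z2 + 1.0 + z * math.sqrt(
        max(0.0, z2 + 2.0 - 1.0 / n + 4.0 * p * (n * (1.0 - p) - 1.0))
    )
    low = 0.0 if successes == 0 else max(0.0, low_num / denom)
    high = 1.0 if successes == trials else min(1.0, high_num / denom)
    return low, high


@dataclass
class HazardEstimate:
    """Per-day event probability within one half-open age bin [start, end)."""

    start_day: int
    end_day: int
    events: int
    exposure_days: float
    hazard: Optional[float]
    ci_low: Optional[float]
    ci_high: Optional[float]
    n_start: int

    @property
    def defined(self) -> bool:
        return self.hazard is not None


@dataclass
class BinScheme:
    """Age-bin layout for interval hazards.

    ``fixed_width`` tiles [start, stop) with equal windows, optionally after a
    partial first window (the maturity-to-first-full-window stub).
    ``explicit_edges`` uses the given day edges verbatim.  ``adaptive`` keeps a
    fixed first bin then closes each later bin once it holds at least
    ``min_events_per_bin`` events, so confidence intervals stay roughly even
    as the population shrinks.
    """

    mode: Literal["fixed_width", "explicit_edges", "adaptive"] = "fixed_width"
    width: int = 200
    start: int = T_SEX_DAYS
    first_full_start: Optional[int] = None  # fixed_width: first full window start
    stop: Optional[int] = None
    edges: Optional[Sequence[int]] = None
    first_bin_end: int = 400  # adaptive: end of the fixed first bin
    min_events_per_bin: int = 30

    def bin_edges(self, observations: Sequence[LifespanObservation],
                  event_of_interest: Event = Event.DEATH) -> list[int]:
        if self.mode == "explicit_edges":
            edges = list(self.edges or [])
            if len(edges) < 2 or any(b <= a for a, b in zip(edges, edges[1:])):
                raise ValueError("explicit edges must be strictly increasing, >= 2 values")
            return edges
        last = max(o.exit_day for o in observations) + 1
        stop = self.stop if self.stop is not None else last
        if self.mode == "fixed_width":
            first_full = self.first_full_start if self.first_full_start is not None else self.start
            edges = [self.start]
            if first_full > self.start:
                edges.append(first_full)
            e = edges[-1]
            while e < stop:
                e += self.width
                edges.append(e)
            return edges
        if self.mode == "adaptive":
            exits = np.sort([o.exit_day for o in observations if o.event is event_of_interest])
            edges = [self.start, self.first_bin_end]
            count = 0
            for t in exits:
                if t < self.first_bin_end:
                    continue
                count += 1
                if count >= self.min_events_per_bin:
                    edges.append(int(t) + 1)
                    count = 0
            if edges[-1] < stop:
                edges.append(stop)
            return edges
        raise ValueError(f"unknown bin mode {self.mode!r}")


def interval_hazard(
    observations: Sequence[LifespanObservation],
    scheme: BinScheme,
    event_of_interest: Event = Event.DEATH,
    confidence: float = 0.95,
) -> list[HazardEstimate]:
    """Exposure-day hazard estimates per age bin.

    Exposure within a bin counts every day an animal was under observation in
    the bin, including the day of its death or censorship.  The point estimate
    is events/exposure; the confidence interval is the continuity-corrected
    Wilson interval with the exposure-day count as the number of trials.
    Bins with zero exposure yield an undefined (flagged) estimate.
    """
    if not observations:
        raise ValueError("no observations")
    edges = scheme.bin_edges(observations, event_of_interest)
    entry = np.array([o.entry_day for o in observations])
    exit_ = np.array([o.exit_day for o in observations])
    is_event = np.array([o.event is event_of_interest for o in observations])

    out = []
    for s, e in zip(edges, edges[1:]):
        # days at risk in [s, e): from max(s, entry) through min(exit, e-1),
        # the exit day itself counted
        lo = np.maximum(s, entry)
        hi = np.minimum(exit_, e - 1)
        exposure = int(np.sum(np.clip(hi - lo + 1, 0, None)[(exit_ >= s) & (entry < e)]))
        events = int(np.sum(is_event & (exit_ >= s) & (exit_ < e)))
        n_start = int(np.sum((exit_ >= s) & (entry <= s)))
        if exposure > 0:
            h = events / exposure
            lo_ci, hi_ci = wilson_interval(events, exposure, confidence)
            out.append(HazardEstimate(s, e, events, exposure, h, lo_ci, hi_ci, n_start))
        else:
            out.append(HazardEstimate(s, e, events, 0, None, None, None, n_start))
    return out


@dataclass
class LifespanSummary:
    """Median and 95th-percentile (operational 'maximal') post-maturity lifespan."""

    t_sex: float
    median_post_tsex: Optional[float]
    maximal_post_tsex: Optional[float]  # 95th percentile of post-T_sex lifespans
    ratio_median_to_max_segment: Optional[float]

    @property
    def median_achieved(self) -> bool:
        return self.median_post_tsex is not None

    @property
    def maximal_achieved(self) -> bool:
        return self.maximal_post_tsex is not None


def lifespan_summary(
    days: Sequence[float], survival: Sequence[float], t_sex: float
) -> LifespanSummary:
    """Percentile summary of a survival curve S(day) beginning at maturity.

    ``days`` are ages on the absolute clock; the summary reports times since
    *t_sex*.  The median is where S first reaches 0.5, the operational maximal
    lifespan where it first reaches 0.05.  A percentile the curve never
    reaches is reported as not achieved (None) rather than extrapolated.
    The segment ratio is (maximal - median)/median: how long the tail from
    median to maximal lifespan is, relative to the maturity-to-median time.
    """
    days = np.asarray(days, dtype=float)
    survival = np.asarray(survival, dtype=float)
    if len(days) != len(survival) or len(days) == 0:
        raise ValueError("days and survival must be equal-length, non-empty")

    def crossing(level: float) -> Optional[float]:
        idx = np.nonzero(survival <= level)[0]
        if len(idx) == 0:
            return None
        return float(days[idx[0]] - t_sex)

    median = crossing(0.5)
    maximal = crossing(0.05)
    ratio = None
    if median is not None and maximal is not None and median > 0:
        ratio = (maximal - median) / median
    return LifespanSummary(t_sex=t_sex, median_post_tsex=median,
                           maximal_post_tsex=maximal,
                           ratio_median_to_max_segment=ratio)


def km_lifespan_summary(curve: KMCurve, t_sex: Optional[float] = None) -> LifespanSummary:
    if t_sex is None:
        t_sex = curve.entry_day
    return lifespan_summary(curve.times, curve.survival, t_sex)


def at_risk_threshold_day(curve: KMCurve, threshold: int) -> Optional[int]:
    """First day-of-life at which the at-risk count falls below *threshold*."""
    n_after = curve.at_risk - curve.deaths - curve.censored
    below = np.nonzero(n_after < threshold)[0]
    if len(below) == 0:
        return None
    return int(curve.times[below[0]])


def hazard_table(estimates: Iterable[HazardEstimate]):
    """Hazard estimates as a pandas DataFrame (one row per bin)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "bin_start": h.start_day,
                "bin_end": h.end_day,
                "events": h.events,
                "exposure_days": h.exposure_days,
                "hazard": h.hazard,
                "ci_low": h.ci_low,
                "ci_high": h.ci_high,
                "n_start": h.n_start,
            }
            for h in estimates
        ]
    )


def km_table(curve: KMCurve):
    """KM curve as a pandas DataFrame (day, S, n_at_risk, d, c)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "day": curve.times,
            "survival": curve.survival,
            "n_at_risk": curve.at_risk,
            "deaths": curve.deaths,
            "censored": curve.censored,
        }
    )
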