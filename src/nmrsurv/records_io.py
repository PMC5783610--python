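"""Reading of colony lifespan spreadsheets and date-imputation.

Colony records store birth and death/censorship dates at mixed resolution:
exact calendar dates, month-of-birth, season or year only, date ranges,
one-sided inequalities ("born after 1997"), or two candidate dates.  Each
record is parsed into a :class:`DateSpec` pair and admitted to the analysis
at one of four *stringency tiers*: day-resolution only, plus month-resolution,
plus all bounded low-resolution forms (season / year / range / two options),
and finally plus one-sided inequalities.

Imputation follows a deterministic mid-point convention: month -> the 15th;
year -> July 2; seasons -> fixed mid-season days (Fall -> November 7); ranges
and two-option dates -> the middle day of the spanned interval; inequalities
-> the nearest date satisfying the inequality.  "Approximate" markers ("~")
are treated the same as the unqualified form.

The analysis clock starts at reproductive maturity (T_sex = day 183 of life);
animals whose death or censorship falls strictly before that day are dropped
and counted.  Censorship applies to animals still alive when the spreadsheet
was compiled, to animals sold or given away, and to animals killed for
research ("KFR").
"""

from __future__ import annotations

import calendar
import csv
import datetime as dt
import enum
import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

logger = logging.getLogger(__name__)

T_SEX_DAYS = 183
"""Age of reproductive maturity in days; entry day of every observation."""


class Resolution(enum.Enum):
    DAY = "day"
    MONTH = "month"
    SEASON_YEAR = "season_year"
    YEAR = "year"
    RANGE = "range"
    INEQUALITY = "inequality"
    TWO_OPTIONS = "two_options"
    MISSING = "missing"


class Tier(enum.IntEnum):
    """Stringency tiers, ordered so that higher tiers admit more resolutions."""

    DAY = 0
    PLUS_MONTH = 1
    PLUS_LOW_RES = 2
    PLUS_INEQUALITY = 3


#: Tier at which each date resolution becomes admissible.
RESOLUTION_TIER: dict[Resolution, Optional[Tier]] = {
    Resolution.DAY: Tier.DAY,
    Resolution.MONTH: Tier.PLUS_MONTH,
    Resolution.SEASON_YEAR: Tier.PLUS_LOW_RES,
    Resolution.YEAR: Tier.PLUS_LOW_RES,
    Resolution.RANGE: Tier.PLUS_LOW_RES,
    Resolution.TWO_OPTIONS: Tier.PLUS_LOW_RES,
    Resolution.INEQUALITY: Tier.PLUS_INEQUALITY,
    Resolution.MISSING: None,
}

#: Mid-season imputation days (month, day).  The Fall convention anchors the
#: set; the other three use the analogous offsets.
SEASON_MIDPOINTS = {
    "winter": (2, 5),
    "spring": (5, 6),
    "summer": (8, 6),
    "fall": (11, 7),
    "autumn": (11, 7),
}

YEAR_MIDPOINT = (7, 2)  # July 2, fixed in leap years too
MONTH_MIDDAY = 15

_MONTHS = {name.lower(): i for i, name in enumerate(calendar.month_name) if name}
_MONTHS.update({name.lower(): i for i, name in enumerate(calendar.month_abbr) if name})

_MISSING_TOKENS = {"", "?", "unknown", "na", "n/a", "none", "nan"}


class Sex(enum.Enum):
    FEMALE = "female"
    MALE = "male"
    UNKNOWN = "unknown"


class Disposition(enum.Enum):
    DEAD = "dead"
    ALIVE_AT_COMPILE = "alive_at_compile"
    SOLD_GIVEN_AWAY = "sold_given_away"
    KFR = "kfr"
    UNKNOWN_DEATH_DATE = "unknown_death_date"


class Event(enum.Enum):
    DEATH = "death"
    CENSOR = "censor"


#: Dispositions recorded as right-censorship rather than death.
CENSORING_DISPOSITIONS = frozenset(
    {Disposition.ALIVE_AT_COMPILE, Disposition.SOLD_GIVEN_AWAY, Disposition.KFR}
)


class DateParseError(ValueError):
    pass


@dataclass(frozen=True)
class DateSpec:
    """A possibly low-resolution date as recorded in the spreadsheet."""

    raw_text: str
    resolution: Resolution
    #: Parsed payload; shape depends on resolution:
    #:   DAY -> date; MONTH -> (year, month); SEASON_YEAR -> (season, year);
    #:   YEAR -> year; RANGE / TWO_OPTIONS -> (start_date, end_date);
    #:   INEQUALITY -> (direction, nearest_satisfying_date); MISSING -> None.
    payload: object = None

    def __post_init__(self) -> None:
        if self.resolution is Resolution.DAY and not isinstance(self.payload, dt.date):
            raise ValueError("day resolution requires a calendar date payload")
        if self.resolution in (Resolution.RANGE, Resolution.TWO_OPTIONS):
            start, end = self.payload
            if start > end:
                raise ValueError(f"range start after end in {self.raw_text!r}")
        if self.resolution is Resolution.MISSING and self.payload is not None:
            raise ValueError("missing resolution carries no payload")

    @property
    def tier(self) -> Optional[Tier]:
        return RESOLUTION_TIER[self.resolution]

    @classmethod
    def missing(cls, raw_text: str = "") -> "DateSpec":
        return cls(raw_text=raw_text, resolution=Resolution.MISSING)

    @classmethod
    def from_date(cls, d: dt.date) -> "DateSpec":
        return cls(raw_text=d.isoformat(), resolution=Resolution.DAY, payload=d)

    @classmethod
    def parse(cls, text: object, dayfirst: bool = False) -> "DateSpec":
        """Parse free text into a DateSpec.

        Accepted forms (leading ``~`` markers are ignored):

        * ``1995-06-17`` or ``17/06/1995`` (slash form month-first when
          ``dayfirst`` is False is not accepted -- slashes are day/month/year;
          ``dayfirst`` switches ``/`` forms to month/day/year when False is
          wanted) -- exact day
        * ``1995-06``, ``June 1995`` -- month
        * ``Fall 1999`` -- season + year
        * ``1997`` -- year
        * ``1996..1998``, ``1996-01-01..1998-12-31``, ``A to B`` -- range
        * ``A or B`` -- two candidate dates
        * ``>1997``, ``<1997-05-12`` -- inequality
        * blank / ``unknown`` -- missing

        Raises :class:`DateParseError` on unintelligible text.
        """
        raw = "" if text is None else str(text).strip()
        norm = raw.strip().strip('"').strip()
        if norm.lower() in _MISSING_TOKENS:
            return cls.missing(raw)

        body = norm.lstrip("~").strip()

        if body[:1] in (">", "<"):
            return cls._parse_inequality(raw, body, dayfirst)

        for sep in ("..", " to ", " TO ", " To "):
            if sep in body:
                a, b = (s.strip() for s in body.split(sep, 1))
                return cls._parse_pair(raw, a, b, Resolution.RANGE, dayfirst)
        m = re.split(r"\s+or\s+", body, flags=re.IGNORECASE)
        if len(m) == 2:
            return cls._parse_pair(raw, m[0].strip(), m[1].strip(), Resolution.TWO_OPTIONS, dayfirst)

        return cls._parse_simple(raw, body, dayfirst)

    @classmethod
    def _parse_simple(cls, raw: str, body: str, dayfirst: bool) -> "DateSpec":
        body = body.lstrip("~").strip()
        # ISO day
        m = re.fullmatch(r"(\d{4})-(\d{1,2})-(\d{1,2})", body)
        if m:
            y, mo, d = map(int, m.groups())
            return cls(raw, Resolution.DAY, _checked_date(y, mo, d, raw))
        # slash day: day/month/year by default, month/day/year if not dayfirst
        m = re.fullmatch(r"(\d{1,2})/(\d{1,2})/(\d{4})", body)
        if m:
            a, b, y = map(int, m.groups())
            d, mo = (a, b) if dayfirst else (b, a)
            return cls(raw, Resolution.DAY, _checked_date(y, mo, d, raw))
        # ISO month
        m = re.fullmatch(r"(\d{4})-(\d{1,2})", body)
        if m:
            y, mo = map(int, m.groups())
            if not 1 <= mo <= 12:
                raise DateParseError(f"bad month in {raw!r}")
            return cls(raw, Resolution.MONTH, (y, mo))
        # "June 1995" / "Jun 1995"
        m = re.fullmatch(r"([A-Za-z]+)\.?\s+(\d{4})", body)
        if m:
            word, y = m.group(1).lower(), int(m.group(2))
            if word in SEASON_MIDPOINTS:
                return cls(raw, Resolution.SEASON_YEAR, (word, y))
            if word in _MONTHS:
                return cls(raw, Resolution.MONTH, (y, _MONTHS[word]))
            raise DateParseError(f"unknown month/season {word!r} in {raw!r}")
        # bare year
        m = re.fullmatch(r"(\d{4})", body)
        if m:
            return cls(raw, Resolution.YEAR, int(m.group(1)))
        raise DateParseError(f"cannot interpret date {raw!r}")

    @classmethod
    def _parse_pair(
        cls, raw: str, a: str, b: str, resolution: Resolution, dayfirst: bool
    ) -> "DateSpec":
        start = cls._parse_simple(a, a, dayfirst).span()[0]
        end = cls._parse_simple(b, b, dayfirst).span()[1]
        if start > end:
            raise DateParseError(f"range start after end in {raw!r}")
        return cls(raw, resolution, (start, end))

    @classmethod
    def _parse_inequality(cls, raw: str, body: str, dayfirst: bool) -> "DateSpec":
        direction = body[0]
        inner = cls._parse_simple(body[1:], body[1:].strip(), dayfirst)
        lo, hi = inner.span()
        if direction == ">":
            nearest = hi + dt.timedelta(days=1)
        else:
            nearest = lo - dt.timedelta(days=1)
        return cls(raw, Resolution.INEQUALITY, (direction, nearest))

    def span(self) -> tuple[dt.date, dt.date]:
        """First and last calendar day consistent with this spec (bounded forms)."""
        r, p = self.resolution, self.payload
        if r is Resolution.DAY:
            return p, p
        if r is Resolution.MONTH:
            y, mo = p
            return dt.date(y, mo, 1), dt.date(y, mo, calendar.monthrange(y, mo)[1])
        if r is Resolution.YEAR:
            return dt.date(p, 1, 1), dt.date(p, 12, 31)
        if r is Resolution.SEASON_YEAR:
            # span unused for resolution; mid-season day repeated
            season, y = p
            mid = dt.date(y, *SEASON_MIDPOINTS[season])
            return mid, mid
        if r in (Resolution.RANGE, Resolution.TWO_OPTIONS):
            return p
        raise ValueError(f"no bounded span for resolution {r}")


def _checked_date(y: int, mo: int, d: int, raw: str) -> dt.date:
    try:
        return dt.date(y, mo, d)
    except ValueError as exc:
        raise DateParseError(f"invalid calendar date {raw!r}: {exc}") from None


def resolve_date(spec: DateSpec, tier: Tier = Tier.PLUS_INEQUALITY) -> Optional[dt.date]:
    """Impute a single calendar date from a DateSpec, if admissible at *tier*.

    Deterministic mid-point conventions: 15th of the month; July 2 of the
    year; fixed mid-season days (Fall -> November 7); middle day of a range
    or of two candidate dates; nearest satisfying date for inequalities.
    Returns None when the spec is missing or not admissible at *tier*.
    """
    spec_tier = spec.tier
    if spec_tier is None or spec_tier > tier:
        return None
    r, p = spec.resolution, spec.payload
    if r is Resolution.DAY:
        return p
    if r is Resolution.MONTH:
        y, mo = p
        return dt.date(y, mo, MONTH_MIDDAY)
    if r is Resolution.SEASON_YEAR:
        season, y = p
        return dt.date(y, *SEASON_MIDPOINTS[season])
    if r is Resolution.YEAR:
        return dt.date(p, *YEAR_MIDPOINT)
    if r in (Resolution.RANGE, Resolution.TWO_OPTIONS):
        start, end = p
        return start + (end - start) // 2
    if r is Resolution.INEQUALITY:
        return p[1]
    raise AssertionError(f"unhandled resolution {r}")


@dataclass
class AnimalRecord:
    """One animal's raw spreadsheet row after parsing."""

    animal_id: str
    sex: Sex
    breeder: bool
    birth: DateSpec
    end: DateSpec
    disposition: Disposition
    compile_date: Optional[dt.date] = None

    @property
    def tier(self) -> Optional[Tier]:
        """Minimum stringency tier admitting both dates; None if either missing."""
        bt, et = self.birth.tier, self.end.tier
        if bt is None or et is None:
            return None
        return max(bt, et)

    @property
    def event(self) -> Event:
        if self.disposition in CENSORING_DISPOSITIONS:
            return Event.CENSOR
        return Event.DEATH


@dataclass
class LifespanObservation:
    """Analysis-ready (entry, exit, event) triple on the day-of-life clock."""

    animal_id: str
    entry_day: int
    exit_day: int
    event: Event
    sex: Sex
    breeder: bool
    tier: Tier

    @property
    def stratum(self) -> tuple[Sex, bool]:
        return (self.sex, self.breeder)


@dataclass
class StringencyReport:
    """Accounting of where every input row went."""

    total_rows: int = 0
    excluded_missing: int = 0
    excluded_unparseable: int = 0
    included: int = 0  # rows that became records with both dates usable at some tier
    #: per-tier additions: tier -> Counter with keys n/death/censor
    tier_added: dict[Tier, Counter] = field(default_factory=dict)

    def add_tier(self, tier: Tier, event: Event) -> None:
        c = self.tier_added.setdefault(tier, Counter())
        c["n"] += 1
        c[event.value] += 1
        self.included += 1

    def check_conservation(self) -> None:
        if self.included + self.excluded_missing + self.excluded_unparseable != self.total_rows:
            raise AssertionError("stringency report does not conserve row count")

    def to_dict(self) -> dict:
        return {
            "total_rows": self.total_rows,
            "included": self.included,
            "excluded_missing": self.excluded_missing,
            "excluded_unparseable": self.excluded_unparseable,
            "tier_added": {
                t.name.lower(): dict(c) for t, c in sorted(self.tier_added.items())
            },
        }


#: Canonical CSV column names; a format_config maps these to actual headers.
CANONICAL_COLUMNS = (
    "animal_id",
    "sex",
    "breeder",
    "date_of_birth",
    "date_of_end",
    "disposition",
    "compile_date",
)

_SEX_MAP = {
    "f": Sex.FEMALE, "female": Sex.FEMALE,
    "m": Sex.MALE, "male": Sex.MALE,
    "u": Sex.UNKNOWN, "unknown": Sex.UNKNOWN, "": Sex.UNKNOWN, "?": Sex.UNKNOWN,
}

_DISPOSITION_MAP = {
    "dead": Disposition.DEAD,
    "died": Disposition.DEAD,
    "alive": Disposition.ALIVE_AT_COMPILE,
    "sold/given away": Disposition.SOLD_GIVEN_AWAY,
    "sold": Disposition.SOLD_GIVEN_AWAY,
    "given away": Disposition.SOLD_GIVEN_AWAY,
    "kfr": Disposition.KFR,
    "unknown": Disposition.UNKNOWN_DEATH_DATE,
}

_TRUE_TOKENS = {"1", "true", "yes", "y", "breeder", "b"}


@dataclass
class FormatConfig:
    """Column mapping and date dialect for one spreadsheet export."""

    columns: Mapping[str, str] = field(default_factory=dict)  # canonical -> actual
    dayfirst: bool = False
    default_compile_date: Optional[dt.date] = None

    def actual(self, canonical: str) -> str:
        return self.columns.get(canonical, canonical)


def parse_collection(
    file_path: Union[str, Path],
    format_config: Optional[FormatConfig] = None,
) -> tuple[list[AnimalRecord], StringencyReport]:
    """Read a lifespan CSV into AnimalRecords plus a row-accounting report.

    Every row becomes either an AnimalRecord (counted as included at its
    stringency tier) or a logged exclusion (missing dates or unparseable);
    no row is silently dropped.  Unmappable required columns are fatal.
    """
    cfg = format_config or FormatConfig()
    path = Path(file_path)
    if not path.exists():
        raise FileNotFoundError(f"collection file not found: {path}")

    records: list[AnimalRecord] = []
    report = StringencyReport()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        for canonical in ("animal_id", "date_of_birth", "date_of_end", "disposition"):
            if cfg.actual(canonical) not in header:
                raise ValueError(
                    f"required column {cfg.actual(canonical)!r} (for {canonical!r}) "
                    f"missing from {path}"
                )
        for row in reader:
            report.total_rows += 1
            try:
                rec = _row_to_record(row, cfg)
            except (DateParseError, ValueError) as exc:
                logger.warning("unparseable row %s: %s", row.get(cfg.actual("animal_id")), exc)
                report.excluded_unparseable += 1
                continue
            if rec.tier is None:
                logger.info("record %s excluded: missing birth or end date", rec.animal_id)
                report.excluded_missing += 1
                continue
            records.append(rec)
            report.add_tier(rec.tier, rec.event)
    _check_unique_ids(records)
    report.check_conservation()
    return records, report


def _row_to_record(row: Mapping[str, str], cfg: FormatConfig) -> AnimalRecord:
    get = lambda canonical: (row.get(cfg.actual(canonical)) or "").strip()

    compile_raw = get("compile_date")
    compile_date = cfg.default_compile_date
    if compile_raw and compile_raw.lower() not in _MISSING_TOKENS:
        spec = DateSpec.parse(compile_raw, cfg.dayfirst)
        if spec.resolution is not Resolution.DAY:
            raise DateParseError(f"compile_date must be day-resolution: {compile_raw!r}")
        compile_date = spec.payload

    disp_raw = get("disposition").lower()
    if disp_raw not in _DISPOSITION_MAP:
        raise ValueError(f"unknown disposition {get('disposition')!r}")
    disposition = _DISPOSITION_MAP[disp_raw]

    end_raw = get("date_of_end")
    end = DateSpec.parse(end_raw, cfg.dayfirst)
    if disposition is Disposition.ALIVE_AT_COMPILE:
        # living animals are censored at spreadsheet completion
        if compile_date is None:
            raise ValueError("ALIVE row without a compile_date")
        end = DateSpec.from_date(compile_date)
    elif disposition is Disposition.DEAD and end.resolution is Resolution.MISSING:
        disposition = Disposition.UNKNOWN_DEATH_DATE

    return AnimalRecord(
        animal_id=get("animal_id"),
        sex=_SEX_MAP.get(get("sex").lower(), Sex.UNKNOWN),
        breeder=get("breeder").lower() in _TRUE_TOKENS,
        birth=DateSpec.parse(get("date_of_birth"), cfg.dayfirst),
        end=end,
        disposition=disposition,
        compile_date=compile_date,
    )


def _check_unique_ids(records: Sequence[AnimalRecord]) -> None:
    seen = Counter(r.animal_id for r in records)
    dups = [k for k, v in seen.items() if v > 1]
    if dups:
        raise ValueError(f"duplicate animal_id(s): {dups[:5]}")


@dataclass
class ObservationBuild:
    """Result of turning records into observations, with exclusion accounting."""

    observations: list[LifespanObservation]
    excluded_pre_entry: int = 0
    excluded_unresolved: int = 0
    excluded_invalid: int = 0
    exclusion_log: list[tuple[str, str]] = field(default_factory=list)


def build_observations(
    records: Iterable[AnimalRecord],
    tier: Tier = Tier.DAY,
    start_day: int = T_SEX_DAYS,
) -> ObservationBuild:
    """Convert records to post-T_sex lifespan observations at a stringency tier.

    Lifespan is the whole-day difference between resolved end and birth dates
    (day-of-life counting is 0-based from birth).  Events strictly before
    *start_day* are dropped and counted; an event at exactly *start_day* is
    kept.  Dead animals contribute death events; alive-at-compile, sold and
    KFR animals contribute censorship events.  An animal with both a KFR
    label and a death record is treated as censored (the label wins) and the
    conflict is logged upstream at parse time.
    """
    out = ObservationBuild(observations=[])
    for rec in records:
        birth = resolve_date(rec.birth, tier)
        end = resolve_date(rec.end, tier)
        if birth is None or end is None:
            out.excluded_unresolved += 1
            continue
        if rec.disposition is Disposition.UNKNOWN_DEATH_DATE:
            out.excluded_unresolved += 1
            out.exclusion_log.append((rec.animal_id, "death date unknown"))
            continue
        lifespan = (end - birth).days
        if lifespan < 0:
            out.excluded_invalid += 1
            out.exclusion_log.append((rec.animal_id, f"end before birth ({lifespan} d)"))
            logger.warning("record %s invalid: end precedes birth", rec.animal_id)
            continue
        if lifespan < start_day:
            out.excluded_pre_entry += 1
            out.exclusion_log.append((rec.animal_id, f"event at day {lifespan} < {start_day}"))
            continue
        out.observations.append(
            LifespanObservation(
                animal_id=rec.animal_id,
                entry_day=start_day,
                exit_day=lifespan,
                event=rec.event,
                sex=rec.sex,
                breeder=rec.breeder,
                tier=tier,
            )
        )
    return out


def stratify(
    observations: Iterable[LifespanObservation],
    include_unknown_sex: bool = False,
) -> dict[tuple[Sex, bool], list[LifespanObservation]]:
    """Partition observations into (sex, breeder) strata.

    All four known-sex strata are always present (possibly empty).  Unknown-sex
    animals get their own strata when *include_unknown_sex* is set, and are
    excluded (with a log line) otherwise.
    """
    strata: dict[tuple[Sex, bool], list[LifespanObservation]] = {
        (sex, breeder): [] for sex in (Sex.FEMALE, Sex.MALE) for breeder in (False, True)
    }
    n_unknown = 0
    for obs in observations:
        if obs.sex is Sex.UNKNOWN and not include_unknown_sex:
            n_unknown += 1
            continue
        strata.setdefault(obs.stratum, []).append(obs)
    if n_unknown:
        logger.info("stratify: excluded %d unknown-sex observations", n_unknown)
    return strata


def write_observations(
    observations: Iterable[LifespanObservation], path: Union[str, Path]
) -> None:
    """Write observations as the canonical observation CSV."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["animal_id", "entry_day", "exit_day", "event", "sex", "breeder", "tier"])
        for o in observations:
            w.writerow(
                [o.animal_id, o.entry_day, o.exit_day, o.event.value,
                 o.sex.value, int(o.breeder), o.tier.name.lower()]
            )


def read_observations(path: Union[str, Path]) -> list[LifespanObservation]:
    """Read the canonical observation CSV back into observations."""
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(
                LifespanObservation(
                    animal_id=row["animal_id"],
                    entry_day=int(row["entry_day"]),
                    exit_day=int(row["exit_day"]),
                    event=Event(row["event"]),
                    sex=Sex(row["sex"]),
                    breeder=bool(int(row["breeder"])),
                    tier=Tier[row["tier"].upper()],
                )
            )
    return out
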