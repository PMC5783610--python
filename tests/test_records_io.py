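import csv
import datetime as dt

import pytest
from hypothesis import given, settings, strategies as st

from nmrsurv.records_io import (
    AnimalRecord,
    DateParseError,
    DateSpec,
    Disposition,
    Event,
    FormatConfig,
    Resolution,
    Sex,
    T_SEX_DAYS,
    Tier,
    build_observations,
    parse_collection,
    resolve_date,
    stratify,
)

D = dt.date


class TestResolveDate:
    @pytest.mark.parametrize(
        "text,tier,expected",
        [
            ("1995-06-17", Tier.DAY, D(1995, 6, 17)),
            ("June 1995", Tier.PLUS_MONTH, D(1995, 6, 15)),  # 15th-of-month midpoint
            ("~June 1995", Tier.PLUS_MONTH, D(1995, 6, 15)),  # approx same as exact
            ("1997", Tier.PLUS_LOW_RES, D(1997, 7, 2)),  # July 2 year midpoint
            ("~1997", Tier.PLUS_LOW_RES, D(1997, 7, 2)),
            ("Fall 1999", Tier.PLUS_LOW_RES, D(1999, 11, 7)),  # Nov 7 mid-Fall
            (">1997", Tier.PLUS_INEQUALITY, D(1998, 1, 1)),  # nearest satisfying
            ("<1997", Tier.PLUS_INEQUALITY, D(1996, 12, 31)),
        ],
    )
    def test_midpoint_conventions(self, text, tier, expected):
        assert resolve_date(DateSpec.parse(text), tier) == expected

    def test_range_midpoint_matches_calendar_arithmetic(self):
        start, end = D(1996, 1, 1), D(1998, 12, 31)
        oracle = start + dt.timedelta(days=(end - start).days // 2)
        got = resolve_date(DateSpec.parse("1996-01-01..1998-12-31"), Tier.PLUS_LOW_RES)
        assert got == oracle
        # year-resolution endpoints expand to the full span
        assert resolve_date(DateSpec.parse("1996..1998"), Tier.PLUS_LOW_RES) == oracle

    def test_two_options_resolve_to_midpoint(self):
        got = resolve_date(DateSpec.parse("1995-06-10 or 1995-06-20"), Tier.PLUS_LOW_RES)
        assert got == D(1995, 6, 15)

    @pytest.mark.parametrize(
        "text,min_tier",
        [
            ("June 1995", Tier.PLUS_MONTH),
            ("1997", Tier.PLUS_LOW_RES),
            ("Fall 1999", Tier.PLUS_LOW_RES),
            (">1997", Tier.PLUS_INEQUALITY),
        ],
    )
    def test_tier_admissibility_is_monotone(self, text, min_tier):
        """A spec is unresolved below its tier and resolves identically above it."""
        spec = DateSpec.parse(text)
        resolved = [resolve_date(spec, t) for t in Tier]
        for t in Tier:
            if t < min_tier:
                assert resolved[t] is None
            else:
                assert resolved[t] == resolved[min_tier]

    def test_missing_is_never_resolved(self):
        assert resolve_date(DateSpec.missing(), Tier.PLUS_INEQUALITY) is None

    @given(st.dates(min_value=D(1980, 1, 1), max_value=D(2020, 12, 31)))
    @settings(max_examples=50, deadline=None)
    def test_resolution_is_pure_and_consistent(self, d):
        """Identical month/year specs always impute the same date, within the span."""
        month_spec = DateSpec.parse(f"{d.year:04d}-{d.month:02d}")
        r1 = resolve_date(month_spec, Tier.PLUS_MONTH)
        r2 = resolve_date(DateSpec.parse(f"{d.year:04d}-{d.month:02d}"), Tier.PLUS_MONTH)
        assert r1 == r2
        assert (r1.year, r1.month) == (d.year, d.month)
        year_mid = resolve_date(DateSpec.parse(str(d.year)), Tier.PLUS_LOW_RES)
        assert year_mid == D(d.year, 7, 2)  # fixed, leap years included

    def test_garbage_raises(self):
        with pytest.raises(DateParseError):
            DateSpec.parse("the fifth of Octember")


def _write_csv(path, rows):
    cols = ["animal_id", "sex", "breeder", "date_of_birth", "date_of_end",
            "disposition", "compile_date"]
    with open(path, "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=cols)
        w.writeheader()
        w.writerows(rows)


def _row(i, birth="2000-01-01", end="2010-01-01", disposition="DEAD", sex="female",
         breeder="0", compile_date="2016-04-14"):
    return {
        "animal_id": f"{100000000 + i}",
        "sex": sex,
        "breeder": breeder,
        "date_of_birth": birth,
        "date_of_end": end,
        "disposition": disposition,
        "compile_date": compile_date,
    }


class TestParseCollection:
    def test_known_composition_round_trips_through_report(self, tmp_path):
        rows = [_row(i) for i in range(90)] + [_row(90 + i, birth="") for i in range(10)]
        path = tmp_path / "c.csv"
        _write_csv(path, rows)
        records, report = parse_collection(path)
        assert report.total_rows == 100
        assert report.excluded_missing == 10
        assert report.included == 90
        assert len(records) == 90
        report.check_conservation()

    def test_alive_rows_are_censored_at_compile_date(self, tmp_path):
        path = tmp_path / "c.csv"
        _write_csv(path, [_row(0, end="", disposition="ALIVE")])
        records, _ = parse_collection(path)
        rec = records[0]
        assert rec.disposition is Disposition.ALIVE_AT_COMPILE
        assert rec.end.payload == D(2016, 4, 14)
        assert rec.event is Event.CENSOR

    def test_unparseable_row_is_logged_not_fatal(self, tmp_path):
        path = tmp_path / "c.csv"
        _write_csv(path, [_row(0), _row(1, birth="garbage text")])
        records, report = parse_collection(path)
        assert len(records) == 1
        assert report.excluded_unparseable == 1
        report.check_conservation()

    def test_missing_required_column_is_fatal(self, tmp_path):
        path = tmp_path / "c.csv"
        with open(path, "w") as fh:
            fh.write("animal_id,sex\nx,female\n")
        with pytest.raises(ValueError, match="date_of_birth"):
            parse_collection(path)

    def test_column_mapping_via_format_config(self, tmp_path):
        path = tmp_path / "c.csv"
        with open(path, "w") as fh:
            fh.write("ID,DOB,DOD,STATUS\n900000001,2000-01-01,2010-01-01,DEAD\n")
        cfg = FormatConfig(columns={"animal_id": "ID", "date_of_birth": "DOB",
                                    "date_of_end": "DOD", "disposition": "STATUS"})
        records, _ = parse_collection(path, cfg)
        assert records[0].animal_id == "900000001"

    def test_duplicate_ids_rejected(self, tmp_path):
        path = tmp_path / "c.csv"
        rows = [_row(0), _row(0)]
        _write_csv(path, rows)
        with pytest.raises(ValueError, match="duplicate"):
            parse_collection(path)

    def test_tier_accounting_splits_deaths_and_censors(self, tmp_path):
        rows = [
            _row(0),  # day-resolution death
            _row(1, disposition="KFR"),  # day-resolution censor
            _row(2, birth="2000-06"),  # month-tier death
            _row(3, birth="1999", disposition="SOLD/GIVEN AWAY"),  # low-res censor
            _row(4, birth=">1998"),  # inequality death
        ]
        path = tmp_path / "c.csv"
        _write_csv(path, rows)
        _, report = parse_collection(path)
        added = {t.name: dict(c) for t, c in report.tier_added.items()}
        assert added["DAY"] == {"n": 2, "death": 1, "censor": 1}
        assert added["PLUS_MONTH"] == {"n": 1, "death": 1}
        assert added["PLUS_LOW_RES"] == {"n": 1, "censor": 1}
        assert added["PLUS_INEQUALITY"] == {"n": 1, "death": 1}


class TestBuildObservations:
    def _record(self, birth, end, disposition=Disposition.DEAD, **kw):
        return AnimalRecord(
            animal_id=kw.get("animal_id", "x1"),
            sex=kw.get("sex", Sex.FEMALE),
            breeder=kw.get("breeder", False),
            birth=DateSpec.from_date(birth),
            end=DateSpec.from_date(end),
            disposition=disposition,
            compile_date=D(2016, 4, 14),
        )

    def test_lifespan_is_whole_day_date_difference(self):
        rec = self._record(D(2000, 1, 1), D(2010, 1, 1))
        build = build_observations([rec], Tier.DAY)
        obs = build.observations[0]
        assert obs.exit_day == 3653  # includes leap days 2000/2004/2008
        assert obs.event is Event.DEATH
        assert obs.entry_day == T_SEX_DAYS

    def test_kfr_is_a_censorship_event(self):
        rec = self._record(D(2000, 1, 1), D(2005, 1, 1), Disposition.KFR)
        assert build_observations([rec], Tier.DAY).observations[0].event is Event.CENSOR

    def test_pre_maturity_events_are_dropped_and_counted(self):
        recs = [
            self._record(D(2000, 1, 1), D(2000, 1, 1) + dt.timedelta(days=d),
                         animal_id=f"x{d}")
            for d in (10, 50, 100, 150, 182)
        ] + [self._record(D(2000, 1, 1), D(2010, 1, 1), animal_id="keeper")]
        build = build_observations(recs, Tier.DAY)
        assert build.excluded_pre_entry == 5
        assert [o.animal_id for o in build.observations] == ["keeper"]

    def test_event_exactly_at_day_183_is_kept(self):
        rec = self._record(D(2000, 1, 1), D(2000, 1, 1) + dt.timedelta(days=183))
        build = build_observations([rec], Tier.DAY)
        assert len(build.observations) == 1
        assert build.observations[0].exit_day == 183

    def test_end_before_birth_is_flagged_invalid(self):
        rec = self._record(D(2010, 1, 1), D(2000, 1, 1))
        build = build_observations([rec], Tier.DAY)
        assert build.excluded_invalid == 1
        assert not build.observations

    def test_tier_monotonicity_observation_sets_nest(self):
        """Each stringency tier's observation set contains the previous tier's."""
        recs = [self._record(D(2000, 1, 1), D(2010, 1, 1), animal_id="d1")]
        recs.append(AnimalRecord("m1", Sex.MALE, False, DateSpec.parse("2000-06"),
                                 DateSpec.from_date(D(2010, 1, 1)), Disposition.DEAD,
                                 D(2016, 4, 14)))
        recs.append(AnimalRecord("y1", Sex.MALE, False, DateSpec.parse("1999"),
                                 DateSpec.from_date(D(2010, 1, 1)), Disposition.KFR,
                                 D(2016, 4, 14)))
        recs.append(AnimalRecord("i1", Sex.FEMALE, False, DateSpec.parse(">1998"),
                                 DateSpec.from_date(D(2010, 1, 1)), Disposition.DEAD,
                                 D(2016, 4, 14)))
        previous: set[str] = set()
        for tier in Tier:
            ids = {o.animal_id for o in build_observations(recs, tier).observations}
            assert previous <= ids
            previous = ids
        assert previous == {"d1", "m1", "y1", "i1"}


class TestStratify:
    def _obs(self, sex, breeder, i):
        from helpers import make_obs

        return make_obs(1000, Event.DEATH, sex=sex, breeder=breeder)

    def test_four_singleton_strata(self):
        obs = [self._obs(s, b, i) for i, (s, b) in enumerate(
            [(Sex.FEMALE, False), (Sex.FEMALE, True), (Sex.MALE, False), (Sex.MALE, True)])]
        strata = stratify(obs)
        assert all(len(v) == 1 for v in strata.values())
        assert len(strata) == 4

    def test_all_female_input_leaves_male_strata_empty_not_absent(self):
        obs = [self._obs(Sex.FEMALE, False, i) for i in range(3)]
        strata = stratify(obs)
        assert (Sex.MALE, False) in strata and strata[(Sex.MALE, False)] == []
        assert (Sex.MALE, True) in strata and strata[(Sex.MALE, True)] == []
        assert len(strata[(Sex.FEMALE, False)]) == 3

    def test_partition_is_exhaustive_and_disjoint(self):
        obs = [self._obs(s, b, i) for i, (s, b) in enumerate(
            [(Sex.FEMALE, False)] * 5 + [(Sex.MALE, True)] * 3)]
        strata = stratify(obs)
        assert sum(len(v) for v in strata.values()) == len(obs)

    def test_unknown_sex_excluded_by_default_included_on_request(self):
        obs = [self._obs(Sex.UNKNOWN, False, 0)]
        assert sum(len(v) for v in stratify(obs).values()) == 0
        strata = stratify(obs, include_unknown_sex=True)
        assert len(strata[(Sex.UNKNOWN, False)]) == 1
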