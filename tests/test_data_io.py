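"""Ingestion, validation, and the three inclusion filters."""

import numpy as np
import pandas as pd
import pytest

from bacipln import data_io
from bacipln.data_io import (
    DEFAULT_EXCLUSIONS,
    PeriodDefinition,
    SchemaError,
    ValidationError,
    apply_lake_exclusions,
    assign_periods,
    filter_consistent_stations,
    plan_station_filter,
    read_catch_table,
    write_canonical_csv,
)

from conftest import make_table, random_table


class TestReadCatchTable:
    def test_three_row_csv_roundtrip(self, tmp_path):
        p = tmp_path / "toy.csv"
        p.write_text(
            "lake,station,year,species,count,role\n"
            "LakeX,A,1995,Walleye,3,impact\n"
            "LakeX,A,1996,Walleye,0,impact\n"
            "LakeX,B,1995,Walleye,7,impact\n"
        )
        table = read_catch_table(p)
        assert len(table) == 3
        assert table.provenance[0]["action"] == "read"
        assert "toy.csv" in table.provenance[0]["detail"]
        assert list(table.records["count"]) == [3, 0, 7]

    def test_negative_count_cites_row(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text(
            "lake,station,year,species,count,role\n"
            "L,A,1995,Walleye,3,impact\n"
            "L,A,1996,Walleye,-1,impact\n"
        )
        with pytest.raises(ValidationError, match="row 2"):
            read_catch_table(p)

    def test_missing_column_named(self, tmp_path):
        p = tmp_path / "noc.csv"
        p.write_text("lake,station,year,species,role\nL,A,1995,W,impact\n")
        with pytest.raises(SchemaError, match="count"):
            read_catch_table(p)

    def test_schema_mapping_and_role_fill(self, tmp_path):
        p = tmp_path / "mapped.csv"
        p.write_text("Waterbody,Site,SurveyYear,Spp,N\nRainy Lake,A,1995,Walleye,4\n")
        table = read_catch_table(
            p,
            schema={
                "lake": "Waterbody",
                "station": "Site",
                "year": "SurveyYear",
                "species": "Spp",
                "count": "N",
            },
        )
        assert table.records.loc[0, "role"] == "impact"

    def test_xlsx_ingestion(self, tmp_path):
        p = tmp_path / "toy.xlsx"
        pd.DataFrame(
            {
                "lake": ["Rainy Lake"],
                "station": ["A"],
                "year": [1995],
                "species": ["Walleye"],
                "count": [2],
            }
        ).to_excel(p, index=False)
        table = read_catch_table(p)
        assert len(table) == 1 and table.records.loc[0, "role"] == "impact"

    def test_date_column_truncated_to_year(self, tmp_path):
        p = tmp_path / "dates.csv"
        df = pd.DataFrame(
            {
                "lake": ["Rainy Lake"],
                "station": ["A"],
                "year": pd.to_datetime(["1995-06-15"]),
                "species": ["Walleye"],
                "count": [2],
                "role": ["impact"],
            }
        )
        df.to_csv(p, index=False)
        table = read_catch_table(p)
        assert table.records.loc[0, "year"] == 1995


class TestStationConsistency:
    def test_incomplete_station_removed(self, toy_table):
        out = filter_consistent_stations(toy_table)
        assert set(out.records["station"]) == {"A"}
        assert "LakeX/B" in out.provenance[-1]["detail"]

    def test_complete_table_identity(self):
        rows = [
            ("L", s, y, "Walleye", 1, "impact")
            for s in ("A", "B")
            for y in (1995, 1996)
        ]
        table = make_table(rows)
        out = filter_consistent_stations(table)
        assert len(out) == len(table)

    def test_matches_brute_force_recount(self):
        """Retained count equals an independent per-station year-set scan."""
        rng = np.random.default_rng(42)
        for _ in range(5):
            table = random_table(rng, drop_frac=0.1)
            out = filter_consistent_stations(table, exclusions=[])
            df = table.records
            expected = 0
            for (lake, station), sub in df.groupby(["lake", "station"]):
                lake_years = set(df.loc[df["lake"] == lake, "year"])
                if lake_years <= set(sub["year"]):
                    expected += len(sub)
            assert len(out) == expected

    def test_per_period_mode_is_looser_than_strict(self):
        # A covers every lake year; B misses 1996 but has one year per period
        rows = [("L", "A", y, "Walleye", 1, "impact") for y in (1995, 1996, 2006)]
        rows += [("L", "B", y, "Walleye", 1, "impact") for y in (1995, 2006)]
        table = make_table(rows)
        strict = filter_consistent_stations(table, exclusions=[])
        loose = filter_consistent_stations(table, mode="per-period", exclusions=[])
        assert set(strict.records["station"]) == {"A"}
        assert set(loose.records["station"]) == {"A", "B"}

    def test_empty_mode_rejected(self, toy_table):
        with pytest.raises(ValueError, match="mode"):
            filter_consistent_stations(toy_table, mode="bogus")


class TestLakeExclusions:
    def test_default_rules_drop_namakan_early_years(self):
        rows = [
            ("Namakan Lake", "A", y, "Walleye", 1, "impact")
            for y in (1990, 1991, 1992, 1993)
        ]
        out = apply_lake_exclusions(make_table(rows))
        assert list(out.records["year"]) == [1993]

    def test_empty_rules_identity(self, toy_table):
        out = apply_lake_exclusions(toy_table, rules=[])
        assert len(out) == len(toy_table)

    def test_single_year_rule(self):
        rows = [("LakeX", "A", y, "W", 1, "impact") for y in (1994, 1995, 1996)]
        out = apply_lake_exclusions(make_table(rows), rules=[("LakeX", (1995, 1995))])
        assert list(out.records["year"]) == [1994, 1996]

    def test_absent_lake_rule_is_noop(self, toy_table):
        out = apply_lake_exclusions(toy_table, rules=[("Nowhere", (1990, 2014))])
        assert len(out) == len(toy_table)
        assert "absent" in out.provenance[-1]["detail"]


class TestAssignPeriods:
    def test_pre_gap_post_labels(self):
        rows = [("L", "A", y, "W", 1, "impact") for y in (1999, 2002, 2005)]
        out = assign_periods(make_table(rows))
        assert list(out.records["year"]) == [1999, 2005]
        assert list(out.records["period"]) == ["pre", "post"]

    def test_all_before(self):
        rows = [("L", "A", y, "W", 1, "impact") for y in (1991, 1995, 1999)]
        out = assign_periods(make_table(rows))
        assert set(out.records["period"]) == {"pre"}

    def test_matches_membership_recount(self):
        rng = np.random.default_rng(3)
        years = rng.integers(1985, 2020, size=200)
        rows = [("L", "A", int(y), "W", 1, "impact") for y in years]
        out = assign_periods(make_table(rows))
        expected = sum(1 for y in years if 1990 <= y <= 1999 or 2005 <= y <= 2014)
        assert len(out) == expected

    def test_caption_variant_period(self):
        periods = PeriodDefinition((1990, 1999), (2006, 2014))
        rows = [("L", "A", 2005, "W", 1, "impact")]
        out = assign_periods(make_table(rows), periods)
        assert len(out) == 0

    def test_invalid_periods_rejected(self):
        with pytest.raises(ValueError):
            PeriodDefinition((1990, 1999), (1995, 2014))


class TestFilterProperties:
    """Idempotence, commutation and record conservation on random tables."""

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_idempotent(self, seed):
        rng = np.random.default_rng(seed)
        table = random_table(rng)
        plan = plan_station_filter(table)
        for f in (
            lambda t: filter_consistent_stations(t, plan=plan),
            lambda t: apply_lake_exclusions(t, [("L0", (1995, 1999))]),
            assign_periods,
        ):
            once = f(table)
            twice = f(once)
            pd.testing.assert_frame_equal(
                once.records.reset_index(drop=True), twice.records.reset_index(drop=True)
            )

    @pytest.mark.parametrize("seed", [3, 4, 5])
    def test_commute_with_shared_plan(self, seed):
        """With the station plan fixed from the raw table, all three filters
        are row predicates and any application order gives the same records."""
        rng = np.random.default_rng(seed)
        table = random_table(rng, drop_frac=0.04)
        rules = [("L1", (1992, 1994))]
        plan = plan_station_filter(table, exclusions=rules)
        filters = [
            lambda t: filter_consistent_stations(t, plan=plan),
            lambda t: apply_lake_exclusions(t, rules),
            assign_periods,
        ]
        import itertools

        results = []
        for order in itertools.permutations(filters):
            t = table
            for f in order:
                t = f(t)
            results.append(
                t.records.sort_values(["lake", "station", "year"]).reset_index(drop=True)
            )
        for r in results[1:]:
            pd.testing.assert_frame_equal(results[0], r)

    @pytest.mark.parametrize("seed", [6, 7])
    def test_record_conservation(self, seed):
        rng = np.random.default_rng(seed)
        table = random_table(rng)
        out = assign_periods(
            apply_lake_exclusions(filter_consistent_stations(table))
        )
        for entry in out.provenance:
            assert entry["n_in"] == entry["n_out"] + entry["n_removed"]
        removed = sum(e["n_removed"] for e in out.provenance)
        assert len(table) == len(out) + removed


def test_canonical_csv_roundtrip(tmp_path, toy_table):
    p = tmp_path / "canon.csv"
    log = tmp_path / "log.txt"
    toy_table.provenance.append(
        {"action": "demo", "n_in": 5, "n_out": 5, "n_removed": 0, "detail": ""}
    )
    write_canonical_csv(toy_table, p, log)
    back = read_catch_table(p)
    assert len(back) == len(toy_table)
    assert "demo" in log.read_text()
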