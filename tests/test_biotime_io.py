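import io
import textwrap

import numpy as np
import pandas as pd
import pytest

from lagturn import biotime_io
from lagturn.synthetic_data import SyntheticConfig, generate_ensemble

CANON = {c: c for c in biotime_io.REQUIRED_COLUMNS + biotime_io.OPTIONAL_COLUMNS}


def _csv(tmp_path, text, name="t.csv"):
    p = tmp_path / name
    p.write_text(textwrap.dedent(text))
    return p


class TestReadSurveyTable:
    def test_duplicates_collapsed(self, tmp_path):
        p = _csv(
            tmp_path,
            """\
            study_id,community_id,year,sample_id,species_id
            s1,c1,2000,a,fox
            s1,c1,2000,a,fox
            s1,c1,2001,a,owl
            """,
        )
        df = biotime_io.read_survey_table(p, dialect=CANON)
        assert len(df) == 2
        assert df.attrs["n_duplicates"] == 1

    def test_missing_species_column_named_in_error(self, tmp_path):
        p = _csv(
            tmp_path,
            """\
            study_id,community_id,year,sample_id
            s1,c1,2000,a
            """,
        )
        with pytest.raises(ValueError, match="species_id"):
            biotime_io.read_survey_table(p, dialect=CANON)

    def test_unparseable_year_rejected_with_warning(self, tmp_path):
        p = _csv(
            tmp_path,
            """\
            study_id,community_id,year,sample_id,species_id
            s1,c1,not-a-year,a,fox
            s1,c1,2001,a,owl
            """,
        )
        with pytest.warns(UserWarning, match="rejected 1"):
            df = biotime_io.read_survey_table(p, dialect=CANON)
        assert len(df) == 1 and df.attrs["n_rejected"] == 1


class TestFilterMinYear:
    def test_cutoff_year_is_retained(self):
        df = pd.DataFrame({"year": [1925, 1927, 1930]})
        kept, removed = biotime_io.filter_min_year(df, 1927)
        assert sorted(kept["year"]) == [1927, 1930] and removed == 1

    def test_empty_input(self):
        kept, removed = biotime_io.filter_min_year(pd.DataFrame({"year": []}), 1927)
        assert len(kept) == 0 and removed == 0

    def test_generator_ledger_reconciles_pre_cutoff_count(self):
        cfg = SyntheticConfig(
            n_communities=4, years=(1920, 1940), seed=5, missing_year_prob=0.0
        )
        records, ledger = generate_ensemble(cfg)
        kept, removed = biotime_io.filter_min_year(records)
        assert removed == ledger["n_pre_cutoff"] > 0
        assert len(kept) + removed == ledger["n_records"] == len(records)


def _records(lat, lon, study="s1"):
    n = len(lat)
    return pd.DataFrame(
        {
            "study_id": study,
            "community_id": study,
            "year": 2000,
            "sample_id": "a",
            "species_id": [f"sp{i}" for i in range(n)],
            "latitude": lat,
            "longitude": lon,
            "taxon_group": "all",
        }
    )


class TestPartitionGrid:
    def test_small_extent_single_community(self):
        df = _records([0.0, 0.005, 0.009], [0.0, 0.005, 0.009])  # ~1 km x 1 km
        out = biotime_io.partition_grid(df)
        assert out["community_id"].nunique() == 1

    def test_two_cell_study_split_exactly(self):
        # ~10 km tall, ~13 km wide: bbox > 96 km^2, spans two 10-km grid columns
        lat = [0.0, 0.089, 0.0, 0.089]
        lon = [0.0, 0.0, 0.12, 0.12]
        out = biotime_io.partition_grid(_records(lat, lon))
        groups = out.groupby("community_id").size()
        assert len(groups) == 2 and set(groups) == {2}

    def test_record_conservation_over_four_cells(self):
        rng = np.random.default_rng(0)
        df = _records(rng.uniform(0, 0.18, 100), rng.uniform(0, 0.18, 100))
        out = biotime_io.partition_grid(df)
        assert len(out) == 100
        assert out["community_id"].nunique() == 4
        assert out.groupby("community_id").size().sum() == 100

    def test_missing_coordinates_skipped_with_warning(self):
        df = _records([0.0, 0.5], [0.0, 0.5])
        df.loc[0, "latitude"] = np.nan
        with pytest.warns(UserWarning, match="incomplete coordinates"):
            out = biotime_io.partition_grid(df)
        assert out["community_id"].nunique() == 1


class TestBuildSeries:
    def test_round_trip_identity_on_record_multisets(self):
        cfg = SyntheticConfig(n_communities=3, years=(1990, 2000), seed=2,
                              samples_per_year=(1, 3), false_negative_rate=0.2)
        records, _ = generate_ensemble(cfg)
        series = biotime_io.build_series(records)
        back = pd.concat([biotime_io.flatten_series(s) for s in series])
        key = ["community_id", "year", "sample_id", "species_id"]
        left = records[key].sort_values(key).reset_index(drop=True)
        right = back[key].sort_values(key).reset_index(drop=True)
        right["year"] = right["year"].astype(left["year"].dtype)
        pd.testing.assert_frame_equal(left, right)

    def test_gap_year_preserved(self):
        df = pd.DataFrame(
            {
                "study_id": "s", "community_id": "c",
                "year": [2000, 2002], "sample_id": "a",
                "species_id": ["x", "y"], "taxon_group": "all",
            }
        )
        (series,) = biotime_io.build_series(df)
        assert series.years == [2000, 2002]

    def test_richness_totals_match_generator_ledger(self):
        cfg = SyntheticConfig(n_communities=5, years=(1980, 1999), seed=9)
        records, ledger = generate_ensemble(cfg)
        series = biotime_io.build_series(records)
        assert len(series) == 5
        for s in series:
            meta = ledger["communities"][s.community_id]
            truth = set().union(*(set(v) for v in meta["true_compositions"].values()))
            assert s.species <= truth  # observed species all attributable to truth
            n_recs = sum(len(sp) for sp in s.presence.values())
            assert n_recs == meta["n_records"]


class TestClimateIO:
    def test_valid_series(self, tmp_path):
        p = tmp_path / "c.csv"
        p.write_text("year,anom\n" + "\n".join(f"{y},{0.01*y}" for y in range(1900, 1911)))
        s = biotime_io.read_climate(p)
        assert s.years[0] == 1900 and len(s.years) == 11

    def test_gap_is_error(self, tmp_path):
        p = tmp_path / "c.csv"
        p.write_text("year,anom\n1900,0.1\n1902,0.2\n")
        with pytest.raises(ValueError, match="consecutive"):
            biotime_io.read_climate(p)

    def test_constant_series(self, tmp_path):
        p = tmp_path / "c.csv"
        p.write_text("year,anom\n" + "\n".join(f"{y},0.3" for y in range(2000, 2005)))
        s = biotime_io.read_climate(p)
        assert np.all(s.values == 0.3)
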