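"""Region lists, table validation and hemispheric pairing."""

import numpy as np
import pandas as pd
import pytest

from neuroasym import (
    DK_REGIONS,
    PFIT_REGIONS,
    NON_PFIT_REGIONS,
    TRACTS,
    RegionPartition,
    default_partition,
    pair_hemispheres,
    read_regional_csv,
    read_wide_regional_csv,
)
from neuroasym.io import RegionalMetricTable, validate_regional, write_regional_csv
from neuroasym.errors import SchemaError, UnknownRegionError, ValidationError


class TestPartition:
    def test_canonical_counts(self):
        assert len(DK_REGIONS) == 34
        assert len(PFIT_REGIONS) == 10
        assert len(NON_PFIT_REGIONS) == 24
        assert len(TRACTS) == 5
        assert set(PFIT_REGIONS) | set(NON_PFIT_REGIONS) == set(DK_REGIONS)
        assert not set(PFIT_REGIONS) & set(NON_PFIT_REGIONS)

    def test_pfit_membership_is_the_frontoparietal_set(self):
        expected = {
            "caudalmiddlefrontal", "frontalpole", "fusiform",
            "inferiorparietal", "lateralorbitofrontal", "medialorbitofrontal",
            "rostralmiddlefrontal", "superiorfrontal", "superiorparietal",
            "supramarginal",
        }
        assert set(PFIT_REGIONS) == expected

    def test_invalid_partition_rejected(self):
        with pytest.raises(ValueError):
            RegionPartition(cortical_regions=("a", "b"), pfit_members=("c",))

    def test_members_selector(self):
        part = default_partition()
        assert part.members("pfit") == PFIT_REGIONS
        assert part.members("all", "fa") == TRACTS
        with pytest.raises(ValueError):
            part.members("pfit", "fa")


class TestReadValidate:
    def _write(self, tmp_path, rows):
        path = tmp_path / "t.csv"
        pd.DataFrame(rows).to_csv(path, index=False)
        return path

    def test_minimal_two_row_file(self, tmp_path):
        path = self._write(tmp_path, [
            {"participant_id": "p1", "region": "bankssts", "hemisphere": "L", "value": 2.0},
            {"participant_id": "p1", "region": "bankssts", "hemisphere": "R", "value": 1.0},
        ])
        table = read_regional_csv(path, "thickness")
        paired = pair_hemispheres(table)
        assert paired.n_pairs == 1
        assert len(table.participants) == 1

    def test_negative_thickness_lists_row(self, tmp_path):
        path = self._write(tmp_path, [
            {"participant_id": "p1", "region": "bankssts", "hemisphere": "L", "value": -1.0},
            {"participant_id": "p1", "region": "bankssts", "hemisphere": "R", "value": 1.0},
        ])
        with pytest.raises(ValidationError, match="row 0"):
            read_regional_csv(path, "thickness")

    def test_fa_bounds(self):
        df = pd.DataFrame({"participant_id": ["p1"], "region": ["arcuate_fasciculus"],
                           "hemisphere": ["L"], "value": [1.2]})
        with pytest.raises(ValidationError):
            validate_regional(df, "fa")

    def test_missing_column_is_schema_error(self):
        with pytest.raises(SchemaError):
            validate_regional(pd.DataFrame({"participant_id": [], "region": []}),
                              "thickness")

    def test_duplicate_cell_rejected(self):
        df = pd.DataFrame({"participant_id": ["p1", "p1"], "region": ["bankssts"] * 2,
                           "hemisphere": ["L", "L"], "value": [1.0, 2.0]})
        with pytest.raises(ValidationError, match="duplicate"):
            validate_regional(df, "thickness")

    def test_unknown_region_error(self):
        df = pd.DataFrame({"participant_id": ["p1"], "region": ["nonexistent"],
                           "hemisphere": ["L"], "value": [1.0]})
        with pytest.raises(UnknownRegionError):
            validate_regional(df, "thickness", default_partition())

    def test_round_trip_full_precision(self, tmp_path, small_cohort):
        table = small_cohort.regional["thickness"]
        out = tmp_path / "rt.csv"
        write_regional_csv(table, out)
        back = read_regional_csv(out, "thickness")
        np.testing.assert_array_equal(back.data["value"].to_numpy(),
                                      table.data["value"].to_numpy())

    def test_wide_reader_normalizes_to_long(self, tmp_path):
        wide = pd.DataFrame({"participant_id": ["p1", "p2"],
                             "lh_bankssts": [2.0, 2.1], "rh_bankssts": [1.9, 2.2]})
        path = tmp_path / "w.csv"
        wide.to_csv(path, index=False)
        table = read_wide_regional_csv(path, "thickness")
        assert len(table.data) == 4
        assert set(table.data["hemisphere"]) == {"L", "R"}


class TestPairing:
    def test_synthetic_cohort_pairs_all_34_regions(self, small_cohort):
        paired = pair_hemispheres(small_cohort.regional["surface_area"])
        assert paired.data["region"].nunique() == 34
        assert paired.n_pairs == 200 * 34
        assert len(paired.flags) == 0

    def test_five_tract_pairs(self, small_cohort):
        paired = pair_hemispheres(small_cohort.regional["fa"])
        assert paired.data["region"].nunique() == 5

    def test_single_hemisphere_flagged_and_dropped(self):
        df = pd.DataFrame({"participant_id": ["p1", "p2", "p2"],
                           "region": ["bankssts"] * 3,
                           "hemisphere": ["L", "L", "R"], "value": [1.0, 1.1, 0.9]})
        table = RegionalMetricTable(metric="thickness", data=df)
        paired = pair_hemispheres(table)
        assert paired.n_pairs == 1
        assert len(paired.flags) == 1
        assert paired.flags.iloc[0]["participant_id"] == "p1"

    def test_pair_count_matches_brute_force(self):
        rng = np.random.default_rng(5)
        for trial in range(10):
            rows = []
            for pid in range(4):
                for region in ("bankssts", "cuneus", "insula"):
                    for hemi in ("L", "R"):
                        if rng.random() < 0.7:
                            rows.append({"participant_id": f"p{pid}",
                                         "region": region, "hemisphere": hemi,
                                         "value": rng.uniform(1, 3)})
            if not rows:
                continue
            df = pd.DataFrame(rows).drop_duplicates(
                subset=["participant_id", "region", "hemisphere"])
            expected = sum(
                1 for (_, _), grp in df.groupby(["participant_id", "region"])
                if set(grp["hemisphere"]) == {"L", "R"}
            )
            table = RegionalMetricTable(metric="thickness", data=df)
            assert pair_hemispheres(table).n_pairs == expected
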