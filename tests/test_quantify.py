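import math

import numpy as np
import pandas as pd
import pytest

import uvtrace as uv
from uvtrace.atlas import ZONE_NAMES, default_atlas
from uvtrace.quantify import (
    TABLE_COLUMNS,
    aggregate_roles,
    contamination_ratio,
    map_to_image,
    normalise_team_maps,
    stage_accumulation,
    zonal_areas,
)
from uvtrace.segmentation import LabelMask

SHAPE = (256, 128)


def make_rows(records):
    """records: (team, subject, role, stage, dye, zone, area)"""
    return pd.DataFrame(list(records), columns=list(TABLE_COLUMNS))


def fill_zones(table):
    """Complete a sparse spec of areas with explicit zero rows so the
    table satisfies the fixed 9-zones-per-dye schema."""
    full = []
    for (team, subject, role, stage, dye), sub in table.groupby(
        ["team", "subject", "role", "stage", "dye"]
    ):
        present = dict(zip(sub["zone"], sub["area_px"]))
        for zone in ZONE_NAMES:
            full.append((team, subject, role, stage, dye, zone, present.get(zone, 0)))
    return make_rows(full)


class TestZonalAreas:
    @pytest.fixture(scope="class")
    def atlas(self):
        return default_atlas(SHAPE)

    def test_empty_labels_give_zero_for_every_zone_and_dye(self, atlas):
        labels = LabelMask(np.zeros(SHAPE, np.uint8), ("green", "blue", "red"))
        rows, qc = zonal_areas(labels, atlas.zones, dict(team="A", subject="A1", role="one", stage="post_pi"))
        assert len(rows) == 27  # 9 zones x 3 dyes
        assert (rows["area_px"] == 0).all()
        assert (qc["overexposed_px"] == 0).all()

    def test_constructed_counts_match_brute_force(self, atlas):
        arr = np.zeros(SHAPE, np.uint8)
        head_px = np.argwhere(atlas.zones["head"])[:10]
        hand_px = np.argwhere(atlas.zones["hands"])[:5]
        arr[head_px[:, 0], head_px[:, 1]] = 1  # green
        arr[hand_px[:, 0], hand_px[:, 1]] = 1
        labels = LabelMask(arr, ("green", "blue", "red"))
        rows, _ = zonal_areas(labels, atlas.zones, dict(team="A", subject="A1", role="one", stage="post_pi"))
        lookup = rows.set_index(["dye", "zone"])["area_px"]
        assert lookup[("green", "head")] == 10
        assert lookup[("green", "hands")] == 5
        assert lookup[("blue", "head")] == 0

    def test_overexposed_and_excluded_reported_separately(self, atlas):
        arr = np.zeros(SHAPE, np.uint8)
        head = np.argwhere(atlas.zones["head"])
        arr[head[:7, 0], head[:7, 1]] = 255
        arr[head[7:12, 0], head[7:12, 1]] = 254
        labels = LabelMask(arr, ("green",))
        rows, qc = zonal_areas(labels, atlas.zones, dict(team="A", subject="A1", role="one", stage="post_pi"))
        assert (rows["area_px"] == 0).all()
        head_qc = qc[qc["zone"] == "head"].iloc[0]
        assert head_qc["overexposed_px"] == 7
        assert head_qc["excluded_px"] == 5

    def test_dimension_mismatch_rejected(self, atlas):
        labels = LabelMask(np.zeros((64, 64), np.uint8), ("green",))
        with pytest.raises(ValueError, match="shape"):
            zonal_areas(labels, atlas.zones, dict(team="A", subject="A1", role="one", stage="post_pi"))


class TestStageAccumulation:
    def test_single_stage_subject_series_length_one(self):
        table = fill_zones(make_rows([("obs", "OBS1", "control", "post_pi", "green", "hands", 42)]))
        series, flags = stage_accumulation(table)
        green = series[(series.subject == "OBS1") & (series.dye == "green")]
        assert len(green) == 1
        assert green["total_px"].iloc[0] == 42

    def test_residual_flag_raised_above_ten_percent(self):
        rows = []
        for stage, area in [("pre_don", 0), ("post_don", 0), ("post_pi", 400), ("post_doff", 60)]:
            rows.append(("A", "A1", "one", stage, "green", "hands", area))
        table = fill_zones(make_rows(rows))
        _, flags = stage_accumulation(table, residual_fraction=0.10)
        flag = flags[flags.subject == "A1"].iloc[0]
        assert flag["residual_fraction"] == pytest.approx(60 / 400)  # 0.15 > 0.10
        assert bool(flag["flagged"])

    def test_no_flag_at_or_below_threshold(self):
        rows = [("A", "A1", "one", "post_pi", "green", "hands", 400),
                ("A", "A1", "one", "post_doff", "green", "hands", 40)]
        _, flags = stage_accumulation(fill_zones(make_rows(rows)), residual_fraction=0.10)
        assert not bool(flags.iloc[0]["flagged"])

    def test_stage_order_preserved(self):
        rows = [("A", "A1", "one", s, "green", "hands", a)
                for s, a in [("post_doff", 10), ("pre_don", 1), ("post_pi", 100), ("post_don", 2)]]
        series, _ = stage_accumulation(fill_zones(make_rows(rows)))
        green = series[series.dye == "green"]
        assert green["stage"].tolist() == ["pre_don", "post_don", "post_pi", "post_doff"]
        assert green["total_px"].tolist() == [1, 2, 100, 10]


class TestTeamMaps:
    def test_single_nonzero_cell_self_normalises_to_one(self):
        table = fill_zones(make_rows([("A", "A1", "one", "post_pi", "green", "hands", 17)]))
        nmap = normalise_team_maps(table)
        assert nmap.value("A", "green", "hands") == 1.0

    def test_team_sums_normalised_to_cross_team_maximum(self):
        rows = [("A", "A1", "one", "post_pi", "green", "hands", 40),
                ("B", "B1", "one", "post_pi", "green", "hands", 80),
                ("C", "C1", "one", "post_pi", "green", "hands", 20)]
        nmap = normalise_team_maps(fill_zones(make_rows(rows)))
        assert nmap.value("A", "green", "hands") == pytest.approx(0.5)
        assert nmap.value("B", "green", "hands") == pytest.approx(1.0)
        assert nmap.value("C", "green", "hands") == pytest.approx(0.25)

    def test_all_zero_dye_stays_zero_without_error(self):
        table = fill_zones(make_rows([("A", "A1", "one", "post_pi", "red", "head", 0)]))
        nmap = normalise_team_maps(table)
        assert (nmap.table[nmap.table.dye == "red"]["value"] == 0).all()

    def test_patient_rows_not_counted_in_team_maps(self):
        rows = [("A", "A1", "one", "post_pi", "green", "hands", 10),
                ("A", "AP", "patient", "post_pi", "green", "hands", 9000)]
        nmap = normalise_team_maps(fill_zones(make_rows(rows)))
        assert nmap.value("A", "green", "hands") == 1.0  # normalised by 10, not 9010


class TestRoleMaps:
    def test_role_sums_normalised_per_dye(self):
        rows = [("A", "A1", "one", "post_pi", "green", "hands", 30),
                ("A", "A2", "two", "post_pi", "green", "hands", 60),
                ("A", "A3", "three", "post_pi", "green", "hands", 60)]
        nmap = aggregate_roles(fill_zones(make_rows(rows)))
        assert nmap.value("one", "green", "hands") == pytest.approx(0.5)
        assert nmap.value("two", "green", "hands") == pytest.approx(1.0)
        assert nmap.value("three", "green", "hands") == pytest.approx(1.0)

    def test_spit_free_role_maps_to_zero(self):
        rows = [("A", "A1", "one", "post_pi", "red", "head", 50),
                ("A", "A2", "two", "post_pi", "red", "thorax_upper_right", 5),
                ("A", "A3", "three", "post_pi", "red", "head", 0)]
        nmap = aggregate_roles(fill_zones(make_rows(rows)))
        three = nmap.table[(nmap.table.role == "three") & (nmap.table.dye == "red")]
        assert (three["value"] == 0).all()

    def test_only_post_pi_stage_enters(self):
        rows = [("A", "A1", "one", "post_pi", "green", "hands", 10),
                ("A", "A1", "one", "post_doff", "green", "hands", 999)]
        nmap = aggregate_roles(fill_zones(make_rows(rows)))
        assert nmap.value("one", "green", "hands") == 1.0


class TestContaminationRatio:
    @staticmethod
    def staff_table(totals):
        rows = [("A", f"A{i+1}", role, "post_pi", "green", "hands", t)
                for i, (role, t) in enumerate(zip(("one", "two", "three"), totals))]
        return fill_zones(make_rows(rows))

    @staticmethod
    def control_table(total):
        return fill_zones(make_rows([("obs", "OBS1", "control", "post_pi", "green", "hands", total)]))

    def test_identical_totals_give_unity(self):
        assert contamination_ratio(self.staff_table([5, 5, 5]), self.control_table(5)).value == pytest.approx(1.0)

    def test_mean_forty_six_over_two_gives_twenty_three(self):
        assert contamination_ratio(self.staff_table([46, 46, 46]), self.control_table(2)).value == pytest.approx(23.0)

    def test_hand_computed_mean_ratio(self):
        # mean(30, 40, 50) / 4 = 10
        result = contamination_ratio(self.staff_table([30, 40, 50]), self.control_table(4))
        assert result.value == pytest.approx(10.0)
        assert result.staff_mean == pytest.approx(40.0)

    def test_zero_control_yields_explicit_undefined_status(self):
        result = contamination_ratio(self.staff_table([30, 40, 50]), self.control_table(0))
        assert result.status == "undefined"
        assert math.isnan(result.value)


class TestInvariants:
    def test_normalised_maps_in_unit_interval_with_exact_max_one(self, small_truth):
        table = small_truth.truth_table()
        for nmap in (normalise_team_maps(table), aggregate_roles(table)):
            nmap.validate()
            vals = nmap.table["value"]
            assert vals.between(0, 1).all()
            for dye, sub in nmap.table.groupby("dye"):
                if (sub["value"] > 0).any():
                    assert sub["value"].max() == 1.0

    def test_scale_invariance_of_maps_and_ratio(self):
        staff = TestContaminationRatio.staff_table([30, 40, 50])
        control = TestContaminationRatio.control_table(4)
        scaled_staff, scaled_control = staff.copy(), control.copy()
        scaled_staff["area_px"] *= 7
        scaled_control["area_px"] *= 7
        pd.testing.assert_frame_equal(
            normalise_team_maps(staff).table, normalise_team_maps(scaled_staff).table
        )
        pd.testing.assert_frame_equal(
            aggregate_roles(staff).table, aggregate_roles(scaled_staff).table
        )
        assert contamination_ratio(staff, control).value == pytest.approx(
            contamination_ratio(scaled_staff, scaled_control).value
        )


def test_map_to_image_darker_means_more(small_truth):
    nmap = aggregate_roles(small_truth.truth_table())
    atlas = small_truth.atlas
    img = map_to_image(nmap, atlas, "two", "green")
    hands_val = nmap.value("two", "green", "hands")
    assert img[atlas.zones["hands"]].max() == int(round(235 - 215 * hands_val))
    assert img.dtype == np.uint8
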