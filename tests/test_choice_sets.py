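"""Geographic choice sets, sample restrictions, and the long-data contract."""

import math

import numpy as np
import pandas as pd
import pytest

from carechoice import choice_sets as cs


def _roster(rows):
    return pd.DataFrame(
        rows,
        columns=["surgeon_id", "hospital_id", "x", "y", "bed_size", "teaching", "cicu"],
    )


ROSTER = _roster(
    [
        ("S0", "H0", 0.0, 0.0, 300, 1, 1),
        ("S1", "H1", 0.0, 40.0, 500, 0, 1),
        ("S1", "H2", 0.0, 70.0, 200, 0, 0),
    ]
)


class TestDistance:
    def test_zero_and_pythagorean(self):
        assert cs.distance_miles((1.0, 2.0), (1.0, 2.0)) == 0.0
        assert cs.distance_miles((0.0, 0.0), (3.0, 4.0)) == 5.0

    def test_haversine_against_law_of_cosines(self):
        # Independent spherical-law-of-cosines oracle.
        pairs = [((39.95, -75.16), (40.44, -79.99)),  # Philadelphia-Pittsburgh
                 ((41.0, -76.0), (40.0, -75.0)),
                 ((45.0, -70.0), (44.9, -70.2))]
        R = 3958.7613
        for a, b in pairs:
            p1, p2 = math.radians(a[0]), math.radians(b[0])
            dl = math.radians(b[1] - a[1])
            oracle = R * math.acos(
                min(1.0, math.sin(p1) * math.sin(p2) + math.cos(p1) * math.cos(p2) * math.cos(dl))
            )
            got = cs.distance_miles(a, b, mode="latlon")
            assert got == pytest.approx(oracle, rel=1e-3)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            cs.distance_miles((float("nan"), 0.0), (0.0, 0.0))


class TestFixedRadius:
    def test_chosen_beyond_radius_excluded(self):
        patient = {"patient_id": "P0", "quarter": 0, "x": 0.0, "y": 10.0,
                   "surgeon_id": "S1", "hospital_id": "H2"}  # 60 miles away
        result, reason = cs.fixed_radius_choice_set(patient, ROSTER, radius_miles=50)
        assert result is None and reason == "chosen_beyond_radius"

    def test_all_within_radius_keeps_full_roster(self):
        patient = {"patient_id": "P0", "quarter": 0, "x": 0.0, "y": 35.0,
                   "surgeon_id": "S0", "hospital_id": "H0"}
        result, reason = cs.fixed_radius_choice_set(patient, ROSTER, radius_miles=50)
        assert reason is None
        assert len(result.alternatives) == len(ROSTER)
        chosen = result.alternatives[result.chosen_index]
        assert (chosen.surgeon_id, chosen.hospital_id) == ("S0", "H0")

    def test_infinite_radius_never_excludes(self):
        patient = {"patient_id": "P0", "quarter": 0, "x": 0.0, "y": 10.0,
                   "surgeon_id": "S1", "hospital_id": "H2"}
        result, reason = cs.fixed_radius_choice_set(patient, ROSTER, radius_miles=np.inf)
        assert reason is None and len(result.alternatives) == 3

    def test_empty_roster_rejected(self):
        with pytest.raises(ValueError):
            cs.fixed_radius_choice_set({"patient_id": "P", "quarter": 0, "x": 0, "y": 0},
                                       ROSTER.iloc[:0], 50)


class TestMarketRadius:
    def _discharges(self, distances, hospital="H0"):
        return pd.DataFrame(
            {"hospital_id": [hospital] * len(distances), "distance": distances}
        )

    def test_linear_interpolation_percentile(self):
        d = self._discharges(list(range(1, 11)))
        assert cs.hospital_market_radius(d, "H0", coverage=0.9) == pytest.approx(9.1)

    def test_single_patient_and_full_coverage(self):
        assert cs.hospital_market_radius(self._discharges([7.0]), "H0") == 7.0
        d = self._discharges([1.0, 5.0, 30.0])
        assert cs.hospital_market_radius(d, "H0", coverage=1.0) == 30.0

    def test_hospital_without_discharges_absent(self):
        d = self._discharges([1.0])
        assert cs.hospital_market_radius(d, "H9") is None
        radii = cs.market_radii(d)
        assert "H9" not in radii.index

    def test_invalid_coverage(self):
        with pytest.raises(ValueError):
            cs.hospital_market_radius(self._discharges([1.0]), "H0", coverage=0.0)


class TestVariableRadius:
    def test_inclusion_by_market(self):
        patient = {"patient_id": "P0", "quarter": 0, "x": 0.0, "y": 12.0}
        radii = {"H0": 15.0, "H1": 5.0, "H2": 5.0}
        result, reason = cs.variable_radius_choice_set(patient, ROSTER, radii)
        assert reason is None
        pairs = {(a.surgeon_id, a.hospital_id) for a in result.alternatives}
        assert pairs == {("S0", "H0")}  # H1 at 28 miles > 5-mile market

    def test_patient_outside_every_market_excluded(self):
        patient = {"patient_id": "P0", "quarter": 0, "x": 50.0, "y": 50.0}
        result, reason = cs.variable_radius_choice_set(
            patient, ROSTER, {"H0": 1.0, "H1": 1.0, "H2": 1.0}
        )
        assert result is None and reason == "empty_choice_set"

    def test_not_nested_with_fixed_radius(self):
        # Two hospitals: H_far lies beyond 50 miles but has a wide market;
        # H_near is within 50 miles but has a tight market.  The variable
        # radius set contains H_far only, the 50-mile set H_near only.
        roster = _roster([
            ("A", "H_far", 0.0, 60.0, 100, 0, 0),
            ("B", "H_near", 0.0, 30.0, 100, 0, 0),
        ])
        patient = {"patient_id": "P0", "quarter": 0, "x": 0.0, "y": 0.0}
        radii = {"H_far": 80.0, "H_near": 10.0}
        var, _ = cs.variable_radius_choice_set(patient, roster, radii)
        fixed, _ = cs.fixed_radius_choice_set(patient, roster, radius_miles=50.0)
        var_pairs = {a.hospital_id for a in var.alternatives}
        fixed_pairs = {a.hospital_id for a in fixed.alternatives}
        assert var_pairs == {"H_far"} and fixed_pairs == {"H_near"}


class TestFilters:
    def test_no_flags_is_identity(self, small_long):
        out, audit = cs.apply_filters(small_long)
        pd.testing.assert_frame_equal(out, small_long)
        assert audit.n_excluded == 0

    def test_attrition_rule_drops_later_alternatives(self, small_long):
        last = (
            small_long[small_long["chosen"] == 1]
            .groupby("surgeon_id")["quarter"].max()
        )
        out, _ = cs.apply_filters(small_long, exclude_exited=True, last_surgery=last)
        merged_last = out["surgeon_id"].map(last)
        assert (merged_last >= out["quarter"]).all()
        # a surgeon whose last surgery was quarter q never appears at q+1+
        some = last.index[0]
        assert not ((out["surgeon_id"] == some) & (out["quarter"] > last[some])).any()

    def test_emergency_filter_bookkeeping(self, small_long):
        out, audit = cs.apply_filters(small_long, nonemergency_only=True)
        n_emerg = small_long.loc[small_long["chosen"] == 1, "emergency"].sum()
        assert audit.reasons["emergency_admission"] == n_emerg
        assert out["patient_id"].nunique() == small_long["patient_id"].nunique() - n_emerg
        assert (out["emergency"] == 0).all()

    def test_patient_filters_commute(self, small_long):
        a, _ = cs.apply_filters(small_long, nonemergency_only=True)
        a, _ = cs.apply_filters(a, nonreferral_only=True)
        b, _ = cs.apply_filters(small_long, nonreferral_only=True)
        b, _ = cs.apply_filters(b, nonemergency_only=True)
        pd.testing.assert_frame_equal(
            a.sort_values(["patient_id", "surgeon_id", "hospital_id"]).reset_index(drop=True),
            b.sort_values(["patient_id", "surgeon_id", "hospital_id"]).reset_index(drop=True),
        )


class TestAssembly:
    def test_row_and_chosen_counts(self, small_long):
        sizes = small_long.groupby("patient_id").size()
        assert len(small_long) == sizes.sum()
        assert (small_long.groupby("patient_id")["chosen"].sum() == 1).all()

    def test_indicator_coding_partitions(self, small_long):
        # high + implied-low + none partition each information block
        assert set(small_long["high_online"]) <= {0, 1}
        assert ((small_long["high_online"] + small_long["no_online"]) <= 1).all()
        assert ((small_long["high_report"] + small_long["no_report"]) <= 1).all()

    def test_missing_panel_cell_is_hard_failure(self, small_study, small_panel):
        rows, _ = cs.build_choice_rows(
            small_study.discharges, small_study.roster_at, radius=None
        )
        truncated = small_panel[small_panel["quarter"] < 5]
        with pytest.raises(KeyError):
            cs.assemble_long_dataset(rows, truncated)

    def test_long_csv_round_trip(self, small_long, tmp_path):
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        cs.write_long_csv(small_long, p1)
        back = cs.read_long_csv(p1)
        cs.write_long_csv(back, p2)
        assert p1.read_bytes() == p2.read_bytes()
        pd.testing.assert_frame_equal(
            back, small_long, check_dtype=False, check_exact=True
        )


class TestAuditArithmetic:
    def test_excluded_share_pct(self):
        assert cs.excluded_share_pct(0, 10) == 0.0
        assert cs.excluded_share_pct(5, 10) == 50.0
        with pytest.raises(ValueError):
            cs.excluded_share_pct(11, 10)
        with pytest.raises(ValueError):
            cs.excluded_share_pct(0, 0)

    def test_radius_exclusions_match_direct_count(self, small_study, small_panel):
        radius = 20.0
        rows, audit = cs.build_choice_rows(
            small_study.discharges, small_study.roster_at, radius=radius
        )
        direct = (small_study.discharges["distance"] > radius).sum()
        assert audit.reasons.get("chosen_beyond_radius", 0) == direct
        assert audit.n_patients == len(small_study.discharges)
        assert audit.n_retained == rows["patient_id"].nunique()
        # retained chosen rows satisfy the radius rule
        chosen = rows[rows["chosen"] == 1]
        assert (chosen["distance"] <= radius).all()
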