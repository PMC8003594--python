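"""MIRD dose arithmetic, S-value tables, and mouse-to-human extrapolation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tracedose import (
    SValueTable,
    absorbed_dose,
    build_dose_table,
    cumulated_activity_absolute,
    extrapolate_human_tiac,
    scale_dose_to_activity,
)
from tracedose.errors import MissingSValueError, OrganMappingError, ValidationError


@pytest.fixture
def mouse_table():
    return SValueTable(
        species="mouse",
        entries={
            ("liver", "liver"): 0.064,
            ("kidneys", "kidneys"): 0.22,
            ("tumor", "tumor"): 0.19,
            ("liver", "kidneys"): 0.004,
            ("kidneys", "liver"): 0.003,
            ("tumor", "liver"): 0.001,
            ("tumor", "kidneys"): 0.001,
            ("liver", "tumor"): 0.002,
            ("kidneys", "tumor"): 0.002,
            ("total_body", "total_body"): 0.0035,
        },
        organ_masses={"liver": 1.2, "kidneys": 0.35, "tumor": 0.4},
        total_body_mass=25.0,
    )


@pytest.fixture
def human_table():
    return SValueTable(
        species="human",
        entries={("liver", "liver"): 5.5e-5, ("kidneys", "kidneys"): 3.2e-4},
        organ_masses={"liver": 1800.0, "kidneys": 310.0},
        total_body_mass=73000.0,
    )


class TestCumulatedActivityAbsolute:
    @pytest.mark.parametrize(
        "tiac, mass, injected, expected",
        [(1.0, 1.0, 1.0, 1.0), (0.5, 0.2, 18.5, 1.85)],
    )
    def test_values(self, tiac, mass, injected, expected):
        assert cumulated_activity_absolute(tiac, mass, injected) == pytest.approx(
            expected, rel=1e-12
        )

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        tiac=st.floats(1e-6, 100.0),
        mass=st.floats(1e-3, 100.0),
        injected=st.floats(1e-3, 100.0),
    )
    def test_linear_in_injected_activity(self, tiac, mass, injected):
        assert cumulated_activity_absolute(tiac, mass, 2 * injected) == pytest.approx(
            2 * cumulated_activity_absolute(tiac, mass, injected), rel=1e-12
        )

    @pytest.mark.parametrize("mass, injected", [(0.0, 1.0), (1.0, 0.0), (-1.0, 1.0)])
    def test_nonpositive_inputs_rejected(self, mass, injected):
        with pytest.raises(ValidationError):
            cumulated_activity_absolute(1.0, mass, injected)


class TestAbsorbedDose:
    def test_unit_self_dose(self, mouse_table):
        assert absorbed_dose({"liver": 1.0}, mouse_table, "liver") == pytest.approx(
            0.064
        )

    def test_cross_mode_sums_all_sources(self, mouse_table):
        cum = {"liver": 2.0, "kidneys": 3.0}
        # independent hand computation of the two-source sums
        assert absorbed_dose(cum, mouse_table, "kidneys", mode="cross") == pytest.approx(
            2.0 * 0.004 + 3.0 * 0.22
        )
        assert absorbed_dose(cum, mouse_table, "liver", mode="cross") == pytest.approx(
            2.0 * 0.064 + 3.0 * 0.003
        )

    def test_zero_everywhere_gives_zero(self, mouse_table):
        cum = {"liver": 0.0, "kidneys": 0.0}
        assert absorbed_dose(cum, mouse_table, "liver", mode="cross") == 0.0

    def test_missing_entry_names_the_pair(self, human_table):
        with pytest.raises(MissingSValueError) as exc:
            absorbed_dose({"kidneys": 1.0}, human_table, "liver", mode="cross")
        assert exc.value.source == "kidneys" and exc.value.target == "liver"

    def test_self_mode_never_exceeds_cross_mode(self, mouse_table):
        cum = {"liver": 1.3, "kidneys": 0.7, "tumor": 2.1}
        for target in cum:
            assert absorbed_dose(cum, mouse_table, target, mode="self") <= absorbed_dose(
                cum, mouse_table, target, mode="cross"
            )


class TestScaleDose:
    def test_zero_activity(self):
        assert scale_dose_to_activity(0.5, 0.0) == 0.0

    def test_negative_activity_rejected(self):
        with pytest.raises(ValidationError):
            scale_dose_to_activity(0.5, -1.0)


class TestHumanExtrapolation:
    def test_relative_mass_hand_arithmetic(self, mouse_table, human_table):
        out = extrapolate_human_tiac({"liver": 0.01}, mouse_table, human_table)
        # 0.01 /g x 1800 g x (25 / 73000)
        assert out["liver"] == pytest.approx(0.01 * 1800.0 * 25.0 / 73000.0, rel=1e-12)

    def test_equal_body_masses_reduce_to_mass_scaling(self, mouse_table):
        same = SValueTable(
            species="human",
            entries={("liver", "liver"): 1.0},
            organ_masses={"liver": 300.0},
            total_body_mass=25.0,  # same as the mouse table
        )
        out = extrapolate_human_tiac({"liver": 0.01}, mouse_table, same)
        assert out["liver"] == pytest.approx(0.01 * 300.0, rel=1e-12)

    def test_direct_strategy_carries_organ_tiac(self, mouse_table, human_table):
        out = extrapolate_human_tiac(
            {"liver": 0.01}, mouse_table, human_table, strategy="direct"
        )
        assert out["liver"] == pytest.approx(0.01 * 1.2, rel=1e-12)

    def test_unmapped_organ_rejected(self, mouse_table, human_table):
        with pytest.raises(OrganMappingError):
            extrapolate_human_tiac({"tumor": 0.5}, mouse_table, human_table)


class TestDoseTable:
    def test_three_organ_fixture_matches_hand_computation(self, mouse_table):
        cum = {"liver": 2.0, "kidneys": 1.0, "tumor": 4.0}
        report = build_dose_table(cum, mouse_table, 18.5, species="mouse", mode="self")
        rows = report.table.set_index("organ")
        assert rows.loc["liver", "dose_gy"] == pytest.approx(2.0 * 0.064)
        assert rows.loc["kidneys", "dose_gy"] == pytest.approx(1.0 * 0.22)
        assert rows.loc["tumor", "dose_gy"] == pytest.approx(4.0 * 0.19)
        # total-body row uses the summed cumulated activity and its self term
        assert rows.loc["total_body", "dose_gy"] == pytest.approx(7.0 * 0.0035)
        # exact per-unit/at-activity identity
        np.testing.assert_allclose(
            rows["dose_gy"],
            rows["dose_gy_per_mbq"] * 18.5,
            rtol=1e-12,
        )

    def test_zero_injected_activity_zeroes_dose_column(self, mouse_table):
        report = build_dose_table(
            {"liver": 0.0, "kidneys": 0.0}, mouse_table, 0.0, species="mouse"
        )
        assert (report.table["dose_gy"] == 0.0).all()

    def test_report_round_trips_bit_identically(self, mouse_table, tmp_path):
        cum = {"liver": 2.0, "kidneys": 1.0}
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        build_dose_table(cum, mouse_table, 18.5, species="mouse", seed=9).to_csv(p1)
        build_dose_table(cum, mouse_table, 18.5, species="mouse", seed=9).to_csv(p2)
        assert p1.read_bytes() == p2.read_bytes()

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(k=st.floats(0.1, 10.0), s=st.floats(1e-4, 1.0))
    def test_dose_linear_in_activity_and_s_value(self, k, s):
        table = SValueTable(
            species="mouse",
            entries={("liver", "liver"): s},
            organ_masses={"liver": 1.2},
            total_body_mass=25.0,
        )
        base = absorbed_dose({"liver": 3.0}, table, "liver")
        scaled_s = SValueTable(
            species="mouse",
            entries={("liver", "liver"): k * s},
            organ_masses={"liver": 1.2},
            total_body_mass=25.0,
        )
        assert absorbed_dose({"liver": 3.0 * k}, table, "liver") == pytest.approx(
            k * base, rel=1e-12
        )
        assert absorbed_dose({"liver": 3.0}, scaled_s, "liver") == pytest.approx(
            k * base, rel=1e-12
        )
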