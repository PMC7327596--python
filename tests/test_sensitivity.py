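"""Sweeps, tornado analysis and the break-even solver."""

import io

import numpy as np
import pytest

from gpworkload import (
    DomainError,
    SweepSpec,
    ValidationError,
    base_case,
    break_even,
    default_grid,
    one_way_sweep,
    tornado,
    tornado_table,
    two_way_grid,
    with_param,
    workload_change,
)


class TestSweepSpec:
    def test_empty_grid_rejected(self):
        with pytest.raises(ValidationError, match="non-empty"):
            SweepSpec("completion_rate", [])

    def test_non_monotone_grid_rejected(self):
        with pytest.raises(ValidationError, match="monotone"):
            SweepSpec("completion_rate", [0.1, 0.3, 0.2])

    def test_default_grids(self):
        assert default_grid("digital_duration").grid == (4.0, 5.0, 6.0)
        demand = default_grid("demand_fraction").grid
        assert demand[0] == pytest.approx(-0.10)
        assert demand[-1] == pytest.approx(0.30)
        assert len(default_grid("completion_rate").grid) == 21


class TestOneWaySweep:
    def test_strictly_decreasing_in_completion(self, telephone_base):
        table = one_way_sweep(telephone_base, SweepSpec("completion_rate", [0.40, 0.52, 0.90]))
        values = table.data["percent_change"].to_numpy()
        assert np.all(np.diff(values) < 0)
        assert values[-1] < 0  # high completion saves workload

    def test_singleton_grid_matches_direct_call(self, econsult_base):
        table = one_way_sweep(econsult_base, SweepSpec("demand_fraction", [0.10]))
        assert table.data["percent_change"].iloc[0] == pytest.approx(
            workload_change(econsult_base).percent_change, abs=1e-12
        )

    def test_every_cell_matches_perturbed_scenario(self, econsult_base):
        spec = SweepSpec("completion_rate", [0.28, 0.30, 0.50, 0.70])
        table = one_way_sweep(econsult_base, spec)
        for value, pct in table.data.itertuples(index=False):
            direct = workload_change(with_param(econsult_base, "completion_rate", value))
            assert pct == pytest.approx(direct.percent_change, abs=1e-12)


class TestTwoWayGrid:
    def test_telephone_completion_55_at_5_minutes(self, telephone_base):
        scenario = with_param(telephone_base, "demand_fraction", 0.0)
        table = two_way_grid(
            scenario,
            SweepSpec("completion_rate", [0.55]),
            SweepSpec("digital_duration", [5.0]),
        )
        assert table.data["percent_change"].iloc[0] == pytest.approx(0.44, abs=0.01)

    def test_econsult_half_completion_zero_demand_saves_workload(self, econsult_base):
        table = two_way_grid(
            econsult_base,
            SweepSpec("completion_rate", [0.50]),
            SweepSpec("demand_fraction", [0.0]),
        )
        assert table.data["percent_change"].iloc[0] < 0

    def test_row_order_legend_major(self, telephone_base):
        table = two_way_grid(
            telephone_base,
            SweepSpec("completion_rate", [0.4, 0.6]),
            SweepSpec("digital_duration", [4.0, 6.0]),
        )
        assert list(table.data["digital_duration"]) == [4.0, 4.0, 6.0, 6.0]
        assert list(table.data["completion_rate"]) == [0.4, 0.6, 0.4, 0.6]

    def test_base_cell_matches_direct_evaluation(self, telephone_base):
        table = two_way_grid(
            telephone_base,
            SweepSpec("completion_rate", [0.4, 0.52]),
            SweepSpec("digital_duration", [5.0]),
        )
        base_cell = table.data.query("completion_rate == 0.52")["percent_change"].iloc[0]
        assert base_cell == pytest.approx(
            workload_change(telephone_base).percent_change, abs=1e-12
        )

    def test_same_variable_twice_rejected(self, telephone_base):
        with pytest.raises(ValidationError, match="distinct"):
            two_way_grid(
                telephone_base,
                SweepSpec("completion_rate", [0.4]),
                SweepSpec("completion_rate", [0.5]),
            )

    def test_csv_export(self, telephone_base):
        table = two_way_grid(
            telephone_base,
            SweepSpec("completion_rate", [0.4, 0.6]),
            SweepSpec("digital_duration", [5.0]),
        )
        text = table.to_csv()
        lines = text.strip().splitlines()
        assert lines[0] == "digital_duration,completion_rate,percent_change"
        assert len(lines) == 3


class TestBreakEven:
    def test_telephone_completion_break_even(self, telephone_base):
        # algebra: 14 - 9c = 9.7 - 1.26c  =>  c = 4.3/7.74 = 5/9
        result = break_even(telephone_base, "completion_rate", 0.0, 1.0)
        assert result.value == pytest.approx(4.3 / 7.74, abs=1e-6)
        assert abs(result.percent_change) < 1e-9

    def test_econsult_break_even_with_four_percent_demand(self, econsult_base):
        scenario = with_param(econsult_base, "demand_fraction", 0.04)
        result = break_even(scenario, "completion_rate", 0.0, 1.0)
        assert result.value == pytest.approx(0.488, abs=0.001)

    def test_solution_substitutes_back_to_zero(self, econsult_base):
        scenario = with_param(econsult_base, "demand_fraction", 0.0)
        result = break_even(scenario, "completion_rate", 0.0, 1.0, tol=1e-10)
        check = workload_change(
            with_param(scenario, "completion_rate", result.value)
        ).percent_change
        assert abs(check) < 1e-10

    def test_scenario_already_at_break_even(self, telephone_base):
        solved = break_even(telephone_base, "completion_rate", 0.0, 1.0)
        at_root = with_param(telephone_base, "completion_rate", solved.value)
        again = break_even(at_root, "completion_rate", solved.value, 1.0, tol=1e-6)
        assert again.value == pytest.approx(solved.value, abs=1e-6)

    def test_no_sign_change_raises_bracket_error(self, video_base):
        # video-first increases workload across the whole completion range
        with pytest.raises(DomainError, match="no sign change"):
            break_even(video_base, "completion_rate", 0.0, 0.5)

    def test_float_conversion(self, telephone_base):
        result = break_even(telephone_base, "completion_rate", 0.0, 1.0)
        assert float(result) == result.value


class TestFigureRegions:
    def test_telephone_sign_flip_between_55_and_56_percent_completion(self, telephone_base):
        scenario = with_param(telephone_base, "demand_fraction", 0.0)
        at_55 = workload_change(with_param(scenario, "completion_rate", 0.55))
        at_56 = workload_change(with_param(scenario, "completion_rate", 0.56))
        assert at_55.percent_change > 0
        assert at_56.percent_change < 0

    def test_econsult_sign_flip_between_5_and_6_percent_demand(self, econsult_base):
        scenario = with_param(econsult_base, "completion_rate", 0.50)
        at_5 = workload_change(with_param(scenario, "demand_fraction", 0.05))
        at_6 = workload_change(with_param(scenario, "demand_fraction", 0.06))
        assert at_5.percent_change < 0
        assert at_6.percent_change > 0


class TestTornado:
    def test_telephone_entries(self):
        entries = {e.variable: e for e in tornado("telephone")}
        assert set(entries) == {
            "access_rate", "completion_rate", "digital_duration", "demand_fraction",
        }
        completion = entries["completion_rate"]
        assert completion.change_at_upper < completion.change_at_lower
        for e in entries.values():
            assert e.base_change == pytest.approx(2.83, abs=0.005)

    def test_video_has_no_phone_followup_entry(self):
        assert "phone_followup_fraction" not in {e.variable for e in tornado("video")}

    def test_table_sorted_by_swing(self):
        frame = tornado_table("econsult")
        swing = (frame["change_at_upper"] - frame["change_at_lower"]).abs()
        assert list(swing) == sorted(swing, reverse=True)
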