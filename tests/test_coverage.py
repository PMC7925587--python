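import numpy as np
import pytest

from gastamp import (
    Quadrant,
    RunConfig,
    SolverOptions,
    build_eye_model,
    covered_percent,
    recommend_position,
    region,
    round_half_away,
    run_case,
    run_grid,
    solve_interface,
    up_vector,
)
from gastamp.errors import EmptyBreakSetError, MismatchedModelError

FLAT = SolverOptions(mode="flat")


class TestCoveredPercent:
    def test_degenerate_interfaces(self, model24):
        up = up_vector("supine").up
        reg = region(model24, "superior")
        all_gas = solve_interface(model24, up, 1.0)
        all_water = solve_interface(model24, up, 0.0)
        assert covered_percent(model24, reg, all_gas).percent_raw == 100.0
        assert covered_percent(model24, reg, all_water).percent_raw == 0.0

    @pytest.mark.parametrize(
        "quadrant, expected",
        [
            # zone-sector closed form with the fill level at -1.8075 mm
            ("superior", 82.8496),
            ("nasal", 100.0),
            ("temporal", 90.4256),
            ("inferior", 93.4802),
        ],
    )
    def test_supine_flat_mode_matches_the_zone_closed_form(
        self, model24, quadrant, expected
    ):
        sol = solve_interface(model24, up_vector("supine").up, 0.6, options=FLAT)
        r = covered_percent(model24, region(model24, quadrant), sol)
        assert r.percent_raw == pytest.approx(expected, abs=0.15)

    def test_mismatched_model_rejected(self, model24):
        other = build_eye_model(26)
        sol = solve_interface(other, up_vector("supine").up, 0.5)
        with pytest.raises(MismatchedModelError):
            covered_percent(model24, region(model24, "superior"), sol)

    def test_meniscus_never_covers_more_than_flat(self, model24):
        for pos in ("supine", "sitting", "prone_closed_eyes", "lower_nasal"):
            for gas in (0.3, 0.6, 0.9):
                flat = run_case(model24, pos, gas, options=FLAT)
                men = run_case(model24, pos, gas, options=SolverOptions(mode="meniscus"))
                for f, m_ in zip(flat, men):
                    assert m_.percent_raw <= f.percent_raw + 1e-9


class TestRunCaseTableCells:
    """Bulk-geometry (flat interface) reproduction of threshold table cells."""

    def test_lower_temporal_keeps_the_nasal_band_dry_down_to_ten_percent(self, model24):
        res = run_case(model24, "lower_temporal", 0.1, options=FLAT)
        assert {r.quadrant: r.percent for r in res}[Quadrant.NASAL] == 100

    def test_lower_nasal_floods_the_nasal_band_at_ninety_percent(self, model24):
        res = run_case(model24, "lower_nasal", 0.9, options=FLAT)
        assert {r.quadrant: r.percent for r in res}[Quadrant.NASAL] == 0

    def test_full_fill_covers_everything(self, model24):
        assert all(r.percent == 100 for r in run_case(model24, "prone", 1.0))


class TestSymmetries:
    def test_nasal_temporal_equal_under_symmetric_ora(self):
        m = build_eye_model(24, ora_arc={"nasal": 6.0, "temporal": 6.0})
        for pos in ("supine", "sitting", "prone"):
            res = {r.quadrant: r.percent_raw for r in run_case(m, pos, 0.55, options=FLAT)}
            assert res[Quadrant.NASAL] == pytest.approx(res[Quadrant.TEMPORAL], abs=1e-6)

    def test_gravity_flip_complement_in_flat_mode(self, model24):
        up = up_vector("prone_closed_eyes").up
        for gas in (0.25, 0.5, 0.7):
            a = run_case(model24, "prone_closed_eyes", gas, options=FLAT)
            sol_down = solve_interface(model24, -up, 1.0 - gas, options=FLAT)
            for r in a:
                reg = region(model24, r.quadrant)
                b = covered_percent(model24, reg, sol_down)
                assert r.percent_raw + b.percent_raw == pytest.approx(100.0, abs=0.3)

    def test_flat_percentages_scale_invariant_but_meniscus_not(self, model24):
        big = build_eye_model(
            48,
            truncation_depth=5.0,
            equator_offset=13.0,
            ora_arc={q.value: 2 * v for q, v in model24.ora_arc.items()},
        )
        small_flat = run_case(model24, "supine", 0.6, options=FLAT)
        big_flat = run_case(big, "supine", 0.6, options=FLAT)
        for s, b in zip(small_flat, big_flat):
            assert s.percent_raw == pytest.approx(b.percent_raw, abs=0.05)
        men = SolverOptions(mode="meniscus")
        small_men = run_case(model24, "supine", 0.6, options=men)
        big_men = run_case(big, "supine", 0.6, options=men)
        # fixed capillary length: the larger eye loses relatively less coverage
        assert any(
            abs(s.percent_raw - b.percent_raw) > 1.0
            for s, b in zip(small_men, big_men)
        )


class TestGridAndRecommendation:
    def test_small_grid_shape_and_monotonicity(self):
        cfg = RunConfig(
            diameters=(24.0,),
            positions=("supine", "sitting"),
            gas_percents=(0, 40, 80, 100),
        )
        table = run_grid(cfg)
        assert len(table) == 1 * 2 * 4 * 4
        assert table.check_monotone()
        assert (table.df[table.df.gas_percent == 100].coverage_percent == 100).all()
        assert (table.df[table.df.gas_percent == 0].coverage_percent == 0).all()

    def test_wide_layout_mirrors_the_printed_tables(self):
        cfg = RunConfig(diameters=(24.0,), positions=("supine",), gas_percents=(0, 50, 100))
        wide = run_grid(cfg).to_wide()
        assert list(wide.columns) == [100, 50, 0]
        assert wide.loc[(24.0, "superior", "supine"), 100] == 100

    def test_empty_break_set_rejected(self):
        cfg = RunConfig(diameters=(24.0,), positions=("supine",), gas_percents=(100,))
        table = run_grid(cfg)
        with pytest.raises(EmptyBreakSetError):
            recommend_position(table, [])


@pytest.mark.parametrize(
    "x, expected", [(0.4, 0), (0.5, 1), (76.5, 77), (99.49, 99), (100.0, 100)]
)
def test_rounding_half_away_from_zero(x, expected):
    assert round_half_away(x) == expected
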