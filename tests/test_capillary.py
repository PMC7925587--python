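import numpy as np
import pytest

from gastamp import (
    CavityProfile,
    PhysicalParams,
    SolverOptions,
    capillary_length,
    bond_number,
    build_eye_model,
    cavity_volume,
    fill_height,
    meniscus_profile_ode,
    meniscus_rise,
    solve_interface,
    up_vector,
    volume_below_plane,
)
from gastamp.errors import InvalidParamsError

UP_Z = np.array([0.0, 0.0, 1.0])


class TestPhysicalParams:
    def test_capillary_length_of_air_against_water(self):
        # sqrt(0.072 / (997.04 * 9.81)) = 2.7132 mm
        assert capillary_length(PhysicalParams()) == pytest.approx(2.713159, abs=1e-4)

    def test_gravity_dominates_at_eye_scale(self):
        assert bond_number(PhysicalParams(), 12.0) > 10.0

    def test_equal_densities_rejected(self):
        with pytest.raises(InvalidParamsError):
            PhysicalParams(rho_gas=998.23)

    def test_metadata_carries_unused_transport_properties(self):
        md = PhysicalParams().metadata
        assert md["kinematic_viscosity_water_m2_s"] == pytest.approx(1.006e-6)
        assert md["temperature_C"] == 37.0


class TestVolumeProfile:
    def test_supine_cap_volume_closed_form(self, model24):
        # spherical cap untouched by the truncation: pi d^2 (3R - d) / 3
        v = volume_below_plane(model24, UP_Z, -12.0 + 8.560403)
        assert v == pytest.approx(2105.6914, rel=1e-4)

    def test_endpoints_are_empty_and_full(self, model24):
        prof = CavityProfile(model24, UP_Z)
        assert prof.volume_below(prof.u_min) == 0.0
        assert prof.total_volume == pytest.approx(cavity_volume(model24), rel=1e-5)
        assert volume_below_plane(model24, UP_Z, -13.0) == 0.0

    def test_monotone_in_height(self, model24):
        prof = CavityProfile(model24, up_vector("prone_closed_eyes").up)
        h = np.linspace(prof.u_min, prof.u_max, 200)
        v = prof.volume_below(h)
        assert np.all(np.diff(v) >= 0)

    @pytest.mark.parametrize(
        "water_fraction, expected_h",
        [(0.3, -3.439597), (0.4, -1.807536), (0.5, -0.242365)],
    )
    def test_fill_height_inverts_the_cap_formula(self, model24, water_fraction, expected_h):
        h = fill_height(model24, UP_Z, water_fraction)
        assert h == pytest.approx(expected_h, abs=2e-3)

    def test_fill_height_endpoints(self, model24):
        prof = CavityProfile(model24, up_vector("sitting").up)
        assert prof.fill_height(0.0) == prof.u_min
        assert prof.fill_height(1.0) == prof.u_max

    def test_half_full_untilted_is_the_centre_plane(self):
        # nearly untruncated sphere: the half-volume level is the centre
        m = build_eye_model(24, truncation_depth=1e-6)
        assert fill_height(m, UP_Z, 0.5) == pytest.approx(0.0, abs=1e-3)


class TestMeniscusRise:
    def test_neutral_wetting_gives_no_rise(self):
        assert meniscus_rise(PhysicalParams(contact_angle_deg=90.0), 0.0) == 0.0

    def test_vertical_wall_closed_form(self):
        assert meniscus_rise(PhysicalParams(), 0.0) == pytest.approx(2.344635, abs=1e-4)

    def test_tilted_wall_closed_form(self):
        assert meniscus_rise(PhysicalParams(), 16.7) == pytest.approx(1.609129, abs=1e-4)

    def test_rise_clamps_at_sqrt2_capillary_lengths(self):
        p = PhysicalParams()
        assert meniscus_rise(p, -80.0) == pytest.approx(
            np.sqrt(2.0) * capillary_length(p), abs=1e-9
        )

    def test_bowl_like_wall_suppresses_the_rise(self):
        p = PhysicalParams()
        assert meniscus_rise(p, 60.0) == 0.0  # theta_eff >= 90

    @pytest.mark.parametrize("incl", [-30.0, -15.0, 0.0, 15.0, 30.0])
    def test_ode_oracle_agrees_with_the_closed_form(self, incl):
        p = PhysicalParams()
        closed = meniscus_rise(p, incl)
        ode = meniscus_profile_ode(p, incl)
        assert ode == pytest.approx(closed, rel=0.05)

    def test_rise_monotone_in_contact_angle(self):
        r10 = meniscus_profile_ode(PhysicalParams(contact_angle_deg=10.0))
        r60 = meniscus_profile_ode(PhysicalParams(contact_angle_deg=60.0))
        assert r10 > r60


class TestSolveInterface:
    def test_degenerate_fractions(self, model24):
        all_gas = solve_interface(model24, UP_Z, 1.0)
        all_water = solve_interface(model24, UP_Z, 0.0)
        assert all_gas.degenerate == "gas"
        assert all_water.degenerate == "water"

    def test_flat_height_matches_the_cap_inversion(self, model24):
        sol = solve_interface(model24, UP_Z, 0.6, options=SolverOptions(mode="flat"))
        assert sol.flat_height == pytest.approx(-1.8075, abs=2e-3)
        assert sol.gas_volume_achieved == pytest.approx(
            0.6 * cavity_volume(model24), rel=1e-6
        )

    def test_water_climbs_in_meniscus_mode(self, model24):
        for pos in ("supine", "sitting", "prone_closed_eyes"):
            up = up_vector(pos).up
            sol = solve_interface(model24, up, 0.6, options=SolverOptions(mode="meniscus"))
            assert np.all(sol.contact_height >= sol.flat_height)

    def test_solution_serialises_to_json(self, model24):
        import json

        sol = solve_interface(model24, UP_Z, 0.6)
        d = json.loads(sol.to_json())
        assert d["diameter_mm"] == 24.0
        assert len(d["contact_height_mm"]) == 720

    def test_contact_refinement_converges(self, model24):
        up = up_vector("prone_closed_eyes").up
        base = solve_interface(model24, up, 0.9, options=SolverOptions(mode="meniscus"))
        ref = solve_interface(
            model24, up, 0.9, options=SolverOptions(mode="meniscus", refine_contact=True)
        )
        # refinement moves the contact line by less than the climb itself
        assert np.max(np.abs(ref.contact_height - base.contact_height)) < 1.0

    def test_rebalanced_flat_level_sits_lower(self, model24):
        plain = solve_interface(model24, UP_Z, 0.6, options=SolverOptions(mode="meniscus"))
        reb = solve_interface(
            model24,
            UP_Z,
            0.6,
            options=SolverOptions(mode="meniscus", include_meniscus_volume=True),
        )
        assert reb.flat_height < plain.flat_height
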