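"""Nutrient uptake, radial depletion, grid solutes, mineralization, stress."""

import math

import numpy as np
import pytest

from rhizosim.hydrology import SoilGrid
from rhizosim.nutrients import (MineralizationPool, NutrientSpec,
                                PlantNutrientState, RadialProfile,
                                SoluteField, barber_cushman_step, exude,
                                fixation, grid_solute_step, mineralize_step,
                                mm_flux, requirements, stress_factors)

P_SPEC = NutrientSpec(name="phosphorus", Imax=0.26, Km=0.003, Cmin=0.0002)


class TestMichaelisMenten:
    def test_half_saturation_exact(self):
        spec = NutrientSpec(name="x", Imax=1.0, Km=0.01, Cmin=0.002)
        flux = mm_flux(spec.Km + spec.Cmin, spec, area=2.0)
        assert flux == pytest.approx(spec.Imax / 2.0 * 2.0)

    def test_below_cutoff_no_uptake(self):
        spec = NutrientSpec(name="x", Imax=1.0, Km=0.01, Cmin=0.002)
        assert mm_flux(0.002, spec, 1.0) == 0.0
        assert mm_flux(0.0, spec, 1.0) == 0.0

    def test_three_km_closed_form(self):
        spec = NutrientSpec(name="x", Imax=2.0, Km=0.01, Cmin=0.0)
        assert mm_flux(0.03, spec, 1.0) == pytest.approx(0.75 * 2.0)

    def test_root_hairs_multiply_area(self):
        spec = NutrientSpec(name="x", Imax=1.0, Km=0.01)
        assert mm_flux(0.05, spec, 1.0, uptake_area_multiplier=1.5) == \
            pytest.approx(1.5 * mm_flux(0.05, spec, 1.0))


class TestBarberCushman:
    def test_no_uptake_no_flow_profile_invariant(self):
        spec = NutrientSpec(name="x", Imax=1e-30, Km=0.003, Cmin=1.0)
        prof = RadialProfile(0.025, 0.5, C_init=0.01, b=100.0, De=1e-3)
        C0 = prof.C.copy()
        for _ in range(50):
            barber_cushman_step(prof, spec, 0.2)
        assert np.max(np.abs(prof.C - C0)) < 1e-14

    def test_annulus_mass_balance_closes(self):
        prof = RadialProfile(0.025, 0.5, C_init=0.01, b=100.0, De=1e-3)
        m0 = prof.mass()
        for _ in range(100):      # 10 d
            barber_cushman_step(prof, P_SPEC, 0.1)
        m1 = prof.mass()
        assert (m0 - m1) == pytest.approx(prof.cumulative_uptake,
                                          rel=1e-3)

    def test_coarse_grid_matches_fine_self_oracle(self):
        def cumulative(n_nodes):
            prof = RadialProfile(0.025, 0.5, C_init=0.01, b=100.0,
                                 De=1e-3, n_nodes=n_nodes)
            for _ in range(100):
                barber_cushman_step(prof, P_SPEC, 0.1)
            return prof.cumulative_uptake
        assert cumulative(20) == pytest.approx(cumulative(200), rel=0.02)

    def test_convection_accelerates_uptake(self):
        def run(v0):
            prof = RadialProfile(0.025, 0.5, C_init=0.01, b=100.0,
                                 De=1e-3, v0=v0)
            for _ in range(50):
                barber_cushman_step(prof, P_SPEC, 0.1)
            return prof.cumulative_uptake
        assert run(0.05) > run(0.0)


class TestGridSolute:
    def _grid(self, nz=10):
        return SoilGrid(3, 3, nz, dx=4, dy=4, dz=4, h_init=-100.0)

    def test_uniform_field_no_flux_unchanged(self):
        field = SoluteField(self._grid(), C_init=1.2)
        C0 = field.C.copy()
        grid_solute_step(field, None, None, None, 1.0)
        assert np.array_equal(field.C, C0)

    def test_closed_domain_mass_balance_with_uptake(self):
        grid = self._grid()
        field = SoluteField(grid, C_init=1.0)
        m0 = field.total_mass()
        sinks = np.zeros_like(field.C)
        sinks[1, 1, 2] = 0.4            # umol/d
        removed = 0.0
        for _ in range(50):
            removed += grid_solute_step(field, None, sinks, None, 0.1)
        assert m0 - field.total_mass() == pytest.approx(removed, rel=1e-3)

    def test_sources_add_mass(self):
        grid = self._grid()
        field = SoluteField(grid, C_init=0.5)
        m0 = field.total_mass()
        src = np.full_like(field.C, 0.01)   # umol/cm^3 solution /d
        grid_solute_step(field, None, None, src, 1.0)
        added = float(np.sum(src * grid.theta)) * grid.cell_volume
        assert field.total_mass() - m0 == pytest.approx(added, rel=1e-9)

    def test_pure_advection_front_speed(self):
        grid = self._grid(nz=30)
        field = SoluteField(grid, C_init=0.0, D0=0.0, dispersivity=0.0)
        field.C[:, :, :5] = 1.0
        theta = grid.theta[0, 0, 0]
        area = grid.dx * grid.dy
        q = 2.0 * theta * area   # cm^3/d downward so pore velocity = 2 cm/d
        fluxes = {"z": np.full((3, 3, 29), q)}
        z = -grid.z_centers()
        com0 = float(np.sum(field.C[1, 1, :] * z) / np.sum(field.C[1, 1, :]))
        T = 10.0
        for _ in range(int(T / 0.1)):
            grid_solute_step(field, fluxes, None, None, 0.1)
        profile = field.C[1, 1, :]
        # method of characteristics: the slug's centre of mass moves v*T
        com = float(np.sum(profile * z) / np.sum(profile))
        assert abs((com - com0) - 2.0 * T) <= grid.dz


class TestMineralization:
    def test_no_substrate_no_source(self):
        pool = MineralizationPool(C_substrate=0.0)
        assert mineralize_step(pool, 1.0) == 0.0

    def test_break_even_cn_ratio_is_algebraic_zero(self):
        pool = MineralizationPool(C_substrate=1e-3, CN_substrate=10.0 / 0.45,
                                  CN_microbial=10.0, e=0.45)
        assert mineralize_step(pool, 1.0) == pytest.approx(0.0, abs=1e-18)

    def test_cumulative_matches_integration_oracle(self):
        # closed form: C(T) = C0 exp(-k1 T^(1-S) / (1-S))
        c0, k1, S, T = 1e-3, 0.02, 0.5, 10.0
        expected = c0 * (1.0 - math.exp(-k1 * T ** (1 - S) / (1 - S)))

        def cumulative(dt):
            pool = MineralizationPool(C_substrate=c0, k1=k1, S=S, age=0.0)
            t = 0.0
            while t < T - 1e-9:
                mineralize_step(pool, dt)
                t += dt
            return c0 - pool.C_substrate

        assert cumulative(0.5) == pytest.approx(expected, rel=5e-3)
        assert cumulative(0.005) == pytest.approx(expected, rel=5e-3)

    def test_immobilization_is_negative(self):
        pool = MineralizationPool(C_substrate=1e-3, CN_substrate=60.0,
                                  CN_microbial=10.0, e=0.45)
        assert mineralize_step(pool, 1.0) < 0.0


class TestRequirementsAndStress:
    def test_zero_biomass_zero_requirement(self):
        out = requirements({}, P_SPEC, 5.0)
        assert out == {"optimal": 0.0, "minimal": 0.0}

    def test_one_gram_times_concentration(self):
        spec = NutrientSpec(name="x", optimal_conc=[(0.0, 100.0)],
                            minimal_conc=[(0.0, 40.0)])
        out = requirements({"leaf": 1.0}, spec, 0.0)
        assert out["optimal"] == pytest.approx(100.0)
        assert out["minimal"] == pytest.approx(40.0)

    def test_rcs_halves_root_contribution(self):
        spec = NutrientSpec(name="x", optimal_conc=[(0.0, 100.0)])
        full = requirements({"root": 2.0}, spec, 0.0)
        half = requirements({"root": 2.0}, spec, 0.0,
                            root_content_multiplier=0.5)
        assert half["optimal"] == pytest.approx(0.5 * full["optimal"])

    def test_all_satisfied_all_multipliers_one(self):
        states = {"n": PlantNutrientState(content=10.0,
                                          requirement_optimal=5.0)}
        states["n"].update_satisfaction()
        out = stress_factors(states, {"n": NutrientSpec(name="n")})
        assert all(v == 1.0 for v in out.values())

    def test_per_process_response_curve_ordering(self):
        # N hits photosynthesis harder than leaf expansion, per its curves
        spec = NutrientSpec(
            name="n",
            stress_responses={
                "photosynthesis": [(0.0, 0.0), (1.0, 1.0)],
                "leaf_expansion": [(0.0, 0.5), (1.0, 1.0)],
            })
        st = PlantNutrientState(content=1.0, requirement_optimal=2.0)
        st.update_satisfaction()
        out = stress_factors({"n": st}, {"n": spec})
        assert out["photosynthesis"] < out["leaf_expansion"]

    def test_aggregation_arithmetic(self):
        s1 = PlantNutrientState(content=4.0, requirement_optimal=10.0)
        s2 = PlantNutrientState(content=9.0, requirement_optimal=10.0)
        s1.update_satisfaction()
        s2.update_satisfaction()
        specs = {"a": NutrientSpec(name="a"), "b": NutrientSpec(name="b")}
        states = {"a": s1, "b": s2}
        assert stress_factors(states, specs, "max")["photosynthesis"] == \
            pytest.approx(0.4)
        assert stress_factors(states, specs, "mean")["photosynthesis"] == \
            pytest.approx(0.65)


class TestFixationAndExudation:
    def test_fixation_credit_arithmetic(self):
        st = PlantNutrientState(requirement_optimal=200.0,
                                fixation_fraction=0.5)
        assert fixation(st) == pytest.approx(100.0)
        st2 = PlantNutrientState(requirement_optimal=200.0,
                                 fixation_fraction=0.0)
        assert fixation(st2) == 0.0

    def test_full_fixation_saturates_regardless_of_soil(self):
        st = PlantNutrientState(requirement_optimal=50.0,
                                fixation_fraction=1.0)
        fixation(st)
        st.update_satisfaction()
        assert st.satisfaction >= 1.0 - 1e-12

    def test_exudation_conserves_total_mass(self):
        prof = RadialProfile(0.025, 0.5, C_init=0.01, b=100.0)
        prof.insoluble = 5.0
        m0 = prof.mass() + prof.insoluble
        moved = exude(prof, rate=0.4, dt=2.0)
        assert moved == pytest.approx(0.8)
        assert prof.mass() + prof.insoluble == pytest.approx(m0, rel=1e-12)

    def test_solubilization_increases_uptake_in_paired_run(self):
        def run(solubilize):
            prof = RadialProfile(0.025, 0.5, C_init=0.01, b=100.0, De=1e-3)
            prof.insoluble = 10.0
            for _ in range(100):
                if solubilize:
                    exude(prof, rate=0.005, dt=0.1)
                barber_cushman_step(prof, P_SPEC, 0.1)
            return prof.cumulative_uptake
        assert run(True) > run(False)
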