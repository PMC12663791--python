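"""Mass-transfer model: uptake, shape factors, growth rates, critical size."""
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from osmolimit.diffusion import (
    CellGeometry,
    ModelConfig,
    NutrientField,
    SCALING_EXPONENT,
    critical_esd,
    cylinder_correction,
    daily_nitrogen_uptake,
    daily_phosphorus_uptake,
    growth_potential,
    n_based_max_growth,
    p_based_max_growth,
    prolate_correction,
    sphere_max_uptake,
)
from osmolimit.errors import DomainError, MissingDataError, NoSolutionError
from osmolimit.physchem import SeawaterState

from conftest import make_field

STATE = SeawaterState(20.0, 35.0)


class TestSphereUptake:
    def test_worked_example(self):
        # 4*pi * 1e-5 * 5e-4 * 0.1 nmol/cm3
        rho = sphere_max_uptake(1e-5, 5e-4, 100.0)
        assert rho == pytest.approx(6.2832e-9, rel=1e-4)

    def test_zero_gradient_gives_zero(self):
        assert sphere_max_uptake(1e-5, 5e-4, 0.0) == 0.0

    @pytest.mark.parametrize("which", [0, 1, 2])
    def test_linearity_in_each_argument(self, which):
        args = [1e-5, 5e-4, 100.0]
        base = sphere_max_uptake(*args)
        doubled = list(args)
        doubled[which] *= 2.0
        assert sphere_max_uptake(*doubled) == pytest.approx(2.0 * base, rel=1e-12)

    def test_negative_inputs_rejected(self):
        with pytest.raises(DomainError):
            sphere_max_uptake(-1e-5, 5e-4, 100.0)
        with pytest.raises(DomainError):
            sphere_max_uptake(1e-5, 5e-4, -1.0)


class TestShapeFactors:
    def test_prolate_limit_is_one_at_sphere(self):
        assert prolate_correction(1.0) == 1.0
        # continuity of the analytic limit
        assert prolate_correction(1.0 + 1e-9) == pytest.approx(1.0, abs=1e-4)

    @pytest.mark.parametrize(
        "aspect, expected", [(2.0, 1.3152), (10.0, 3.3242)]
    )
    def test_prolate_high_precision_values(self, aspect, expected):
        assert prolate_correction(aspect) == pytest.approx(expected, abs=1e-4)

    def test_prolate_strictly_increasing(self):
        es = np.linspace(1.0, 50.0, 200)
        vals = [prolate_correction(e) for e in es]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_prolate_rejects_aspect_below_one(self):
        with pytest.raises(DomainError):
            prolate_correction(0.9)

    def test_cylinder_frozen_regression_value(self):
        # boundary-element capacitance of a solid cylinder, L/d = 10, in
        # units of its radius (frozen from a converged run of this solver)
        assert cylinder_correction(10.0) == pytest.approx(3.8137, rel=1e-3)

    def test_cylinder_exceeds_prolate_by_about_15_percent_at_aspect_10(self):
        ratio = cylinder_correction(10.0) / prolate_correction(10.0)
        assert round(100.0 * (ratio - 1.0)) == 15

    def test_cylinder_monotone_increasing(self):
        es = [1.5, 3.0, 10.0, 30.0, 100.0]
        vals = [cylinder_correction(e) for e in es]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_cylinder_rejects_aspect_at_or_below_one(self):
        with pytest.raises(DomainError):
            cylinder_correction(1.0)


class TestDailyUptake:
    def test_single_solute_is_window_times_rho(self):
        geom = CellGeometry(esd=10.0)
        field = make_field(nh4=100.0)
        uptake = daily_nitrogen_uptake(geom, field, STATE, diffusivity_override=1e-5)
        assert uptake == pytest.approx(86400.0 * 6.2832e-9, rel=1e-4)
        assert uptake == pytest.approx(5.4288e-4, rel=1e-4)

    def test_nitrate_contributes_half_of_ammonium_at_equal_rho(self):
        geom = CellGeometry(esd=10.0)
        u_nh4 = daily_nitrogen_uptake(geom, make_field(nh4=100.0), STATE, diffusivity_override=1e-5)
        u_no3 = daily_nitrogen_uptake(geom, make_field(no3=100.0), STATE, diffusivity_override=1e-5)
        assert u_no3 == pytest.approx(0.5 * u_nh4, rel=1e-12)

    def test_additivity_over_solutes(self):
        geom = CellGeometry(esd=8.0)
        total = daily_nitrogen_uptake(
            geom, make_field(nh4=50.0, no2=10.0, no3=200.0), STATE
        )
        parts = sum(
            daily_nitrogen_uptake(geom, f, STATE)
            for f in (make_field(nh4=50.0), make_field(no2=10.0), make_field(no3=200.0))
        )
        assert total == pytest.approx(parts, rel=1e-14)

    def test_missing_concentration_raises_not_zero_fills(self):
        geom = CellGeometry(esd=10.0)
        with pytest.raises(MissingDataError):
            daily_nitrogen_uptake(geom, NutrientField(ammonium=10.0, nitrate=5.0), STATE)
        with pytest.raises(MissingDataError):
            daily_phosphorus_uptake(geom, make_field(nh4=1, no2=1, no3=1, dip=None), STATE)


class TestGrowthRates:
    def test_worked_example_chain(self):
        geom = CellGeometry(esd=10.0)
        field = make_field(nh4=100.0, dip=100.0)
        gr_n = n_based_max_growth(geom, field, STATE, diffusivity_override=1e-5)
        assert gr_n == pytest.approx(0.4888, rel=1e-3)
        gr_p = p_based_max_growth(geom, field, STATE, diffusivity_override=1e-5)
        assert gr_p == pytest.approx(7.822, rel=1e-3)

    def test_zero_nitrogen_gives_zero_growth(self):
        geom = CellGeometry(esd=10.0)
        assert n_based_max_growth(geom, make_field(dip=10.0), STATE) == 0.0

    def test_p_rate_is_16x_n_rate_for_matched_fields(self):
        # with DIN carried by ammonium only (24-h window) at the same D and
        # concentration as phosphate, P_cell = N_cell/16 forces gr_p = 16 gr_n
        geom = CellGeometry(esd=12.0)
        field = make_field(nh4=80.0, dip=80.0)
        gr_n = n_based_max_growth(geom, field, STATE, diffusivity_override=1e-5)
        gr_p = p_based_max_growth(geom, field, STATE, diffusivity_override=1e-5)
        assert gr_p == pytest.approx(16.0 * gr_n, rel=1e-12)

    @given(
        esd=st.floats(min_value=0.5, max_value=500.0),
        alpha=st.floats(min_value=0.1, max_value=10.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_size_scaling_power_law(self, esd, alpha):
        field = make_field(nh4=30.0, no2=5.0, no3=200.0)
        g1 = n_based_max_growth(CellGeometry(esd=esd), field, STATE)
        g2 = n_based_max_growth(CellGeometry(esd=alpha * esd), field, STATE)
        assert g2 == pytest.approx(alpha ** (-SCALING_EXPONENT) * g1, rel=1e-9)

    def test_aspect_one_prolate_equals_sphere_path_exactly(self):
        field = make_field(nh4=30.0, no2=5.0, no3=200.0)
        sphere = n_based_max_growth(CellGeometry(esd=7.0), field, STATE)
        prolate = n_based_max_growth(
            CellGeometry(esd=7.0, aspect_ratio=1.0, shape="prolate"), field, STATE
        )
        assert prolate == sphere

    def test_growth_potential_bundle_consistent(self):
        geom = CellGeometry(esd=10.0, aspect_ratio=3.0, shape="prolate")
        field = make_field(nh4=50.0, no2=5.0, no3=100.0, dip=40.0)
        gp = growth_potential(geom, field, STATE)
        assert gp.gr_n == pytest.approx(n_based_max_growth(geom, field, STATE), rel=1e-14)
        assert gp.gr_p == pytest.approx(p_based_max_growth(geom, field, STATE), rel=1e-14)
        for solute, rho in gp.max_uptake.items():
            assert gp.corrected_uptake[solute] >= rho  # E >= 1 only enhances


class TestCriticalEsd:
    def test_worked_example_cell_18um(self):
        field = make_field(nh4=100.0)
        esd = critical_esd(0.2, field, STATE, diffusivity_override=1e-5)
        assert esd == pytest.approx(18.07, abs=0.01)
        # the 18.07-um cell grows at exactly the target
        assert n_based_max_growth(
            CellGeometry(esd=esd), field, STATE, diffusivity_override=1e-5
        ) == pytest.approx(0.2, rel=1e-9)

    def test_decreasing_in_target_growth_rate(self):
        field = make_field(nh4=100.0, no2=10.0, no3=500.0)
        esds = [critical_esd(g, field, STATE) for g in (0.1, 0.2, 0.6, 2.0)]
        assert all(a > b for a, b in zip(esds, esds[1:]))

    def test_doubling_concentrations_scales_by_power_law(self):
        field = make_field(nh4=40.0, no2=5.0, no3=150.0)
        double = make_field(nh4=80.0, no2=10.0, no3=300.0)
        e1 = critical_esd(0.2, field, STATE)
        e2 = critical_esd(0.2, double, STATE)
        assert e2 / e1 == pytest.approx(2.0 ** (1.0 / SCALING_EXPONENT), rel=1e-9)
        assert e2 / e1 == pytest.approx(1.582, abs=2e-3)

    def test_root_finder_agrees_with_closed_form_for_elongated_cells(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            field = make_field(nh4=rng.uniform(1, 500), no2=rng.uniform(0, 50), no3=rng.uniform(1, 2000))
            aspect = rng.uniform(1.01, 20.0)
            target = rng.uniform(0.05, 2.0)
            via_root = critical_esd(target, field, STATE, aspect_ratio=aspect)
            gr1 = n_based_max_growth(
                CellGeometry(esd=1.0, aspect_ratio=aspect, shape="prolate"), field, STATE
            )
            closed = (gr1 / target) ** (1.0 / SCALING_EXPONENT)
            assert abs(via_root - closed) / closed < 1e-6

    def test_urea_strictly_increases_the_size_limit(self):
        base = make_field(nh4=20.0, no2=2.0, no3=30.0)
        with_urea = make_field(nh4=20.0, no2=2.0, no3=30.0, urea=200.0)
        assert critical_esd(0.6, with_urea, STATE) > critical_esd(0.6, base, STATE)

    def test_all_zero_nitrogen_has_no_solution(self):
        with pytest.raises(NoSolutionError):
            critical_esd(0.2, make_field(), STATE)


class TestValidation:
    def test_geometry_invariants(self):
        geom = CellGeometry(esd=10.0)
        assert geom.biovolume == pytest.approx(math.pi / 6.0 * 1000.0, rel=1e-12)
        assert geom.r0_cm == pytest.approx(5e-4, rel=1e-12)
        with pytest.raises(DomainError):
            CellGeometry(esd=-1.0)
        with pytest.raises(DomainError):
            CellGeometry(esd=10.0, aspect_ratio=0.5, shape="prolate")
        with pytest.raises(DomainError):
            CellGeometry(esd=10.0, aspect_ratio=2.0, shape="sphere")

    def test_nutrient_field_rejects_negative(self):
        with pytest.raises(DomainError):
            NutrientField(ammonium=-1.0)

    def test_model_config_thresholds_must_increase(self):
        from osmolimit.errors import ConfigurationError

        with pytest.raises(ConfigurationError):
            ModelConfig(growth_thresholds=(0.6, 0.2))
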