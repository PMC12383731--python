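import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stentflow.flowsolve import StructuredGrid
from stentflow.ldpm import (
    CoilFill,
    FluidProperties,
    PorousField,
    PorousModelError,
    build_coil_region,
    build_porous_field,
    hydraulic_diameter,
    inertial_bracket,
    porosity,
    pressure_loss,
)
from stentflow.workbench import UniformScreenCell


class TestPorosity:
    @pytest.mark.parametrize(
        "At,Aw,expected", [(1.0, 0.0, 1.0), (1.0, 1.0, 0.0), (2.0e-7, 6.0e-8, 0.7)]
    )
    def test_values(self, At, Aw, expected):
        assert porosity(At, Aw) == pytest.approx(expected, abs=1e-12)

    def test_overdense_cell_rejected(self):
        with pytest.raises(PorousModelError):
            porosity(1.0, 1.5)


class TestHydraulicDiameter:
    @pytest.mark.parametrize(
        "s,alpha,expected", [(2.0e-4, np.pi / 2, 2.0e-4), (2.0e-4, np.pi / 6, 1.0e-4)]
    )
    def test_verbatim(self, s, alpha, expected):
        assert hydraulic_diameter(s, alpha) == pytest.approx(expected, rel=1e-12)

    def test_pore_mode_equals_verbatim_at_zero_wire_width(self):
        # 4A/P of a rhombus of side s is s*sin(alpha); at d_w=0 the pore is
        # the full cell, so both modes coincide
        v = hydraulic_diameter(2.0e-4, np.pi / 2, mode="pore_hydraulic", wire_diameter=0.0)
        assert v == pytest.approx(2.0e-4, rel=1e-12)

    def test_pore_mode_shrinks_with_wire(self):
        v = hydraulic_diameter(2.0e-4, np.pi / 3, mode="pore_hydraulic", wire_diameter=30e-6)
        assert v == pytest.approx(2.0e-4 * np.sin(np.pi / 3) - 30e-6, rel=1e-9)

    def test_degenerate_angle_rejected(self):
        with pytest.raises(PorousModelError):
            hydraulic_diameter(2.0e-4, 1e-9)


class TestPressureLoss:
    def test_zero_velocity(self, blood):
        assert pressure_loss(0.7, 1e-4, 0.0, blood) == 0.0

    def test_open_screen_purely_viscous(self, blood):
        dp = pressure_loss(1.0, 1e-4, 0.1, blood)
        assert dp == pytest.approx(-11 * 3.6e-3 * 0.1 / 1e-4, rel=1e-12)

    def test_hand_evaluated_example(self, blood):
        # bracket 0.39 + 0.18367 = 0.57367; -550*0.57367*0.01 - 39.6
        assert pressure_loss(0.7, 1e-4, 0.1, blood) == pytest.approx(-42.76, abs=0.01)

    def test_occluded_cell_raises(self, blood):
        with pytest.raises(PorousModelError):
            pressure_loss(0.0, 1e-4, 0.1, blood)

    def test_bracket_strictly_decreasing(self):
        eps = np.linspace(1e-3, 1.0, 1000)
        br = inertial_bracket(eps)
        assert np.all(np.diff(br) < 0)

    @given(
        v1=st.floats(0.001, 2.0), scale=st.floats(1.1, 5.0),
        eps=st.floats(0.2, 0.99), dh=st.floats(1e-5, 1e-3),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_loss_increases_with_speed_and_viscosity(self, v1, scale, eps, dh):
        blood = FluidProperties()
        thick = FluidProperties(viscosity=3.6e-3 * scale)
        lo = abs(pressure_loss(eps, dh, v1, blood))
        hi_v = abs(pressure_loss(eps, dh, v1 * scale, blood))
        hi_mu = abs(pressure_loss(eps, dh, v1, thick))
        assert hi_v > lo and hi_mu > lo


def _duct_grid(nx=40, ny=10):
    g = StructuredGrid(nx, ny, 1e-4, 1e-4)
    return g


class TestPorousField:
    def test_empty_field_all_zero(self):
        f = PorousField.empty((8, 8))
        assert f.is_empty()
        assert np.all(f.region_tag == PorousField.TAG_NONE)

    def test_uniform_screen_field_uniform(self, blood):
        g = _duct_grid()
        g.mark_shell(axis=0, position=2e-3, t_shell=60e-6)
        f = build_porous_field([UniformScreenCell(0.7, 1.5e-4)], g, 60e-6, blood)
        c1 = f.C1[f.region_tag == PorousField.TAG_SHELL]
        c2 = f.C2[f.region_tag == PorousField.TAG_SHELL]
        assert np.ptp(c1) == 0 and np.ptp(c2) == 0
        assert c2[0] == pytest.approx(550 * inertial_bracket(0.7), rel=1e-12)

    def test_field_support_moves_with_screen(self, blood):
        # translation equivariance of the nonzero-coefficient support
        cells = [UniformScreenCell(0.7, 1.5e-4)]
        g1, g2 = _duct_grid(), _duct_grid()
        g1.mark_shell(axis=0, position=1e-3, t_shell=60e-6)
        g2.mark_shell(axis=0, position=2e-3, t_shell=60e-6)
        f1 = build_porous_field(cells, g1, 60e-6, blood)
        f2 = build_porous_field(cells, g2, 60e-6, blood)
        shift = int(round(1e-3 / g1.dx))
        assert np.array_equal(np.roll(f1.C1 > 0, shift, axis=0), f2.C1 > 0)

    def test_unresolvable_shell_raises(self, blood):
        g = _duct_grid()
        with pytest.raises(Exception):
            g.mark_shell(axis=0, position=1e-2, t_shell=60e-6)  # outside the grid

    def test_open_cells_have_zero_quadratic_term(self, blood):
        g = _duct_grid()
        g.mark_shell(axis=0, position=2e-3, t_shell=60e-6)
        f = build_porous_field([UniformScreenCell(1.0, 1.5e-4)], g, 60e-6, blood)
        assert np.all(f.C2 == 0)
        assert np.any(f.C1 > 0)


class TestIntersectionZeroing:
    def test_toggle_zeroes_near_crossings(self, blood):
        g = _duct_grid()
        g.mark_shell(axis=0, position=2e-3, t_shell=60e-6)
        crossings = np.column_stack([np.zeros(5), np.linspace(0, 2 * np.pi, 5)])
        f_on = build_porous_field(
            [UniformScreenCell(0.7, 1.5e-4)], g, 60e-6, blood,
            intersections_zero=True, crossing_points=crossings, wire_diameter=1.0,
        )
        f_off = build_porous_field(
            [UniformScreenCell(0.7, 1.5e-4)], g, 60e-6, blood,
        )
        # with an exaggerated zeroing radius every shell cell is hit
        assert np.all(f_on.C1 == 0) and np.all(f_on.C2 == 0)
        assert np.any(f_off.C1 > 0)


class TestViscosityLaw:
    def test_constant_law_matches_newtonian(self, blood):
        from stentflow.flowsolve import BoundaryConditions, StructuredGrid, solve_steady

        g1 = StructuredGrid(30, 12, 2e-4, 1e-4)
        g2 = StructuredGrid(30, 12, 2e-4, 1e-4)
        law = FluidProperties(viscosity=3.6e-3, viscosity_law=lambda g: np.full_like(g, 3.6e-3))
        bc = BoundaryConditions(mass_flow=1100 * 0.2 * 1.2e-3)
        f1 = solve_steady(g1, None, blood, bc, tol=1e-6, max_iter=400)
        f2 = solve_steady(g2, None, law, bc, tol=1e-6, max_iter=400)
        assert np.allclose(f1.u, f2.u, rtol=1e-8, atol=1e-12)

    def test_shear_thinning_lowers_pressure_drop(self, blood):
        from stentflow.flowsolve import BoundaryConditions, StructuredGrid, solve_steady

        def thinning(g):
            return 3.6e-3 / (1.0 + 0.005 * np.abs(g))

        g1 = StructuredGrid(30, 12, 2e-4, 1e-4)
        g2 = StructuredGrid(30, 12, 2e-4, 1e-4)
        law = FluidProperties(viscosity=3.6e-3, viscosity_law=thinning)
        bc = BoundaryConditions(mass_flow=1100 * 0.2 * 1.2e-3)
        f1 = solve_steady(g1, None, blood, bc, tol=1e-6, max_iter=600)
        f2 = solve_steady(g2, None, law, bc, tol=1e-6, max_iter=600)
        assert f2.p[0, :].mean() < f1.p[0, :].mean()

    def test_negative_viscosity_rejected(self):
        bad = FluidProperties(viscosity_law=lambda g: np.full_like(g, -1.0))
        with pytest.raises(PorousModelError):
            bad.mu(1.0)


class TestCoilRegion:
    def test_ver_doubles_with_coil_count(self):
        # coil volume / sac volume = 0.012 per coil
        sac_vol = np.pi * (0.25e-3 / 2) ** 2 * 0.20 / 0.012
        one = CoilFill.from_coils(1, sac_vol)
        two = CoilFill.from_coils(2, sac_vol)
        assert one.ver == pytest.approx(0.012, rel=1e-12)
        assert two.ver == pytest.approx(0.024, rel=1e-12)

    def test_zero_ver_contributes_nothing(self, blood):
        mask = np.zeros((10, 10), dtype=bool)
        mask[3:7, 3:7] = True
        f = build_coil_region(CoilFill(ver=0.0), mask, blood)
        assert f.is_empty()

    def test_resistance_increases_with_ver(self, blood):
        mask = np.ones((4, 4), dtype=bool)
        f1 = build_coil_region(CoilFill(ver=0.012), mask, blood)
        f2 = build_coil_region(CoilFill(ver=0.024), mask, blood)
        assert np.all(f2.C1_iso >= f1.C1_iso)
        assert f2.C1_iso[0, 0] > f1.C1_iso[0, 0]

    def test_ver_out_of_range_rejected(self):
        with pytest.raises(PorousModelError):
            CoilFill(ver=1.0)
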