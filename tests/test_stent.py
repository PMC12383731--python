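import numpy as np
import pytest

from stentflow.geometry import make_curved_vessel, make_straight_vessel
from stentflow.stent import (
    DeploymentError,
    StentDesign,
    deploy_stent,
    extract_cells,
    local_braid_angle,
)


class TestDesign:
    def test_odd_wire_count_rejected(self):
        with pytest.raises(DeploymentError):
            StentDesign(n_wires=47)

    def test_shell_thickness_defaults_to_twice_wire_diameter(self):
        d = StentDesign(wire_diameter=30e-6)
        assert d.shell_thickness == pytest.approx(60e-6)

    def test_wire_free_length_from_nominal_geometry(self):
        d = StentDesign(nominal_length=10e-3, nominal_braid_angle=np.deg2rad(150))
        assert d.wire_free_length == pytest.approx(10e-3 / np.cos(np.deg2rad(75)))


class TestDeployment:
    def test_nominal_vessel_keeps_nominal_angle_and_length(self, nominal_deployment):
        design, _vessel, dep = nominal_deployment
        assert np.max(np.abs(dep.alpha - design.nominal_braid_angle)) < 1e-6
        assert dep.end - dep.start == pytest.approx(design.nominal_length, rel=1e-6)

    def test_wire_length_conserved(self, nominal_deployment):
        design, _vessel, dep = nominal_deployment
        lens = dep.deployed_wire_lengths()
        assert np.max(np.abs(lens - design.wire_free_length)) / design.wire_free_length < 0.005

    def test_narrow_vessel_elongates_stent(self, oversized_deployment):
        design, _vessel, dep = oversized_deployment
        assert dep.end - dep.start > design.nominal_length
        lens = dep.deployed_wire_lengths()
        assert np.max(np.abs(lens - design.wire_free_length)) / design.wire_free_length < 0.005

    def test_vessel_too_short_raises(self):
        design = StentDesign(nominal_length=30e-3)
        vessel = make_straight_vessel(2.25e-3, 0.025, 2.5e-4)
        with pytest.raises(DeploymentError):
            deploy_stent(design, vessel, 1e-3)

    def test_porosity_rises_as_vessel_narrows_below_nominal(self):
        # radial constraint of a high-angle braid scissors cells toward 90
        # degrees and lowers metal coverage (the classical oversizing effect)
        design = StentDesign(nominal_diameter=4.5e-3, nominal_length=8e-3)
        eps_prev = None
        for R in (2.25e-3, 2.1e-3, 1.95e-3, 1.8e-3):
            vessel = make_straight_vessel(R, 0.08, 2.5e-4)
            cells = extract_cells(deploy_stent(design, vessel, 5e-3), design)
            eps = float(np.mean([c.porosity for c in cells]))
            if eps_prev is not None:
                assert eps > eps_prev
            eps_prev = eps

    def test_poor_apposition_flagged_in_wide_vessel(self):
        design = StentDesign(nominal_diameter=4.5e-3, nominal_length=8e-3)
        vessel = make_straight_vessel(2.8e-3, 0.08, 2.5e-4)
        with pytest.warns(UserWarning):
            dep = deploy_stent(design, vessel, 5e-3)
        assert dep.poor_apposition


class TestCells:
    def test_uniform_deployment_gives_equal_cells(self, nominal_cells):
        At = np.array([c.A_t for c in nominal_cells])
        assert At.std() / At.mean() < 0.01

    def test_cell_area_sums_to_lateral_area(self, nominal_deployment, nominal_cells):
        _design, vessel, dep = nominal_deployment
        At = np.array([c.A_t for c in nominal_cells])
        lateral = 2 * np.pi * vessel.radii[0] * (dep.end - dep.start)
        assert abs(At.sum() - lateral) / lateral < 0.03

    def test_pore_plus_wire_partition_cell(self, nominal_cells):
        for c in nominal_cells[:50]:
            assert c.A_p == pytest.approx(c.A_t - c.A_w, abs=0.0)
            assert 0 <= c.porosity <= 1
            assert c.hydraulic_diameter > 0

    def test_metal_strip_area_tracks_covered_wire_length(self):
        # the raw wire strip area per unit covered wire length is d_w for any
        # deployment; the crossing-overlap correction (subtracted from A_w)
        # is the only braid-angle-dependent part of the metal budget
        design = StentDesign(nominal_diameter=4.5e-3, nominal_length=8e-3)
        d_w = design.wire_diameter
        for R in (2.25e-3, 2.0e-3):
            vessel = make_straight_vessel(R, 0.08, 2.5e-4)
            cells = extract_cells(deploy_stent(design, vessel, 5e-3), design)
            strip = sum(c.A_w + d_w**2 / np.sin(c.braid_angle) for c in cells)
            covered_len = sum(2 * c.side_length for c in cells)  # 4 half-sides
            assert abs(strip - d_w * covered_len) / strip < 0.02

    def test_inner_curve_cells_smaller_than_outer(self):
        vessel = make_curved_vessel(2.25e-3, 15e-3, np.pi / 2, 1e-4)
        design = StentDesign(nominal_diameter=4.5e-3, nominal_length=8e-3)
        cells = extract_cells(deploy_stent(design, vessel, 4e-3), design)
        ang = np.array([c.angle for c in cells])
        At = np.array([c.A_t for c in cells])
        inner = At[np.cos(ang) > 0.5].mean()   # frame normal points to the bend center
        outer = At[np.cos(ang) < -0.5].mean()
        assert inner < outer

    def test_porosity_matches_rasterized_flat_braid(self):
        # synthetic flat braid: two strip families of width d_w at angle alpha,
        # spacing equal to the rhombus height s*sin(alpha); the open fraction
        # from pixel rasterization is the oracle for the cell formula
        s, alpha, d_w = 200e-6, np.pi / 3, 30e-6
        n = 2400
        # periodic unit cell in strip-normal coordinates: a point is metal if
        # its distance to either strip family's lattice is under d_w/2
        h = s * np.sin(alpha)
        xi = (np.arange(n) + 0.5) / n * h
        u1, u2 = np.meshgrid(xi, xi, indexing="ij")
        metal = (np.minimum(u1, h - u1) < d_w / 2) | (np.minimum(u2, h - u2) < d_w / 2)
        eps_raster = 1.0 - metal.mean()
        A_t = s**2 * np.sin(alpha)
        A_w = 2 * s * d_w - d_w**2 / np.sin(alpha)
        eps_cells = (A_t - A_w) / A_t
        assert abs(eps_cells - eps_raster) / eps_raster < 0.02

    def test_extracted_porosity_matches_rasterization_of_same_braid(self, nominal_cells):
        # rasterize a flat braid with the deployment's own mean cell side,
        # angle and wire width; the pixel-counted open fraction must agree
        # with the porosity extract_cells reports
        s = float(np.mean([c.side_length for c in nominal_cells]))
        alpha = float(np.mean([c.braid_angle for c in nominal_cells]))
        d_w = 30e-6
        h = s * np.sin(alpha)
        n = 2400
        xi = (np.arange(n) + 0.5) / n * h
        u1, u2 = np.meshgrid(xi, xi, indexing="ij")
        metal = (np.minimum(u1, h - u1) < d_w / 2) | (np.minimum(u2, h - u2) < d_w / 2)
        eps_raster = 1.0 - metal.mean()
        eps_cells = float(np.mean([c.porosity for c in nominal_cells]))
        assert abs(eps_cells - eps_raster) / eps_raster < 0.02

    def test_braid_angle_clip(self):
        design = StentDesign(nominal_diameter=4.5e-3)
        a = local_braid_angle(design, np.array([1e-5, 2.25e-3, 1.0]))
        assert a[0] >= 0.05 * np.pi - 1e-12
        assert a[2] <= 0.95 * np.pi + 1e-12
        assert a[1] == pytest.approx(np.deg2rad(150))
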