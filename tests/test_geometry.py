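import io

import numpy as np
import pytest

from stentflow.geometry import (
    AneurysmSpec,
    GeometryError,
    attach_aneurysm,
    make_curved_vessel,
    make_straight_vessel,
    parallel_transport_frames,
)


class TestStraightVessel:
    def test_construction(self):
        v = make_straight_vessel(0.002, 0.04, 0.0005)
        assert v.n_points == 81
        assert np.all(v.radii == 0.002)
        assert abs(v.arc_length[-1] - 0.04) < 1e-12

    def test_frames_constant(self):
        v = make_straight_vessel(0.002, 0.04, 0.0005)
        for arr in (v.tangents, v.normals, v.binormals):
            assert np.allclose(arr, arr[0])

    @pytest.mark.parametrize("radius,length", [(-1e-3, 0.04), (2e-3, 0.01), (2e-3, -0.1)])
    def test_bad_dimensions_rejected(self, radius, length):
        with pytest.raises(GeometryError):
            make_straight_vessel(radius, length, 2.5e-4)


class TestCurvedVessel:
    def test_arc_length(self):
        v = make_curved_vessel(0.002, 0.01, np.pi / 2, 1e-4)
        assert abs(v.arc_length[-1] - 0.01 * np.pi / 2) < 1e-10

    def test_zero_angle_degenerates_to_straight(self):
        v = make_curved_vessel(0.002, 0.01, 0.0, 2.5e-4)
        assert np.allclose(v.tangents, v.tangents[0])

    def test_half_turn_tangent_antiparallel(self):
        v = make_curved_vessel(0.002, 0.01, np.pi, 1e-4)
        assert abs(v.tangents[0] @ v.tangents[-1] + 1.0) < 1e-8

    def test_kink_rejected(self):
        with pytest.raises(GeometryError):
            make_curved_vessel(0.002, 0.003, np.pi / 2, 1e-4)

    def test_tangent_matches_analytic_arc(self):
        Rb, ang = 0.01, np.pi / 2
        v = make_curved_vessel(0.002, Rb, ang, 5e-5)
        phi = v.arc_length / Rb
        analytic = np.column_stack([np.cos(phi), np.sin(phi), np.zeros_like(phi)])
        assert np.max(np.abs(v.tangents - analytic)) < 1e-8


class TestAneurysm:
    def test_degenerate_dome_rejected(self):
        with pytest.raises(GeometryError):
            AneurysmSpec(dome_radius=0.0, neck_radius=0.0, position=0.02)

    def test_neck_wider_than_dome_rejected(self):
        with pytest.raises(GeometryError):
            AneurysmSpec(dome_radius=1e-3, neck_radius=2e-3, position=0.02)

    def test_attachment_too_close_to_end_rejected(self):
        v = make_straight_vessel(0.002, 0.04, 2.5e-4)
        with pytest.raises(GeometryError):
            attach_aneurysm(v, AneurysmSpec(2.5e-3, 1.25e-3, 1e-3))

    def test_sac_volume_close_to_spherical(self):
        # a wide sac barely clipped by the vessel: voxel volume near 4/3 pi r^3
        v = make_straight_vessel(0.002, 0.06, 2.5e-4)
        r = 3e-3
        att = attach_aneurysm(v, AneurysmSpec(r, 0.5e-3, 0.03))
        vol = att.sac_volume(voxel=r / 30)
        full = 4.0 / 3.0 * np.pi * r**3
        # the sphere minus the small cap inside the lumen
        h_cap = r - np.sqrt(r**2 - 0.5e-3**2)
        expect = full - np.pi * h_cap**2 * (3 * r - h_cap) / 3
        assert abs(vol - expect) / expect < 0.02

    def test_classification_labels(self):
        v = make_straight_vessel(0.002, 0.06, 2.5e-4)
        att = attach_aneurysm(v, AneurysmSpec(2.5e-3, 1.25e-3, 0.03))
        pts = np.array(
            [
                [0.03, 0.0, 0.0],                      # centerline -> lumen
                [0.03, 0.002 + 2.165e-3 + 1e-4, 0.0],  # dome center-ish -> sac
                [0.03, 0.02, 0.0],                     # far away -> exterior
            ]
        )
        labels = att.classify(pts)
        assert list(labels) == [att.LUMEN, att.SAC, att.EXTERIOR]


class TestCenterlineCSV:
    def test_round_trip(self, tmp_path):
        from stentflow.geometry import read_centerline_csv

        p = tmp_path / "cl.csv"
        rows = ["x,y,z,radius"] + [
            f"{0.001 * i},0,0,0.002" for i in range(20)
        ]
        p.write_text("\n".join(rows) + "\n")
        v = read_centerline_csv(p)
        assert v.n_points == 20
        assert v.length == pytest.approx(0.019)
        assert np.allclose(v.radii, 0.002)

    def test_missing_header_rejected(self, tmp_path):
        from stentflow.geometry import read_centerline_csv

        p = tmp_path / "bad.csv"
        p.write_text("a,b,c\n1,2,3\n")
        with pytest.raises(GeometryError):
            read_centerline_csv(p)


class TestFrames:
    def test_parallel_transport_orthonormal(self):
        t = np.linspace(0, 1, 50)
        pts = np.column_stack([np.cos(t), np.sin(t), 0.3 * t])
        tan, nrm, bnm = parallel_transport_frames(pts)
        assert np.max(np.abs(np.sum(tan * nrm, axis=1))) < 1e-10
        assert np.max(np.abs(np.linalg.norm(bnm, axis=1) - 1)) < 1e-10

    def test_lumen_volume_converges_with_refinement(self):
        v = make_straight_vessel(0.002, 0.04, 2.5e-4)
        att = attach_aneurysm(v, AneurysmSpec(1.5e-3, 0.5e-3, 0.02))
        exact = np.pi * 0.002**2 * 0.04
        errs = []
        for h in (8e-4, 4e-4, 2e-4):
            xs = np.arange(0.0, 0.04, h) + h / 2
            ys = np.arange(-0.00252, 0.00252, h) + h / 2
            X, Y, Z = np.meshgrid(xs, ys, ys, indexing="ij")
            pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
            lab = att.classify(pts)
            vol = np.count_nonzero(lab == att.LUMEN) * h**3
            errs.append(abs(vol - exact) / exact)
        assert errs[2] < errs[1] < errs[0]
        assert errs[2] < 0.01
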