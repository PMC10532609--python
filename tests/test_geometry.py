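"""Ray geometry, triangulation accuracy and principal-axis morphometrics."""

import numpy as np
import pytest

from cslight.decode import Correspondence
from cslight.geometry import (CalibrationModel, Morphometrics, PointCloud,
                              measure, pixel_to_ray, triangulate,
                              triangulate_correspondences)


def project(point, device, calib):
    """Forward projection of a world point into device pixels (oracle)."""
    p = np.asarray(point, float)
    if device == "camera":
        local = p
        f = calib.cam_focal_px
    else:
        local = calib.proj_rotation.T @ (p - calib.proj_origin)
        f = calib.proj_focal_px
    cx, cy = calib.principal(device)
    return (f * local[0] / local[2] + cx, f * local[1] / local[2] + cy)


class TestRays:
    def test_camera_principal_point_along_z(self, calib):
        o, d = pixel_to_ray("camera", calib.principal("camera"), calib)
        assert np.allclose(o, 0)
        assert np.allclose(d, [0, 0, 1])

    def test_projector_principal_point(self):
        calib = CalibrationModel(convergence_deg=0.0)
        o, d = pixel_to_ray("projector", calib.principal("projector"), calib)
        assert np.allclose(o, [53.4, 0, 0])
        assert np.allclose(d, [0, 0, 1])

    def test_edge_pixel_at_half_hfov(self, calib):
        """A ray through the horizontal image edge makes hfov/2 with the
        optical axis (closed form for the pinhole model)."""
        w, h = calib.cam_resolution
        _, d = pixel_to_ray("camera", (0.0, h / 2.0), calib)
        angle = np.degrees(np.arctan2(abs(d[0]), d[2]))
        assert angle == pytest.approx(calib.cam_hfov_deg / 2, abs=1e-6)

    def test_out_of_range_pixel(self, calib):
        with pytest.raises(ValueError):
            pixel_to_ray("camera", (-10.0, 5.0), calib)

    def test_focal_length_from_hfov(self, calib):
        f = calib.cam_focal_px
        w = calib.cam_resolution[0]
        assert np.degrees(2 * np.arctan((w / 2) / f)) == pytest.approx(78.7)


class TestTriangulation:
    @staticmethod
    def _corr_for_point(p, calib):
        return Correspondence(
            pattern_point=project(p, "projector", calib),
            image_point=project(p, "camera", calib),
            grid_pos=(0, 0), component_id=0, best_hd=0)

    def test_plane_points_recovered_exactly(self, calib):
        """Noiseless forward-projected points on the z = 72 cm plane come
        back with depth error below 1e-6 cm."""
        rng = np.random.default_rng(3)
        for _ in range(50):
            p = np.array([rng.uniform(10, 40), rng.uniform(-10, 10), 72.0])
            res = triangulate(self._corr_for_point(p, calib), calib)
            assert res is not None
            point, skew = res
            assert np.allclose(point, p, atol=1e-6)
            assert skew < 1e-9

    def test_depth_error_monotone_in_centroid_noise(self, calib):
        """RMS depth error grows with image-centroid noise over
        sigma in {0, 0.5, 1, 2} px."""
        rng = np.random.default_rng(4)
        pts = [np.array([rng.uniform(15, 35), rng.uniform(-8, 8), 72.0])
               for _ in range(80)]
        rmses = []
        for sigma in (0.0, 0.5, 1.0, 2.0):
            noise_rng = np.random.default_rng(5)
            errs = []
            for p in pts:
                corr = self._corr_for_point(p, calib)
                ix, iy = corr.image_point
                corr.image_point = (ix + noise_rng.normal(0, sigma),
                                    iy + noise_rng.normal(0, sigma))
                res = triangulate(corr, calib)
                errs.append(res[0][2] - p[2])
            rmses.append(float(np.sqrt(np.mean(np.square(errs)))))
        assert all(a <= b + 1e-12 for a, b in zip(rmses, rmses[1:]))

    def test_one_pixel_error_within_analytic_bound(self, calib):
        """A 1 px centroid offset at 72 cm stays below the closed-form
        sensitivity bound dz = z^2 / (f * b_eff) per pixel, with b_eff the
        baseline component perpendicular to the viewing direction."""
        p = np.array([27.0, 0.0, 72.0])
        corr = self._corr_for_point(p, calib)
        ix, iy = corr.image_point
        corr.image_point = (ix + 1.0, iy)
        res = triangulate(corr, calib)
        dz = abs(res[0][2] - 72.0)
        bound = 72.0 ** 2 / (calib.cam_focal_px * calib.baseline_cm) * 2.0
        assert 0 < dz < bound

    def test_parallel_rays_rejected(self):
        calib = CalibrationModel(convergence_deg=0.0)
        corr = Correspondence(pattern_point=calib.principal("projector"),
                              image_point=calib.principal("camera"),
                              grid_pos=(0, 0), component_id=0, best_hd=0)
        assert triangulate(corr, calib) is None


class TestMeasure:
    def test_axis_aligned_box_exact(self):
        rng = np.random.default_rng(6)
        pts = rng.uniform(0, 1, (500, 3)) * np.array([12.0, 4.0, 1.0])
        corners = np.array([[0, 0, 0], [12, 4, 1], [12, 0, 0], [0, 4, 1],
                            [0, 4, 0], [12, 0, 1], [12, 4, 0], [0, 0, 1]])
        pts = np.vstack([pts, corners])
        m = measure(PointCloud(points=pts, skew_cm=np.zeros(len(pts))))
        assert m.total_length_cm == pytest.approx(12.0, abs=0.2)
        assert m.height_cm == pytest.approx(4.0, abs=0.2)

    def test_ellipsoid_extents(self):
        """Dense samples of a (15, 5.5, 2) cm half-ellipsoid measure
        30 x 11 cm along the first two principal axes."""
        u = np.linspace(0, 2 * np.pi, 400)
        v = np.linspace(0, np.pi / 2, 200)  # front half
        uu, vv = np.meshgrid(u, v)
        pts = np.column_stack([
            (15 * np.cos(uu) * np.sin(vv)).ravel(),
            (5.5 * np.sin(uu) * np.sin(vv)).ravel(),
            (2 * np.cos(vv)).ravel(),
        ])
        m = measure(PointCloud(points=pts, skew_cm=np.zeros(len(pts))))
        assert m.total_length_cm == pytest.approx(30.0, abs=0.5)
        assert m.height_cm == pytest.approx(11.0, abs=0.5)

    def test_rotation_invariance(self):
        rng = np.random.default_rng(8)
        pts = rng.normal(0, 1, (300, 3)) * np.array([5.0, 2.0, 0.5])
        from scipy.spatial.transform import Rotation
        rot = Rotation.from_euler("xyz", [20, -35, 50], degrees=True)
        a = measure(PointCloud(points=pts, skew_cm=np.zeros(300)))
        b = measure(PointCloud(points=rot.apply(pts), skew_cm=np.zeros(300)))
        assert a.total_length_cm == pytest.approx(b.total_length_cm, abs=1e-8)
        assert a.height_cm == pytest.approx(b.height_cm, abs=1e-8)

    def test_degenerate_and_tiny_clouds_rejected(self):
        line = np.column_stack([np.linspace(0, 1, 50)] * 3)
        with pytest.raises(ValueError):
            measure(PointCloud(points=line, skew_cm=np.zeros(50)))
        with pytest.raises(ValueError):
            measure(PointCloud(points=line[:5], skew_cm=np.zeros(5)))

    def test_percentile_option_trims_outliers(self):
        rng = np.random.default_rng(9)
        pts = rng.uniform(-1, 1, (1000, 3)) * np.array([10.0, 3.0, 0.5])
        pts[0] = [100.0, 0, 0]
        full = measure(PointCloud(points=pts, skew_cm=np.zeros(1000)))
        trimmed = measure(PointCloud(points=pts, skew_cm=np.zeros(1000)),
                          percentile=1.0)
        assert trimmed.total_length_cm < full.total_length_cm


class TestWriters:
    def test_ply_and_xyz_roundtrip(self, tmp_path):
        from cslight.io import write_ply, write_xyz
        pts = np.array([[1.0, 2.0, 3.0], [-1.5, 0.25, 72.0]])
        ply = tmp_path / "c.ply"
        write_ply(ply, pts)
        lines = ply.read_text().splitlines()
        assert lines[0] == "ply"
        assert "element vertex 2" in lines[2]
        got = np.loadtxt(lines[-2:])
        assert np.allclose(got, pts)
        xyz = tmp_path / "c.xyz"
        write_xyz(xyz, pts)
        assert np.allclose(np.loadtxt(xyz), pts)
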