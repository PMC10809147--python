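import numpy as np
import pytest

from camdart._geometry import angular_distance, polar_from_cartesian
from camdart.errors import GeometryError
from camdart.shape_normalization import (
    PolarOutline,
    RadialMap,
    normalize_frame,
    outline_to_polar,
)

from conftest import circle_boundary, disk_mask, ellipse_boundary


class TestOutlineToPolar:
    def test_circle_all_radii_equal(self):
        outline = outline_to_polar(circle_boundary((50, 50), 10, n=36), (50, 50))
        np.testing.assert_allclose(outline.radii, 10.0, atol=0.01)
        assert outline.r_av == pytest.approx(10.0, abs=0.01)

    def test_ellipse_axis_radii(self):
        outline = outline_to_polar(ellipse_boundary((60, 60), a=20, b=10), (60, 60))
        assert outline.radius_at(0.0) == pytest.approx(20.0, abs=0.05)
        assert outline.radius_at(np.pi / 2) == pytest.approx(10.0, abs=0.05)

    def test_ellipse_r_av_matches_closed_form_average(self):
        a, b = 20.0, 10.0
        outline = outline_to_polar(ellipse_boundary((60, 60), a=a, b=b, n=360), (60, 60))
        theta = np.linspace(0, 2 * np.pi, 360, endpoint=False)
        analytic = (a * b / np.sqrt(b**2 * np.cos(theta) ** 2 + a**2 * np.sin(theta) ** 2)).mean()
        assert outline.r_av == pytest.approx(analytic, rel=1e-3)

    def test_centroid_outside_rejected(self):
        with pytest.raises(GeometryError):
            outline_to_polar(circle_boundary((50, 50), 10), (80, 80))

    def test_too_few_samples_rejected(self):
        with pytest.raises(GeometryError):
            outline_to_polar(circle_boundary((50, 50), 10, n=5), (50, 50))

    def test_nonconvex_outline_warns_and_takes_outermost(self):
        # circle with a deep inward fold: two crossings share an angular bin
        theta = np.linspace(0, 2 * np.pi, 720, endpoint=False)
        r = np.full(720, 20.0)
        r[100:104] = 5.0  # narrow spike toward the centroid
        boundary = np.stack([50 - r * np.sin(theta), 50 + r * np.cos(theta)], axis=1)
        with pytest.warns(UserWarning, match="star-convex"):
            outline = outline_to_polar(boundary, (50, 50), n_samples=45)
        # the outermost crossing wins in the folded bin
        assert outline.radii.min() > 15.0


class TestRadialMap:
    def test_angle_preserved_and_monotone(self):
        outline = outline_to_polar(ellipse_boundary((60, 60), a=20, b=10), (60, 60))
        rmap = RadialMap(outline, template_radius=outline.r_av)
        r = np.linspace(0.1, 20, 50)
        fwd = rmap.forward(r, 0.3)
        assert np.all(np.diff(fwd) > 0)  # no fold-over
        np.testing.assert_allclose(rmap.inverse(fwd, 0.3), r, rtol=1e-12)


def disk_cell(shape=(81, 81), center=(40, 40), radius=25, rng=None):
    frame = np.full(shape, 10.0)
    mask = disk_mask(shape, center, radius)
    frame[mask] = 100.0
    if rng is not None:
        frame += rng.random(shape)
    return frame, mask


class TestNormalizeFrame:
    def test_circular_cell_is_identity(self):
        frame, mask = disk_cell()
        outline = outline_to_polar(circle_boundary((40, 40), 25.0), (40, 40))
        out, disk = normalize_frame(frame, mask, outline)
        inside = disk
        same = (out[inside] == frame[inside]).mean()
        assert same >= 0.99

    def test_ellipse_boundary_spot_maps_to_template_radius(self):
        # bright spot at theta=0 on the ellipse boundary
        a, b, center = 24.0, 12.0, (40, 40)
        frame = np.full((81, 81), 10.0)
        theta_g = np.linspace(0, 2 * np.pi, 720)
        r_g = a * b / np.sqrt(b**2 * np.cos(theta_g) ** 2 + a**2 * np.sin(theta_g) ** 2)
        mask = np.zeros((81, 81), dtype=bool)
        yy, xx = np.mgrid[0:81, 0:81]
        rr, tt = polar_from_cartesian(yy - center[0], xx - center[1])
        mask = rr <= a * b / np.sqrt(b**2 * np.cos(tt) ** 2 + a**2 * np.sin(tt) ** 2)
        frame[mask] = 50.0
        spot = (40, 40 + int(a) - 2)  # near boundary at theta = 0
        frame[spot] = 500.0
        outline = outline_to_polar(ellipse_boundary(center, a=a, b=b), center)
        out, disk = normalize_frame(frame, mask, outline)
        py, px = np.unravel_index(np.argmax(out), out.shape)
        r_out, theta_out = polar_from_cartesian(py - 40, px - 40)
        r_spot, theta_spot = polar_from_cartesian(spot[0] - 40, spot[1] - 40)
        expected_r = r_spot / outline.radius_at(theta_spot) * outline.template_radius
        assert r_out == pytest.approx(expected_r, abs=1.0)
        assert angular_distance(theta_out, theta_spot) < 2 * np.pi / 90

    def test_interior_mean_preserved_for_smooth_field(self, rng):
        a, b, center = 24.0, 16.0, (40, 40)
        yy, xx = np.mgrid[0:81, 0:81]
        frame = 50.0 + 20.0 * np.sin(yy / 15.0) + 10.0 * np.cos(xx / 11.0)
        rr, tt = polar_from_cartesian(yy - center[0], xx - center[1])
        mask = rr <= a * b / np.sqrt(b**2 * np.cos(tt) ** 2 + a**2 * np.sin(tt) ** 2)
        outline = outline_to_polar(ellipse_boundary(center, a=a, b=b), center)
        out, disk = normalize_frame(frame, mask, outline)
        assert out[disk].mean() == pytest.approx(frame[mask].mean(), rel=0.05)

    def test_angle_preservation_property(self, rng):
        # random star-convex outline: image of any bright probe pixel keeps its angle
        theta_s = np.linspace(0, 2 * np.pi, 180, endpoint=False)
        r_s = 22 + 3 * np.cos(3 * theta_s + 1.0) + 2 * np.sin(5 * theta_s)
        boundary = np.stack([40 - r_s * np.sin(theta_s), 40 + r_s * np.cos(theta_s)], axis=1)
        outline = outline_to_polar(boundary, (40, 40))
        for probe_theta in rng.uniform(0, 2 * np.pi, 5):
            frame = np.full((81, 81), 10.0)
            r_b = outline.radius_at(probe_theta)
            py = int(round(40 - 0.8 * r_b * np.sin(probe_theta)))
            px = int(round(40 + 0.8 * r_b * np.cos(probe_theta)))
            frame[py, px] = 1000.0
            out, disk = normalize_frame(frame, frame > 5, outline)
            qy, qx = np.unravel_index(np.argmax(out), out.shape)
            _, theta_out = polar_from_cartesian(qy - 40, qx - 40)
            assert angular_distance(theta_out, probe_theta) < 2 * np.pi / 60

    def test_idempotent_on_template(self):
        frame, mask = disk_cell()
        outline = outline_to_polar(circle_boundary((40, 40), 25.0), (40, 40))
        once, disk = normalize_frame(frame, mask, outline)
        outline2 = outline_to_polar(circle_boundary((40, 40), outline.template_radius), (40, 40))
        twice, disk2 = normalize_frame(once, disk, outline2, template_radius=outline.template_radius)
        changed = (once[disk] != twice[disk]).mean()
        assert changed <= 0.02

    def test_normalized_mask_is_template_disk(self):
        frame, mask = disk_cell()
        outline = outline_to_polar(circle_boundary((40, 40), 25.0), (40, 40))
        _, disk = normalize_frame(frame, mask, outline)
        yy, xx = np.mgrid[0:81, 0:81]
        expected = np.hypot(yy - 40, xx - 40) <= outline.template_radius
        np.testing.assert_array_equal(disk, expected)


class TestNormalizeTrace:
    def make_trace(self, radii):
        from camdart.detection_tracking import CellTrace
        from camdart.image_model import FrameSequence

        frames, masks, boundaries = [], [], []
        for r in radii:
            frame = np.full((81, 81), 10.0)
            m = disk_mask((81, 81), (40, 40), r)
            frame[m] = 100.0
            frames.append(frame)
            masks.append(m)
            boundaries.append(circle_boundary((40, 40), r))
        return CellTrace(
            roi=FrameSequence(np.stack(frames), pixel_size_um=1.0, frame_interval_s=0.1),
            masks=np.stack(masks),
            boundaries=boundaries,
            frames=np.arange(len(radii)),
            source_track=0,
            offset_per_frame=np.zeros((len(radii), 2), dtype=int),
        )

    def test_oscillating_radius_becomes_constant(self):
        from camdart.shape_normalization import normalize_trace

        trace = self.make_trace([22, 25, 28, 25, 22])
        normalized, outlines, template_radius = normalize_trace(trace)
        assert template_radius == pytest.approx(25.0, abs=0.6)
        for s in range(5):
            ys, xs = np.nonzero(normalized.masks[s])
            r_max = np.hypot(ys - 40.0, xs - 40.0).max()
            assert r_max == pytest.approx(template_radius, abs=1.0)

    def test_circular_cell_content_stable(self):
        from camdart.shape_normalization import normalize_trace

        trace = self.make_trace([25, 25, 25])
        normalized, _, template_radius = normalize_trace(trace)
        inside = disk_mask((81, 81), (40, 40), 20)
        for s in range(3):
            same = (normalized.roi.data[s][inside] == trace.roi.data[s][inside]).mean()
            assert same >= 0.98
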