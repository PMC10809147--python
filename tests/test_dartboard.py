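import numpy as np
import pytest

from camdart._geometry import TWO_PI
from camdart.dartboard import (
    AlignedEvent,
    BeadContact,
    DartboardGeometry,
    accumulate,
    align_domains,
    assign_segment,
    clock_to_angle,
    moving_average_densities,
    render_dartboard,
)
from camdart.microdomain import DomainTimeSeries, Microdomain


class TestClockToAngle:
    @pytest.mark.parametrize(
        "clock,angle",
        [(3, 0.0), (12, np.pi / 2), (6, 3 * np.pi / 2), (9, np.pi), (7.5, 5 * np.pi / 4)],
    )
    def test_convention_anchors(self, clock, angle):
        assert clock_to_angle(clock) == pytest.approx(angle)

    @pytest.mark.parametrize("bad", [0, -1, 12.5])
    def test_out_of_range(self, bad):
        with pytest.raises(ValueError):
            clock_to_angle(bad)


class TestGeometry:
    def test_equal_area_radii_closed_form(self):
        geom = DartboardGeometry(n_rings=3, bullseye_frac=0.2, radius=1.0)
        np.testing.assert_allclose(
            geom.ring_radii, [0.2, np.sqrt(0.36), np.sqrt(0.68), 1.0]
        )

    def test_annuli_exactly_equal_area(self):
        geom = DartboardGeometry(n_rings=7, bullseye_frac=0.3, radius=2.5)
        r = geom.ring_radii
        areas = np.pi * (r[1:] ** 2 - r[:-1] ** 2)
        assert areas.max() / areas.min() == pytest.approx(1.0, rel=1e-12)

    def test_total_area(self):
        geom = DartboardGeometry()
        areas = geom.segment_areas
        total = areas[0, 0] + np.nansum(areas[1:])
        assert total == pytest.approx(np.pi * geom.radius**2, rel=1e-12)


class TestAssignSegment:
    def test_center_is_bullseye(self):
        assert assign_segment(0.0, 1.23, DartboardGeometry()) == (0, 0)

    def test_ring_example_closed_form(self):
        geom = DartboardGeometry(n_rings=3, bullseye_frac=0.2)
        ring, _ = assign_segment(0.7, 0.0, geom)
        assert ring == 2  # boundaries 0.6, 0.8246, 1.0

    def test_segment_zero_centered_on_reference(self):
        geom = DartboardGeometry(n_segments=12)
        w = TWO_PI / 12
        assert assign_segment(0.9, 0.0, geom)[1] == 0
        assert assign_segment(0.9, w / 2 - 1e-6, geom)[1] == 0
        assert assign_segment(0.9, w / 2 + 1e-6, geom)[1] == 1
        assert assign_segment(0.9, -w / 2 + 1e-6 + TWO_PI, geom)[1] == 0

    def test_overflow_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="clipping"):
            ring, _ = assign_segment(1.2, 0.0, DartboardGeometry())
        assert ring == DartboardGeometry().n_rings

    def test_monte_carlo_counts_proportional_to_areas(self):
        rng = np.random.default_rng(42)
        n = 100_000
        r = np.sqrt(rng.uniform(size=n))
        theta = rng.uniform(0, TWO_PI, n)
        geom = DartboardGeometry()
        counts = np.zeros((geom.n_rings + 1, geom.n_segments))
        for ri, ti in zip(r, theta):
            ring, seg = assign_segment(ri, ti, geom)
            counts[ring, seg] += 1
        areas = geom.segment_areas
        total_area = np.pi
        expect_bull = n * areas[0, 0] / total_area
        assert counts[0, 0] == pytest.approx(expect_bull, rel=0.05)
        expect_seg = n * areas[1, 0] / total_area
        np.testing.assert_allclose(counts[1:], expect_seg, rtol=0.12)


def one_domain_series(frame, centroid, cell_id=0):
    d = Microdomain(
        frame=frame,
        pixels=np.zeros((1, 2)),
        centroid=centroid,
        area_px=4,
        mean_rel_intensity=2.5,
        max_rel_intensity=3.0,
    )
    return DomainTimeSeries(cell_id=cell_id, domains_by_frame={frame: [d]})


class TestAlignDomains:
    def test_domain_at_contact_direction_lands_on_reference(self):
        center, radius = (40.0, 40.0), 20.0
        for clock in (1.5, 3, 6, 9, 12):
            ang = clock_to_angle(clock)
            centroid = (center[0] - 15 * np.sin(ang), center[1] + 15 * np.cos(ang))
            series = one_domain_series(5, centroid)
            contact = BeadContact(cell_id=0, contact_frame=5, clock_position=clock)
            (ev,) = align_domains(series, contact, center, radius, 0.1, reference_angle=0.0)
            assert ev.theta_aligned == pytest.approx(0.0, abs=1e-9)
            assert ev.r_frac == pytest.approx(0.75)
            assert ev.t_rel_s == 0.0

    def test_board_center_domain(self):
        series = one_domain_series(7, (40.0, 40.0))
        contact = BeadContact(cell_id=0, contact_frame=5, clock_position=6)
        (ev,) = align_domains(series, contact, (40.0, 40.0), 20.0, 0.5)
        assert ev.r_frac == 0.0
        assert ev.t_rel_s == pytest.approx(1.0)

    def test_clock12_domain_left_arithmetic(self):
        # contact at clock 12, domain at image angle pi: aligned = pi - pi/2 + ref
        series = one_domain_series(0, (40.0, 20.0))  # left of center
        contact = BeadContact(cell_id=0, contact_frame=0, clock_position=12)
        (ev,) = align_domains(series, contact, (40.0, 40.0), 20.0, 0.1,
                              reference_angle=np.pi / 2)
        assert ev.theta_aligned == pytest.approx(np.pi)

    def test_rotation_equivariance(self):
        # rotating contact clock and domain angle together leaves assignment fixed
        geom = DartboardGeometry()
        center, radius = (40.0, 40.0), 20.0
        base_angle = clock_to_angle(4) + 0.4
        results = []
        for dh in [0, 2, 5, 9]:
            clock = (4 + dh - 1) % 12 + 1
            ang = base_angle - dh * np.pi / 6
            centroid = (center[0] - 14 * np.sin(ang), center[1] + 14 * np.cos(ang))
            contact = BeadContact(cell_id=0, contact_frame=0, clock_position=clock)
            (ev,) = align_domains(one_domain_series(0, centroid), contact, center, radius, 0.1)
            results.append(assign_segment(ev.r_frac, ev.theta_aligned, geom))
        assert len(set(results)) == 1


class TestAccumulate:
    def test_empty_events_zero_densities(self):
        acc = accumulate([], DartboardGeometry(), [(0, 5), (5, 10)], n_cells=3)
        assert acc.counts.sum() == 0
        assert np.nansum(acc.densities) == 0

    def test_single_bullseye_event_density_formula(self):
        geom = DartboardGeometry()
        ev = AlignedEvent(t_rel_s=2.0, r_frac=0.05, theta_aligned=1.0)
        acc = accumulate([ev], geom, [(0.0, 5.0)], n_cells=1)
        assert acc.counts[0, 0, 0] == 1
        assert acc.densities[0, 0, 0] == pytest.approx(1.0 / (geom.bullseye_area * 5.0))

    def test_doubling_events_doubles_densities(self):
        geom = DartboardGeometry()
        evs = [AlignedEvent(t_rel_s=1.0, r_frac=0.7, theta_aligned=0.3)] * 3
        a1 = accumulate(evs, geom, [(0.0, 5.0)], n_cells=2)
        a2 = accumulate(evs * 2, geom, [(0.0, 5.0)], n_cells=2)
        np.testing.assert_allclose(
            np.nan_to_num(a2.densities), 2 * np.nan_to_num(a1.densities)
        )

    def test_count_conservation(self, rng):
        geom = DartboardGeometry()
        evs = [
            AlignedEvent(
                t_rel_s=float(rng.uniform(0, 15)),
                r_frac=float(np.sqrt(rng.uniform())),
                theta_aligned=float(rng.uniform(0, TWO_PI)),
            )
            for _ in range(500)
        ]
        bins = [(0.0, 5.0), (5.0, 10.0), (10.0, 15.0)]
        acc = accumulate(evs, geom, bins, n_cells=5)
        for b, (lo, hi) in enumerate(bins):
            in_window = sum(lo <= e.t_rel_s < hi for e in evs)
            assert acc.counts[b].sum() == in_window

    def test_overlapping_bins_rejected(self):
        with pytest.raises(ValueError):
            accumulate([], DartboardGeometry(), [(0, 5), (4, 8)], n_cells=1)

    def test_densities_recomputable_from_counts(self, rng):
        geom = DartboardGeometry()
        evs = [AlignedEvent(1.0, 0.5, 0.8)] * 7
        acc = accumulate(evs, geom, [(0.0, 2.0)], n_cells=4)
        manual = acc.counts / (geom.segment_areas[None] * 2.0 * 4)
        np.testing.assert_allclose(
            np.nan_to_num(acc.densities), np.nan_to_num(manual)
        )


class TestMovingAverage:
    def make_acc(self, counts_t):
        geom = DartboardGeometry(n_segments=4, n_rings=2)
        n = len(counts_t)
        counts = np.zeros((n, 3, 4), dtype=int)
        counts[:, 1, 0] = counts_t
        bins = [(float(i), float(i + 1)) for i in range(n)]
        return accumulate([], geom, bins, 1).__class__(
            counts=counts, geom=geom, time_bins=bins, n_cells=1
        )

    def test_constant_unchanged(self):
        acc = self.make_acc([3, 3, 3, 3, 3])
        out = moving_average_densities(acc, window_s=3.0)
        np.testing.assert_allclose(out[:, 1, 0], acc.densities[:, 1, 0])

    def test_impulse_spreads_thirds(self):
        acc = self.make_acc([0, 0, 3, 0, 0])
        out = moving_average_densities(acc, window_s=3.0)
        d = acc.densities[2, 1, 0]
        np.testing.assert_allclose(out[1:4, 1, 0], d / 3)
        assert out[0, 1, 0] == 0

    def test_sum_preserved_in_interior(self):
        acc = self.make_acc([1, 2, 5, 2, 1, 0, 0])
        out = moving_average_densities(acc, window_s=3.0)
        assert out[:, 1, 0].sum() == pytest.approx(acc.densities[:, 1, 0].sum(), rel=0.2)

    def test_window_shorter_than_bin_rejected(self):
        with pytest.raises(ValueError):
            moving_average_densities(self.make_acc([1, 2]), window_s=0.5)


class TestRender:
    def test_roundtrip_segment_values(self):
        import matplotlib

        matplotlib.use("Agg")
        geom = DartboardGeometry(n_segments=6, n_rings=3)
        counts = np.zeros((1, 4, 6), dtype=int)
        counts[0, 2, 1] = 5
        counts[0, 3, 4] = 2
        from camdart.dartboard import DartboardAccumulator

        acc = DartboardAccumulator(counts=counts, geom=geom, time_bins=[(0.0, 5.0)], n_cells=2)
        fig, ax = render_dartboard(acc)
        mesh_vals = np.asarray(ax.collections[0].get_array()).reshape(3, 6)
        np.testing.assert_allclose(mesh_vals, acc.densities[0, 1:, :])
        import matplotlib.pyplot as plt

        plt.close(fig)
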