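"""Iterative place-field detection and field geometry."""

import numpy as np
import pytest
from scipy import ndimage

from placepop.environments import EnvironmentSpec
from placepop.fields import (
    PlaceField,
    detect_fields,
    field_geometry,
    field_maps,
)


def bump(gx, gy, cx, cy, sigma, amp):
    return amp * np.exp(-((gx - cx) ** 2 + (gy - cy) ** 2) / (2 * sigma**2))


def flood_fill_components(mask):
    """Independent 4-connected labelling oracle."""
    labels, n = ndimage.label(mask, structure=ndimage.generate_binary_structure(2, 1))
    return [set(map(tuple, np.argwhere(labels == k))) for k in range(1, n + 1)]


class TestDetectFields:
    def test_flat_low_map_has_no_fields(self, env_a, make_analytic_ratemap):
        rm = make_analytic_ratemap(env_a, lambda gx, gy: np.full(gx.shape, 0.5))
        assert detect_fields(rm, (rm, rm)) == []

    def test_single_bump_equals_superlevel_component(self, env_a, make_analytic_ratemap):
        rm = make_analytic_ratemap(
            env_a, lambda gx, gy: bump(gx, gy, 44, 60, 12, 8.0)
        )
        fields = detect_fields(rm, (rm, rm))
        assert len(fields) == 1
        # oracle: the 1-Hz superlevel set's connected component
        comps = flood_fill_components(rm.rate >= 1.0)
        assert len(comps) == 1
        assert fields[0].bins == frozenset(comps[0])

    def test_two_bumps_merged_at_base_threshold_split_into_two(
        self, env_a, make_analytic_ratemap
    ):
        # bumps merged at 1 Hz (saddle ~1.3 Hz) but separate above 1.5 Hz
        fn = lambda gx, gy: bump(gx, gy, 24, 50, 9, 8.0) + bump(gx, gy, 52, 79, 9, 8.0)
        rm = make_analytic_ratemap(env_a, fn)
        comps_at_base = flood_fill_components(rm.rate >= 1.0)
        assert len(comps_at_base) == 1  # merged at the base threshold
        n_by_level = {
            thr: len(flood_fill_components(rm.rate >= thr))
            for thr in np.arange(1.0, 3.0, 0.05)
        }
        assert max(n_by_level.values()) == 2  # brute-force scan confirms a split
        fields = detect_fields(rm, (rm, rm))
        assert len(fields) == 2
        assert fields[0].bins.isdisjoint(fields[1].bins)

    def test_each_field_is_one_connected_component(self, env_a, make_analytic_ratemap):
        fn = lambda gx, gy: bump(gx, gy, 24, 30, 9, 6.0) + bump(gx, gy, 60, 95, 9, 7.0)
        rm = make_analytic_ratemap(env_a, fn)
        for f in detect_fields(rm, (rm, rm)):
            comps = flood_fill_components(f.mask(rm.shape))
            assert len(comps) == 1

    def test_unstable_candidate_rejected(self, env_a, make_analytic_ratemap):
        rm = make_analytic_ratemap(env_a, lambda gx, gy: bump(gx, gy, 44, 60, 12, 8.0))
        # an uncorrelated odd/even pair: stability gate must reject
        rng = np.random.default_rng(0)
        noise_a = make_analytic_ratemap(
            env_a, lambda gx, gy: rng.uniform(0, 8, size=gx.shape)
        )
        noise_b = make_analytic_ratemap(
            env_a, lambda gx, gy: rng.uniform(0, 8, size=gx.shape)
        )
        assert detect_fields(rm, (noise_a, noise_b)) == []

    def test_raising_min_peak_never_adds_fields(self, env_a, make_analytic_ratemap):
        fn = lambda gx, gy: bump(gx, gy, 24, 30, 9, 3.0) + bump(gx, gy, 60, 95, 9, 8.0)
        rm = make_analytic_ratemap(env_a, fn)
        counts = [
            len(detect_fields(rm, (rm, rm), min_peak=p)) for p in (2.0, 4.0, 9.0)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_spiking_two_bump_cell_yields_two_fields(self, two_bump_session):
        _, _, rm, splits = two_bump_session
        fields = detect_fields(rm, splits)
        assert len(fields) == 2

    def test_geometry_mismatch_rejected(self, env_a, env_d, make_analytic_ratemap):
        rm = make_analytic_ratemap(env_a, lambda gx, gy: np.zeros(gx.shape))
        other = make_analytic_ratemap(env_d, lambda gx, gy: np.zeros(gx.shape))
        with pytest.raises(ValueError):
            detect_fields(rm, (other, other))


class TestFieldGeometry:
    def _field(self, bins):
        return PlaceField(
            bins=frozenset(bins),
            threshold_hz=1.0,
            peak_bin=(0, 0),
            peak_rate=5.0,
            area_cm2=16.0 * len(bins),
            width_x_cm=0.0,
            width_y_cm=0.0,
        )

    def test_rectangle_area_and_widths(self, env_a, make_analytic_ratemap):
        rm = make_analytic_ratemap(env_a, lambda gx, gy: np.ones(gx.shape))
        bins = {(i, j) for i in range(3) for j in range(5)}
        area, wx, wy, _ = field_geometry(self._field(bins), rm)
        assert (area, wx, wy) == (240.0, 12.0, 20.0)

    def test_l_shape_widths_are_bounding_extent(self, env_a, make_analytic_ratemap):
        rm = make_analytic_ratemap(env_a, lambda gx, gy: np.ones(gx.shape))
        bins = {(i, 0) for i in range(4)} | {(0, j) for j in range(4)}
        bins |= {(1, 1), (2, 1), (1, 2), (3, 1), (1, 3)}
        assert len(bins) == 12
        area, wx, wy, _ = field_geometry(self._field(bins), rm)
        assert (area, wx, wy) == (192.0, 16.0, 16.0)

    def test_single_row_field_has_4cm_orthogonal_width(self, env_a, make_analytic_ratemap):
        rm = make_analytic_ratemap(env_a, lambda gx, gy: np.ones(gx.shape))
        bins = {(i, 7) for i in range(6)}
        _, wx, wy, _ = field_geometry(self._field(bins), rm)
        assert wy == 4.0 and wx == 24.0

    def test_empty_field_rejected(self, env_a, make_analytic_ratemap):
        rm = make_analytic_ratemap(env_a, lambda gx, gy: np.ones(gx.shape))
        with pytest.raises(ValueError):
            field_geometry(self._field(set()) , rm)


class TestFieldMaps:
    def _field(self, bins, area, peak):
        return PlaceField(
            bins=frozenset(bins),
            threshold_hz=1.0,
            peak_bin=peak,
            peak_rate=5.0,
            area_cm2=area,
            width_x_cm=8.0,
            width_y_cm=8.0,
        )

    def test_single_field_bins_carry_its_area(self, env_a):
        f = self._field({(2, 2), (2, 3)}, 160.0, (2, 2))
        out = field_maps([f], env_a)
        assert out["mean_area_cm2"][2, 2] == 160.0
        assert np.isnan(out["mean_area_cm2"][10, 10])

    def test_overlap_bins_average_areas(self, env_a):
        f1 = self._field({(2, 2), (2, 3)}, 160.0, (2, 2))
        f2 = self._field({(2, 3), (2, 4)}, 320.0, (2, 4))
        out = field_maps([f1, f2], env_a)
        assert out["mean_area_cm2"][2, 3] == 240.0

    def test_outer_band_peak_density(self):
        # env B has a single complete outer band (25-cm) plus remainder
        env = EnvironmentSpec("B", 175.0, 125.0)
        # 10 peaks in the outer band (within 25 cm of a wall)
        peaks = [(1, 1), (1, 10), (1, 20), (40, 1), (20, 1), (30, 30),
                 (43, 5), (2, 28), (40, 29), (22, 2)]
        fields = [self._field({p}, 16.0, p) for p in peaks]
        out = field_maps(fields, env)
        # oracle: outer-band area by subtracting the nested rectangle
        inner_w, inner_h = 175 - 50, 125 - 50
        outer_m2 = (175 * 125 - inner_w * inner_h) / 1e4
        band0_in_band = sum(1 for p in peaks
                            if min(p[0] * 4 + 2, 175 - p[0] * 4 - 2,
                                   p[1] * 4 + 2, 125 - p[1] * 4 - 2) < 25)
        assert out["band_area_m2"][0] == pytest.approx(outer_m2, rel=0.05)
        assert out["peak_density_per_m2"][0] == pytest.approx(
            band0_in_band / out["band_area_m2"][0]
        )
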