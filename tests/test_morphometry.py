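"""Densities, partitions, extent fractions, layer widths and Mann-Whitney."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import mannwhitneyu
from shapely.geometry import Polygon

from patchdev import (
    GeometryError,
    GradientConfig,
    LayerProfile,
    PointPattern,
    PointPatternConfig,
    ROI,
    cell_density,
    density_trajectory,
    dv_partition,
    gen_dv_gradient_mask,
    gen_point_pattern,
    layer_widths,
    mann_whitney_two_tailed,
    marker_extent_fraction,
    read_point_table,
    write_point_table,
)
from conftest import exact_mw_two_tailed_by_permutation

SQUARE_1MM = ((0.0, 0.0), (1000.0, 0.0), (1000.0, 1000.0), (0.0, 1000.0))


def _square_pattern(points, marker="calbindin"):
    return PointPattern(points=np.asarray(points, float), marker=marker,
                        region=Polygon(SQUARE_1MM), region_area_mm2=1.0)


class TestCellDensity:
    def test_exact_arithmetic(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 1000, size=(100, 2))
        small = PointPattern(points=pts * [0.316227766, 0.316227766],
                             marker="cb",
                             region=Polygon([(0, 0), (316.227766, 0),
                                             (316.227766, 316.227766),
                                             (0, 316.227766)]),
                             region_area_mm2=0.1)
        est = cell_density(small)
        assert est.count == 100
        assert est.density == pytest.approx(1000.0)

    def test_empty_pattern_zero_density(self):
        est = cell_density(_square_pattern(np.empty((0, 2))))
        assert est.density == 0.0

    def test_density_recovered_from_generator(self):
        dens = [cell_density(gen_point_pattern(PointPatternConfig(
            region_polygon=SQUARE_1MM, density_per_mm2=1000.0, seed=s))).density
            for s in range(20)]
        sem = np.std(dens, ddof=1) / np.sqrt(len(dens))
        assert abs(np.mean(dens) - 1000.0) < 3 * sem + 1e-9

    def test_rigid_motion_invariance(self):
        pp = gen_point_pattern(PointPatternConfig(
            region_polygon=SQUARE_1MM, density_per_mm2=500.0, seed=1))
        th = 0.7
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        moved = PointPattern(points=pp.points @ R.T + [500, -200],
                             marker=pp.marker,
                             region=Polygon(np.asarray(SQUARE_1MM) @ R.T + [500, -200]),
                             region_area_mm2=pp.region_area_mm2)
        assert cell_density(moved).density == cell_density(pp).density

    def test_declared_area_must_match_polygon(self):
        with pytest.raises(GeometryError, match="area"):
            PointPattern(points=np.empty((0, 2)), marker="cb",
                         region=Polygon(SQUARE_1MM), region_area_mm2=2.0)


class TestDVPartition:
    def test_uniform_pattern_gives_equal_thirds(self):
        pp = gen_point_pattern(PointPatternConfig(
            region_polygon=SQUARE_1MM, density_per_mm2=3000.0, seed=2))
        assert pp.count >= 3000 - 3 * np.sqrt(3000)
        part = dv_partition(pp)
        for v in part.proportions.values():
            assert abs(v - 1 / 3) < 0.05

    def test_all_points_dorsal(self):
        rng = np.random.default_rng(3)
        pts = np.column_stack([rng.uniform(0, 1000, 200), rng.uniform(0, 300, 200)])
        part = dv_partition(_square_pattern(pts))
        assert part.proportions["dorsal"] == pytest.approx(1.0)
        assert part.proportions["intermediate"] == 0.0
        assert part.proportions["ventral"] == 0.0

    def test_linear_gradient_recovers_1_2_3(self):
        # slope 1.5 makes the third-bin densities proportional to 1:2:3
        pp = gen_point_pattern(PointPatternConfig(
            region_polygon=SQUARE_1MM, density_per_mm2=3000.0,
            dv_gradient_slope=1.5, seed=4))
        part = dv_partition(pp)
        expect = {"dorsal": 1 / 6, "intermediate": 2 / 6, "ventral": 3 / 6}
        for k, v in expect.items():
            assert abs(part.proportions[k] - v) < 0.05

    def test_count_conservation_and_normalization(self):
        pp = gen_point_pattern(PointPatternConfig(
            region_polygon=SQUARE_1MM, density_per_mm2=800.0,
            dv_gradient_slope=0.8, seed=5))
        part = dv_partition(pp)
        assert sum(d.count for d in part.thirds.values()) == pp.count
        assert sum(part.proportions.values()) == pytest.approx(1.0, abs=1e-9)

    def test_degenerate_axis_rejected(self):
        pp = _square_pattern(np.array([[1.0, 1.0]]))
        with pytest.raises(GeometryError):
            dv_partition(pp, dv_axis=(0.0, 0.0))


class TestDensityTrajectory:
    @staticmethod
    def _estimates(density, n, seed0):
        return [cell_density(gen_point_pattern(PointPatternConfig(
            region_polygon=SQUARE_1MM, density_per_mm2=density, seed=seed0 + s)))
            for s in range(n)]

    def test_single_estimate_group(self):
        ests = self._estimates(500, 1, 0)
        df = density_trajectory({"P4": ests})
        assert df.loc[0, "mean_density"] == ests[0].density
        assert df.loc[0, "sd_density"] == 0.0

    def test_developmental_decline_recovered(self):
        # mirrors the declining layer-3 trajectory: 955 -> 333 -> 141 cells/mm^2
        groups = {"P4-P8": self._estimates(955, 8, 10),
                  "P12-P16": self._estimates(333, 8, 30),
                  "adult": self._estimates(141, 7, 50)}
        df = density_trajectory(groups)
        means = df.mean_density.to_numpy()
        for m, true in zip(means, (955, 333, 141)):
            assert abs(m - true) / true < 0.10
        assert np.all(np.diff(means) < 0)

    def test_order_within_group_is_irrelevant(self):
        ests = self._estimates(400, 5, 70)
        a = density_trajectory({"g": ests})
        b = density_trajectory({"g": ests[::-1]})
        assert a.equals(b)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="no density"):
            density_trajectory({"g": []})


class TestExtentFraction:
    BAND = ROI(("rect", (0, 0, 60, 400)), dv_axis=(0.0, 1.0))

    def test_uniform_bright_band(self):
        img = gen_dv_gradient_mask(self.BAND, GradientConfig(front_fraction=1.0))
        assert marker_extent_fraction(img, self.BAND, threshold=0.5).fraction == 1.0

    def test_uniform_dark_band(self):
        img = gen_dv_gradient_mask(self.BAND, GradientConfig(front_fraction=0.0))
        assert marker_extent_fraction(img, self.BAND, threshold=0.5).fraction == 0.0

    @pytest.mark.parametrize("ff", [0.1, 0.4, 0.75, 1.0])
    def test_generator_round_trip(self, ff):
        img = gen_dv_gradient_mask(
            self.BAND, GradientConfig(front_fraction=ff, front_softness_um=4.0),
            pixel_size_um=2.0)
        ef = marker_extent_fraction(img, self.BAND, threshold=0.5)
        assert abs(ef.fraction - ff) <= 0.02

    def test_otsu_default_threshold_round_trip(self):
        img = gen_dv_gradient_mask(
            self.BAND, GradientConfig(front_fraction=0.4, front_softness_um=4.0),
            pixel_size_um=2.0)
        ef = marker_extent_fraction(img, self.BAND)
        assert abs(ef.fraction - 0.4) <= 0.02

    def test_monotone_in_front_fraction(self):
        fracs = []
        for ff in np.linspace(0, 1, 11):
            img = gen_dv_gradient_mask(
                self.BAND, GradientConfig(front_fraction=float(ff),
                                          front_softness_um=2.0))
            fracs.append(marker_extent_fraction(img, self.BAND, threshold=0.5).fraction)
        assert np.all(np.diff(fracs) >= 0)

    def test_short_band_rejected(self):
        short = ROI(("rect", (0, 0, 60, 40)), dv_axis=(0.0, 1.0))
        img = gen_dv_gradient_mask(short, GradientConfig(front_fraction=0.5))
        with pytest.raises(GeometryError, match="50"):
            marker_extent_fraction(img, short, threshold=0.5)

    def test_ventral_island_not_added_to_front(self):
        img = gen_dv_gradient_mask(
            self.BAND, GradientConfig(front_fraction=0.3, front_softness_um=0.0))
        px = img.pixels.copy()
        px[350:360, :] = 1.0  # isolated ventral island
        from patchdev import Image2D

        ef = marker_extent_fraction(Image2D(px, img.pixel_size_um), self.BAND,
                                    threshold=0.5)
        assert abs(ef.fraction - 0.3) <= 0.02
        assert ef.islands_ventral > 0


class TestLayerWidths:
    def test_flat_parallel_boundaries_exact(self):
        # boundary depths 0 / 100 / 343 / 995 um -> widths 100, 243, 652 um
        base = np.array([[0.0, 0.0], [1000.0, 0.0]])
        profile = LayerProfile(
            boundaries=[base, base + [0, 100], base + [0, 343], base + [0, 995]],
            boundary_names=["pia", "l12", "l34", "wm"],
            sample_positions={"dorsal": (200.0, 0.0), "medial": (500.0, 0.0),
                              "ventral": (800.0, 0.0)})
        df = layer_widths(profile)
        for pos in ("dorsal", "medial", "ventral"):
            w = df[df.position == pos].width_um.to_numpy()
            assert np.allclose(w, [100.0, 243.0, 652.0])

    def test_proportions_sum_to_one(self):
        base = np.array([[0.0, 0.0], [1000.0, 0.0]])
        profile = LayerProfile(
            boundaries=[base, base + [0, 150], base + [0, 900]],
            boundary_names=["pia", "mid", "wm"],
            sample_positions={"medial": (500.0, 0.0)})
        df = layer_widths(profile)
        assert df.proportion.sum() == pytest.approx(1.0)

    def test_curved_concentric_boundaries(self):
        th = np.linspace(0.0, np.pi / 2, 400)

        def arc(r):
            return np.column_stack([r * np.cos(th), r * np.sin(th)])

        profile = LayerProfile(
            boundaries=[arc(1000.0), arc(900.0), arc(650.0)],
            boundary_names=["pia", "a", "b"],
            sample_positions={"mid": (1000 * np.cos(0.8), 1000 * np.sin(0.8))})
        df = layer_widths(profile)
        w = df.width_um.to_numpy()
        assert abs(w[0] - 100.0) / 100.0 < 0.01
        assert abs(w[1] - 250.0) / 250.0 < 0.01

    def test_crossing_boundaries_rejected(self):
        base = np.array([[0.0, 0.0], [1000.0, 0.0]])
        # middle boundary lies beyond the white matter at the sampled normal
        crossing = np.array([[0.0, 200.0], [1000.0, 200.0]])
        profile = LayerProfile(
            boundaries=[base, crossing, base + [0, 100]],
            boundary_names=["pia", "x", "wm"],
            sample_positions={"medial": (500.0, 0.0)})
        with pytest.raises(GeometryError, match="cross"):
            layer_widths(profile)


class TestMannWhitney:
    def test_identical_samples_give_p_one(self):
        res = mann_whitney_two_tailed([1, 2, 3], [1, 2, 3])
        assert res.p_value == 1.0

    def test_fully_separated_small_samples_exact(self):
        # all 20 rank arrangements: two-tailed p = 2/20
        res = mann_whitney_two_tailed([1, 2, 3], [4, 5, 6])
        assert res.method == "exact"
        assert res.p_value == pytest.approx(0.1)

    def test_exact_matches_permutation_oracle_small_layouts(self):
        rng = np.random.default_rng(0)
        for n_a in range(1, 6):
            for n_b in range(1, 6):
                vals = rng.permutation(np.arange(1.0, n_a + n_b + 1))
                a, b = vals[:n_a], vals[n_a:]
                res = mann_whitney_two_tailed(a, b)
                assert res.method == "exact"
                assert res.p_value == pytest.approx(
                    exact_mw_two_tailed_by_permutation(a, b), abs=1e-12)

    def test_exact_matches_scipy(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 6)
        b = rng.normal(1, 1, 7)
        res = mann_whitney_two_tailed(a, b)
        ref = mannwhitneyu(a, b, alternative="two-sided", method="exact")
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_normal_approx_close_to_exact_at_n8(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 1, 8)
        b = rng.normal(0.8, 1, 8)
        exact = mann_whitney_two_tailed(a, b)
        approx = mann_whitney_two_tailed(a, b, exact_limit=0)
        assert exact.method == "exact" and approx.method == "normal_approx"
        assert abs(exact.p_value - approx.p_value) < 0.01

    @given(st.lists(st.integers(0, 50), min_size=1, max_size=8),
           st.lists(st.integers(0, 50), min_size=1, max_size=8))
    @settings(max_examples=50, deadline=None)
    def test_p_in_unit_interval_and_swap_invariant(self, a, b):
        r1 = mann_whitney_two_tailed(a, b)
        r2 = mann_whitney_two_tailed(b, a)
        assert 0.0 < r1.p_value <= 1.0
        assert r1.p_value == pytest.approx(r2.p_value, abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_two_tailed([], [1.0])


class TestPointTableIO:
    def test_roundtrip(self, tmp_path):
        pp = gen_point_pattern(PointPatternConfig(
            region_polygon=SQUARE_1MM, density_per_mm2=300.0, seed=6))
        path = tmp_path / "cells.tsv"
        write_point_table(pp, path)
        header = path.read_text().splitlines()[0]
        assert header.split("\t") == ["x_um", "y_um", "marker", "region"]
        back = read_point_table(path, Polygon(SQUARE_1MM))
        assert np.allclose(back.points, pp.points)
        assert back.marker == pp.marker
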