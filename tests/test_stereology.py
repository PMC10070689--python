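"""Unit tests for the grid test system and stereological estimators."""

import math

import numpy as np
import pytest

from microstereo import (
    CountingFrame,
    Ellipse,
    FieldCounts,
    GridSpec,
    VesselScene,
    apply_cavity_rule,
    boundary_length,
    count_intersections,
    count_points,
    count_profiles,
    generate_grid,
    normalize_field,
    point_count_area,
    quantify_field,
    render,
    render_labels,
)
from conftest import disc_scene

PX = 0.33


class TestGrid:
    def test_zero_offset_line_and_point_counts(self):
        spec = GridSpec(offset_x_um=0.0, offset_y_um=0.0)
        grid = generate_grid(spec)
        assert len(grid.xs) == 25
        assert len(grid.ys) == 35
        assert grid.n_points == 875

    def test_seeded_offsets_differ_but_counts_stable(self):
        spec = GridSpec()
        g1, g2 = generate_grid(spec, seed=1), generate_grid(spec, seed=2)
        assert (g1.offset_x_um, g1.offset_y_um) != (g2.offset_x_um, g2.offset_y_um)
        assert abs(len(g1.xs) - len(g2.xs)) <= 1
        assert abs(len(g1.ys) - len(g2.ys)) <= 1
        # determinism
        g1b = generate_grid(spec, seed=1)
        np.testing.assert_array_equal(g1.xs, g1b.xs)
        np.testing.assert_array_equal(g1.ys, g1b.ys)

    def test_field_smaller_than_pitch_names_dimension(self):
        with pytest.raises(ValueError, match="field_width_um"):
            GridSpec(field_width_um=10.0)
        with pytest.raises(ValueError, match="field_height_um"):
            GridSpec(field_height_um=10.0)

    def test_mean_point_number_matches_field_area(self):
        """E[#points] x d^2 equals the field area (uniform-offset sampling)."""
        spec = GridSpec()
        mean_points = np.mean([generate_grid(spec, seed=s).n_points for s in range(1000)])
        field_area = spec.field_width_um * spec.field_height_um
        assert mean_points * spec.area_per_point_um2 == pytest.approx(field_area, rel=0.01)

    def test_offset_outside_pitch_rejected(self):
        with pytest.raises(ValueError, match="offset"):
            GridSpec(offset_x_um=13.0)


class TestCounts:
    def test_empty_mask_zero_everywhere(self, default_spec):
        shape = (1301, 964)
        empty = np.zeros(shape, dtype=bool)
        roi = np.ones(shape, dtype=bool)
        grid = generate_grid(default_spec, seed=0)
        p, p_roi = count_points(empty, roi, grid, PX)
        assert p == 0 and p_roi == grid.n_points
        assert count_intersections(empty, roi, grid, PX) == (0, 0)

    def test_vessel_equal_to_roi_gives_p_equal_p_roi(self, default_spec):
        shape = (1301, 964)
        roi = np.zeros(shape, dtype=bool)
        roi[100:600, 100:600] = True
        grid = generate_grid(default_spec, seed=3)
        p, p_roi = count_points(roi, roi, grid, PX)
        assert p == p_roi > 0

    def test_mismatched_dimensions_raise(self, default_spec):
        grid = generate_grid(default_spec, seed=0)
        with pytest.raises(ValueError, match="dimensions"):
            count_points(np.zeros((10, 10), bool), np.zeros((11, 10), bool), grid, PX)

    def test_square_straddling_two_lines_each_way(self):
        # Lines at 6.125 + k*12.25; a 30 um square over [10, 40) in x and y
        # is traversed by exactly two lines of each family.
        spec = GridSpec(offset_x_um=6.125, offset_y_um=6.125)
        grid = generate_grid(spec)
        mask = np.zeros((1301, 964), dtype=bool)
        lo, hi = int(10 / PX), int(40 / PX)
        mask[lo:hi, lo:hi] = True
        roi = np.ones_like(mask)
        assert count_intersections(mask, roi, grid, PX) == (4, 4)

    def test_disc_point_and_intersection_expectations(self, disc40):
        """1000 random offsets: d^2*E[P] ~ disc area, E[B] ~ circumference (2%)."""
        scene, mask, roi = disc40
        spec = GridSpec()
        ps, bs = [], []
        for seed in range(1000):
            grid = generate_grid(spec, seed=seed)
            p, _ = count_points(mask, roi, grid, PX)
            h_i, v_i = count_intersections(mask, roi, grid, PX)
            ps.append(p)
            bs.append(boundary_length(h_i, v_i, spec.pitch_um))
        assert np.mean(ps) * spec.area_per_point_um2 == pytest.approx(math.pi * 40**2, rel=0.02)
        assert np.mean(bs) == pytest.approx(2 * math.pi * 40, rel=0.02)

    def test_rotation_swaps_intersection_roles(self, default_spec):
        """Transposing the scene exchanges hI and vI exactly."""
        scene = disc_scene(120.0, 300.0, 35.0)
        mask = render(scene)
        roi = np.ones_like(mask)
        spec = GridSpec(offset_x_um=3.0, offset_y_um=7.0)
        grid = generate_grid(spec)
        spec_t = GridSpec(
            field_width_um=spec.field_height_um,
            field_height_um=spec.field_width_um,
            offset_x_um=7.0,
            offset_y_um=3.0,
        )
        grid_t = generate_grid(spec_t)
        h_i, v_i = count_intersections(mask, roi, grid, PX)
        h_t, v_t = count_intersections(mask.T, roi.T, grid_t, PX)
        assert (h_t, v_t) == (v_i, h_i)
        assert boundary_length(h_i, v_i) == boundary_length(v_i, h_i)


class TestCountingFrame:
    def frame(self):
        return CountingFrame(0.0, 0.0, 318.0, 429.0)

    def test_no_profiles(self):
        lab = np.zeros((1301, 964), dtype=np.uint16)
        assert count_profiles(lab, self.frame(), PX) == 0

    def test_profile_inside_counted_once(self):
        lab = render_labels(disc_scene(150.0, 200.0, 20.0))
        assert count_profiles(lab, self.frame(), PX) == 1

    def test_profile_on_forbidden_edges_excluded(self):
        # touching the left edge (x ~ 0)
        left = render_labels(disc_scene(10.0, 200.0, 15.0))
        assert left[:, 0].any()
        assert count_profiles(left, self.frame(), PX) == 0
        # touching the bottom edge (y ~ height)
        bottom = render_labels(disc_scene(150.0, 422.0, 15.0))
        assert count_profiles(bottom, self.frame(), PX) == 0

    def test_non_integer_labels_rejected(self):
        with pytest.raises(ValueError, match="integer"):
            count_profiles(np.zeros((10, 10)), self.frame(), PX)

    def test_edge_losses_match_uniform_placement_expectation(self):
        """Uniformly placed discs: E[N] = n(1 - r/W)(1 - r/H) over many scenes."""
        n, r, side = 60, 5.0, 200.0
        frame = CountingFrame(0.0, 0.0, side, side)
        rng = np.random.default_rng(99)
        counts = []
        for _ in range(500):
            profiles = tuple(
                Ellipse(rng.uniform(0, side), rng.uniform(0, side), r, r)
                for _ in range(n)
            )
            scene = VesselScene(profiles, width_um=side, height_um=side)
            counts.append(count_profiles(render_labels(scene), frame, PX))
        expected = n * (1 - r / side) ** 2
        assert np.mean(counts) == pytest.approx(expected, rel=0.03)


class TestFormulas:
    def test_boundary_length_values(self):
        assert boundary_length(0, 0, 12.25) == 0.0
        assert boundary_length(10, 10, 12.25) == pytest.approx(0.5 * math.pi * 10 * 12.25)
        assert boundary_length(10, 10, 12.25) == pytest.approx(192.42, abs=0.01)

    def test_boundary_length_rejects_negative_counts(self):
        with pytest.raises(ValueError):
            boundary_length(-1, 0, 12.25)

    @pytest.mark.parametrize("p,expected", [(0, 0.0), (1, 150.0625), (4, 600.25)])
    def test_point_count_area(self, p, expected):
        assert point_count_area(p, 12.25) == pytest.approx(expected)

    def test_area_per_point_matches_nominal(self):
        assert GridSpec().area_per_point_um2 == pytest.approx(150.0, rel=0.001)


class TestCavityRule:
    def test_no_cavity_keeps_roi(self):
        roi = np.ones((100, 100), dtype=bool)
        eff, frac, missing = apply_cavity_rule(roi, np.zeros_like(roi))
        assert frac == 0.0 and not missing
        np.testing.assert_array_equal(eff, roi)

    def test_full_cavity_flags_missing(self):
        roi = np.ones((100, 100), dtype=bool)
        eff, frac, missing = apply_cavity_rule(roi, roi)
        assert frac == 1.0 and missing
        assert not eff.any()

    def test_half_cavity_halves_roi(self):
        roi = np.ones((100, 100), dtype=bool)
        cavity = np.zeros_like(roi)
        cavity[:50] = True
        eff, frac, missing = apply_cavity_rule(roi, cavity)
        assert frac == 0.5 and not missing
        assert eff.sum() == roi.sum() // 2

    def test_threshold_configurable(self):
        roi = np.ones((100, 100), dtype=bool)
        cavity = np.zeros_like(roi)
        cavity[:80] = True
        assert apply_cavity_rule(roi, cavity, threshold=0.75)[2]
        assert not apply_cavity_rule(roi, cavity, threshold=0.95)[2]


class TestNormalize:
    def counts(self, **kw):
        base = dict(points_on_vessel=20, intersections_h=10, intersections_v=12,
                    profile_count=50, roi_area_mm2=0.1, cavity_fraction=0.0)
        base.update(kw)
        return FieldCounts(**base)

    def test_density_normalisation(self):
        est = normalize_field(self.counts())
        assert est.vessel_density_per_mm2 == pytest.approx(500.0)

    def test_homogeneity_and_sv_invariance(self):
        e1 = normalize_field(self.counts(roi_area_mm2=0.1))
        e2 = normalize_field(self.counts(roi_area_mm2=0.2))
        assert e2.vessel_density_per_mm2 == pytest.approx(e1.vessel_density_per_mm2 / 2)
        assert e2.surface_density_um_per_mm2 == pytest.approx(e1.surface_density_um_per_mm2 / 2)
        assert e2.areal_density_um2_per_mm2 == pytest.approx(e1.areal_density_um2_per_mm2 / 2)
        assert e2.surface_to_volume_per_um == pytest.approx(e1.surface_to_volume_per_um)

    def test_sv_is_surface_over_areal(self):
        est = normalize_field(self.counts())
        assert est.surface_to_volume_per_um == pytest.approx(
            est.surface_density_um_per_mm2 / est.areal_density_um2_per_mm2
        )

    def test_cavity_field_yields_absent_values(self):
        est = normalize_field(self.counts(cavity_fraction=1.0, roi_area_mm2=0.0))
        assert est.missing
        assert math.isnan(est.vessel_density_per_mm2)

    def test_zero_area_without_cavity_is_an_error(self):
        with pytest.raises(ValueError, match="segmentation"):
            normalize_field(self.counts(roi_area_mm2=0.0))


class TestQuantifyField:
    def test_deterministic_counts(self, disc40, default_spec):
        _, mask, roi = disc40
        lab = mask.astype(np.uint16)
        runs = [
            quantify_field(mask, lab, roi, None, default_spec, seed=123)
            for _ in range(2)
        ]
        assert runs[0][1] == runs[1][1]
        assert runs[0][2] == runs[1][2]

    def test_sham_grey_density_recovered(self):
        """Mean recovered VG density over 100 sham fields within 5% of 571."""
        from microstereo import EffectModel, sample_profiles

        model = EffectModel()
        spec = GridSpec()
        densities = []
        for seed in range(100):
            scene = sample_profiles(model, "sham", "T10", "VG", seed=seed)
            mask = render(scene)
            lab = render_labels(scene)
            roi = np.ones_like(mask)
            _, _, est = quantify_field(mask, lab, roi, None, spec, seed=seed + 10_000)
            densities.append(est.vessel_density_per_mm2)
        assert np.mean(densities) == pytest.approx(571.0, rel=0.05)
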