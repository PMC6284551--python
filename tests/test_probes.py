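"""Point grids, cycloid arcs, meander fields and orthogonal intercepts."""

import numpy as np
import pytest

from stereoplacenta import (
    GridSpec,
    LABELS,
    SectionImage,
    make_shell_phantom,
    make_sphere_phantom,
    meander_fields,
    orthogonal_intercepts,
    overlay_cycloid_grid,
    overlay_point_grid,
    section_phantom,
    surface_area,
)
from stereoplacenta.probes import Field, point_in_field


def _section(labels, pixel_size=1.0, vertical=(0.0, 1.0)):
    return SectionImage(labels=labels.astype(np.uint8), pixel_size=pixel_size,
                        index=0, plane_position=0.0, thickness=7.0,
                        vertical_axis=vertical)


class TestPointGrid:
    def test_uniform_label_all_points_on_it(self, rng):
        sec = _section(np.full((50, 50), LABELS["tissue"]))
        counts = overlay_point_grid(sec, GridSpec("point", 5.0), rng)
        assert counts.get("tissue", 0) > 0
        assert counts.get("background", 0) == 0

    def test_empty_image_counts_background_only(self, rng):
        sec = _section(np.zeros((30, 30)))
        counts = overlay_point_grid(sec, GridSpec("point", 5.0), rng)
        assert counts.get("tissue", 0) == 0

    def test_half_plane_fraction_half_on_average(self):
        img = np.zeros((64, 64))
        img[:, :32] = LABELS["tissue"]
        sec = _section(img)
        rng = np.random.default_rng(0)
        fracs = []
        for _ in range(2000):
            c = overlay_point_grid(sec, GridSpec("point", 7.0), rng)
            tot = c.get("tissue", 0) + c.get("background", 0)
            fracs.append(c.get("tissue", 0) / tot)
        assert np.mean(fracs) == pytest.approx(0.5, abs=0.01)

    def test_spacing_below_pixel_warns(self, rng):
        sec = _section(np.zeros((10, 10)), pixel_size=2.0)
        with pytest.warns(UserWarning, match="pixel"):
            overlay_point_grid(sec, GridSpec("point", 1.0), rng)

    def test_reproducible_given_seed(self):
        img = (np.random.default_rng(1).random((40, 40)) > 0.5) * LABELS["tissue"]
        sec = _section(img)
        c1 = overlay_point_grid(sec, GridSpec("point", 3.0), 77)
        c2 = overlay_point_grid(sec, GridSpec("point", 3.0), 77)
        assert c1 == c2

    def test_point_count_scales_with_mask_area(self):
        # E[P] * a_p estimates mask area for an arbitrary blob
        rng = np.random.default_rng(5)
        from scipy.ndimage import gaussian_filter
        img = (gaussian_filter(rng.random((80, 80)), 6) > 0.5) * LABELS["tissue"]
        sec = _section(img)
        area_true = float((img > 0).sum())
        grid = GridSpec("point", 6.0)
        est = np.mean([
            overlay_point_grid(sec, grid, rng).get("tissue", 0) * grid.a_p
            for _ in range(1500)])
        assert est == pytest.approx(area_true, rel=0.03)


class TestCycloidGrid:
    def test_absent_boundary_zero_crossings(self, rng):
        sec = _section(np.zeros((40, 40)))
        cc = overlay_cycloid_grid(sec, GridSpec("cycloid", 10.0),
                                  structure="tissue", reference=None, rng=rng)
        assert cc.sum_I == 0
        assert cc.sum_P_ref > 0

    def test_missing_vertical_axis_rejected(self, rng):
        sec = SectionImage(labels=np.zeros((10, 10), dtype=np.uint8),
                           pixel_size=1.0, index=0, plane_position=0.0,
                           thickness=7.0, vertical_axis=None)
        with pytest.raises(ValueError, match="vertical"):
            overlay_cycloid_grid(sec, GridSpec("cycloid", 5.0),
                                 structure="tissue", reference=None, rng=rng)

    def test_doubling_density_doubles_counts_ratio_invariant(self):
        ph, _ = make_sphere_phantom(150.0)
        sec_arr = ph.rasterize_section(0.0, 2.0)
        sec = _section(sec_arr, pixel_size=2.0)
        rng = np.random.default_rng(0)
        coarse = GridSpec("cycloid", 40.0)
        dense = GridSpec("cycloid", 20.0)
        cI, cP, dI, dP = 0, 0, 0, 0
        for _ in range(150):
            a = overlay_cycloid_grid(sec, coarse, "tissue", None, rng)
            b = overlay_cycloid_grid(sec, dense, "tissue", None, rng)
            cI += a.sum_I; cP += a.sum_P_ref
            dI += b.sum_I; dP += b.sum_P_ref
        # four tiles of the dense grid per coarse tile -> 4x points, and
        # twice the arc length per unit area -> 2x crossings
        assert dP == pytest.approx(4 * cP, rel=0.02)
        assert dI == pytest.approx(2 * cI, rel=0.05)
        # the downstream ratio Sv = 2 I / (l_p P) is invariant
        sv_c = 2 * cI / (coarse.l_p * cP)
        sv_d = 2 * dI / (dense.l_p * dP)
        assert sv_d == pytest.approx(sv_c, rel=0.05)

    def test_rotation_with_metadata_leaves_estimate_unchanged(self):
        # rotating the raster together with its vertical-axis metadata must
        # not move the surface-density estimate
        ph, _ = make_sphere_phantom(150.0)
        arr = ph.rasterize_section(40.0, 2.0)
        sec_up = _section(arr, pixel_size=2.0, vertical=(0.0, 1.0))
        sec_rot = _section(np.rot90(arr).copy(), pixel_size=2.0,
                           vertical=(1.0, 0.0))
        rng1 = np.random.default_rng(0)
        rng2 = np.random.default_rng(0)
        grid = GridSpec("cycloid", 20.0)
        sv = []
        for sec, rng in ((sec_up, rng1), (sec_rot, rng2)):
            sI = sP = 0
            for _ in range(200):
                cc = overlay_cycloid_grid(sec, grid, "tissue", None, rng)
                sI += cc.sum_I
                sP += cc.sum_P_ref
            sv.append(2 * sI / (grid.l_p * sP))
        assert sv[1] == pytest.approx(sv[0], rel=0.05)

    def test_straight_vertical_boundary_crossing_rate(self):
        # a straight vertical boundary of length L probed by sine-weighted
        # arcs: E[I] = L_A * L * E[|sin(theta)|] with tangent-angle density
        # f(theta) = sin(theta) (theta from vertical), so E[|sin|] = pi/4,
        # and arc-length intensity L_A = l_p / tile area = 1 / (pi a)
        img = np.zeros((64, 64))
        img[:, :32] = LABELS["tissue"]
        sec = _section(img)
        rng = np.random.default_rng(1)
        grid = GridSpec("cycloid", 16.0)
        n_rep = 400
        tot_I = 0
        for _ in range(n_rep):
            tot_I += overlay_cycloid_grid(sec, grid, "tissue", None,
                                          rng).sum_I
        a = grid.cycloid_a
        expected = (1.0 / (np.pi * a)) * (np.pi / 4.0) * 64.0
        assert tot_I / n_rep == pytest.approx(expected, rel=0.1)


class TestMeanderFields:
    def test_full_image_single_field(self, rng):
        sec = _section(np.zeros((20, 20)))
        fields = meander_fields(sec, 50.0, rng)
        assert len(fields) == 1
        assert fields[0].width == 20.0

    def test_zero_offset_tiling_serpentine(self, rng):
        sec = _section(np.zeros((100, 100)))
        fields = meander_fields(sec, 25.0, rng, offset=(0.0, 0.0))
        assert len(fields) == 16
        xs = [f.x0 for f in fields]
        assert xs[:4] == [0.0, 25.0, 50.0, 75.0]
        assert xs[4:8] == [75.0, 50.0, 25.0, 0.0]  # serpentine return

    def test_fields_cover_zone(self):
        ph, _ = make_sphere_phantom(100.0)
        arr = ph.rasterize_section(0.0, 2.0)
        sec = _section(arr, pixel_size=2.0)
        fields = meander_fields(sec, 40.0, np.random.default_rng(0),
                                zone="tissue")
        # every tissue pixel lies within one field-width of a kept field
        rows, cols = np.nonzero(arr)
        xs, ys = (cols + 0.5) * 2.0, (rows + 0.5) * 2.0
        covered = np.zeros(len(xs), dtype=bool)
        for f in fields:
            covered |= ((xs >= f.x0 - 40.0) & (xs < f.x0 + 2 * 40.0)
                        & (ys >= f.y0 - 40.0) & (ys < f.y0 + 2 * 40.0))
        assert covered.all()

    def test_absent_zone_warns_empty(self, rng):
        sec = _section(np.zeros((30, 30)))
        with pytest.warns(UserWarning, match="absent"):
            fields = meander_fields(sec, 10.0, rng, zone="capillary")
        assert fields == []

    def test_counting_frame_rule_is_half_open(self):
        f = Field(0.0, 0.0, 10.0, 10.0)
        assert point_in_field(0.0, 0.0, f)
        assert not point_in_field(10.0, 5.0, f)
        assert not point_in_field(5.0, 10.0, f)


class TestOrthogonalIntercepts:
    def test_equatorial_shell_section_constant_thickness(self):
        ph, _ = make_shell_phantom(80.0, 5.0)
        arr = ph.rasterize_section(0.0, 0.5)
        sec = _section(arr, pixel_size=0.5)
        lengths = orthogonal_intercepts(sec, line_spacing=8.0,
                                        rng=np.random.default_rng(0))
        assert len(lengths) > 10
        assert np.all(np.abs(lengths - 5.0) < 1.0)  # within ~one pixel pair

    def test_no_capillary_empty_sample_with_warning(self, rng):
        sec = _section(np.zeros((30, 30)))
        with pytest.warns(UserWarning, match="capillary"):
            lengths = orthogonal_intercepts(sec, rng=rng)
        assert lengths.size == 0

    def test_oblique_sections_have_tail_above_true_thickness(self):
        ph, _ = make_shell_phantom(80.0, 5.0)
        all_lengths = []
        for seed in range(4):
            stack = section_phantom(ph, t_sec=4.0, n_select=20,
                                    rng=np.random.default_rng(seed),
                                    pixel_size=0.5)
            for sec in stack:
                all_lengths.extend(
                    orthogonal_intercepts(sec, line_spacing=10.0,
                                          rng=np.random.default_rng(seed)))
        arr = np.array(all_lengths)
        assert arr.min() > 5.0 - 1.0
        assert (arr > 6.0).mean() > 0.1  # obliquity tail present
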