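"""Opacity law, outlines, compositing, colorbar, and panel rendering."""

import numpy as np
import pytest

from lucidmap import (AlphaSpec, RenderSpec, ThresholdSpec, colorbar_rgb,
                      composite_slice, compute_alpha, default_affine,
                      extract_clusters, make_quartet, outline_boundary,
                      render_adjustment_pair, render_panel)
from lucidmap.rendering import to_uint8
from lucidmap.volumes import GridAlignmentError, StatVolume, Volume3D

from conftest import make_stat


class TestComputeAlpha:
    def test_threshold_boundary_fully_opaque(self):
        a = compute_alpha(np.array([[[3.0]]]), 3.0, AlphaSpec())
        assert a.flat[0] == 1.0

    def test_zero_statistic_fades_to_floor(self):
        for floor in (0.0, 0.2):
            spec = AlphaSpec(floor=floor)
            a = compute_alpha(np.array([[[0.0]]]), 3.0, spec)
            assert a.flat[0] == pytest.approx(floor)

    def test_quadratic_law_at_half_threshold(self):
        a = compute_alpha(np.array([[[1.5]]]), 3.0, AlphaSpec())
        assert a.flat[0] == pytest.approx(0.25)

    def test_opaque_mode_is_binary(self):
        vals = np.array([0.0, 2.9, 3.0, 5.0]).reshape(4, 1, 1)
        a = compute_alpha(vals, 3.0, AlphaSpec(mode="opaque"))
        np.testing.assert_array_equal(a.ravel(), [0, 0, 1, 1])

    def test_monotone_in_magnitude_and_bounded(self):
        vals = np.linspace(-6, 6, 101).reshape(101, 1, 1)
        for spec in (AlphaSpec(), AlphaSpec(exponent=1.5, floor=0.1),
                     AlphaSpec(mode="opaque")):
            a = compute_alpha(vals, 3.0, spec).ravel()
            assert np.all((a >= 0) & (a <= 1))
            mags = np.abs(vals.ravel())
            order = np.argsort(mags)
            assert np.all(np.diff(a[order]) >= -1e-12)

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            compute_alpha(np.zeros((2, 2, 2)), 0.0, AlphaSpec())


class TestOutlineBoundary:
    def test_single_pixel_is_its_own_boundary(self):
        m = np.zeros((5, 5), dtype=bool)
        m[2, 2] = True
        np.testing.assert_array_equal(outline_boundary(m), m)

    def test_solid_square_keeps_perimeter(self):
        m = np.zeros((5, 5), dtype=bool)
        m[1:4, 1:4] = True
        b = outline_boundary(m)
        expected = m.copy()
        expected[2, 2] = False  # interior pixel eroded away
        np.testing.assert_array_equal(b, expected)
        assert b.sum() == 8

    def test_empty_in_empty_out(self):
        assert not outline_boundary(np.zeros((4, 4), dtype=bool)).any()

    def test_boundary_is_subset_and_strictly_shrinks(self):
        rng = np.random.default_rng(77)
        for _ in range(30):
            m = rng.uniform(size=(12, 12)) < 0.4
            b = outline_boundary(m)
            assert not (b & ~m).any()
            if m.any():
                assert (m & ~b).sum() < m.sum()


def _quartet_scene(theta=3.0, seed=0):
    maps = make_quartet(theta, seed=seed)
    under = maps[0].vol.like(np.zeros(maps[0].vol.shape))
    tspec = ThresholdSpec(stat_threshold=theta)
    return maps, under, tspec


class TestCompositeSlice:
    def test_zero_alpha_reproduces_underlay(self):
        maps, under, tspec = _quartet_scene()
        rng = np.random.default_rng(1)
        under = under.like(rng.uniform(size=under.shape))
        rspec = RenderSpec(color_range=5.0)
        alpha = np.zeros(under.shape)
        img = composite_slice(under, maps[0].vol, alpha, None, rspec,
                              "axial", 0.0)
        from lucidmap.rendering import _gray_underlay, orient_slice, slice_index_for_mm
        idx = slice_index_for_mm(under, "axial", 0.0)
        gray = orient_slice(_gray_underlay(under, rspec.underlay_range),
                            "axial", idx)
        np.testing.assert_allclose(img, np.repeat(gray[..., None], 3, -1),
                                   atol=1e-12)

    def test_full_alpha_pixel_equals_colormap_color(self):
        maps, under, _ = _quartet_scene()
        rspec = RenderSpec(color_range=5.0, outline=False)
        alpha = np.ones(under.shape)
        img = composite_slice(under, maps[0].vol, alpha, None, rspec,
                              "axial", 0.0)
        from lucidmap.rendering import (_overlay_rgb, orient_slice,
                                        slice_index_for_mm)
        idx = slice_index_for_mm(under, "axial", 0.0)
        over2d = orient_slice(maps[0].vol.data, "axial", idx)
        np.testing.assert_allclose(img, _overlay_rgb(over2d, "RdBu_r", 5.0),
                                   atol=1e-12)

    def test_output_is_convex_combination(self):
        maps, under, tspec = _quartet_scene()
        rng = np.random.default_rng(2)
        under = under.like(rng.uniform(size=under.shape))
        rspec = RenderSpec(color_range=5.0, outline=False)
        alpha = compute_alpha(maps[0].data, 3.0, AlphaSpec())
        img = composite_slice(under, maps[0].vol, alpha, None, rspec,
                              "axial", 0.0)
        from lucidmap.rendering import (_gray_underlay, _overlay_rgb,
                                        orient_slice, slice_index_for_mm)
        idx = slice_index_for_mm(under, "axial", 0.0)
        gray = orient_slice(_gray_underlay(under, rspec.underlay_range),
                            "axial", idx)[..., None]
        over = _overlay_rgb(orient_slice(maps[0].vol.data, "axial", idx),
                            "RdBu_r", 5.0)
        lo = np.minimum(gray.repeat(3, -1), over) - 1e-12
        hi = np.maximum(gray.repeat(3, -1), over) + 1e-12
        assert np.all((img >= lo) & (img <= hi))

    def test_left_convention_flips_horizontally_only(self):
        maps, under, tspec = _quartet_scene()
        clusters = extract_clusters(maps[0], tspec)
        alpha = compute_alpha(maps[0].data, 3.0, AlphaSpec())
        neuro = composite_slice(under, maps[0].vol, alpha, clusters,
                                RenderSpec(color_range=5.0), "axial", 0.0)
        radio = composite_slice(under, maps[0].vol, alpha, clusters,
                                RenderSpec(color_range=5.0,
                                           left_convention="radiological"),
                                "axial", 0.0)
        np.testing.assert_array_equal(radio, neuro[:, ::-1])

    def test_misaligned_inputs_rejected(self):
        maps, under, _ = _quartet_scene()
        other = Volume3D(np.zeros((8, 8, 8)), default_affine((8, 8, 8)))
        with pytest.raises(GridAlignmentError):
            composite_slice(other, maps[0].vol, np.zeros((8, 8, 8)), None,
                            RenderSpec(), "axial", 0.0)

    def test_out_of_bounds_slice_rejected(self):
        maps, under, _ = _quartet_scene()
        with pytest.raises(ValueError, match="out of bounds"):
            composite_slice(under, maps[0].vol, np.zeros(under.shape), None,
                            RenderSpec(), "axial", 500.0)


class TestQuartetDegeneracy:
    def test_opaque_renders_byte_identical(self):
        """Strict thresholding collapses the four stories into one image."""
        maps, under, tspec = _quartet_scene()
        rspec = RenderSpec(color_range=5.0)
        imgs = []
        for m in maps:
            clusters = extract_clusters(m, tspec)
            alpha = compute_alpha(m.data, 3.0, AlphaSpec(mode="opaque"))
            imgs.append(to_uint8(composite_slice(under, m.vol, alpha,
                                                 clusters, rspec,
                                                 "axial", 0.0)))
        for img in imgs[1:]:
            np.testing.assert_array_equal(img, imgs[0])

    def test_transparent_renders_pairwise_distinct(self):
        maps, under, tspec = _quartet_scene()
        rspec = RenderSpec(color_range=5.0)
        imgs = []
        for m in maps:
            clusters = extract_clusters(m, tspec)
            alpha = compute_alpha(m.data, 3.0, AlphaSpec())
            imgs.append(to_uint8(composite_slice(under, m.vol, alpha,
                                                 clusters, rspec,
                                                 "axial", 0.0)))
        for i in range(4):
            for j in range(i + 1, 4):
                assert (imgs[i] != imgs[j]).any()


class TestColorbar:
    def test_fade_matches_alpha_law(self):
        """Recover alpha from blended rows; must equal compute_alpha."""
        aspec = AlphaSpec(floor=0.1)
        rspec = RenderSpec()
        theta, vmax, bg = 3.0, 6.0, 0.5
        values, strip = colorbar_rgb(vmax, theta, aspec, rspec, bg_gray=bg)
        from lucidmap.rendering import _overlay_rgb
        pure = _overlay_rgb(values[:, None], rspec.colormap, vmax)[:, 0, :]
        expected_alpha = compute_alpha(values, theta, aspec)
        denom = pure - bg
        usable = np.abs(denom).max(axis=1) > 0.05
        recovered = np.full(len(values), np.nan)
        for i in np.where(usable)[0]:
            ch = np.argmax(np.abs(denom[i]))
            recovered[i] = (strip[i, 0, ch] - bg) / denom[i, ch]
        np.testing.assert_allclose(recovered[usable], expected_alpha[usable],
                                   atol=1e-9)

    def test_threshold_row_opaque_and_zero_row_at_floor(self):
        aspec = AlphaSpec(floor=0.25)
        values, strip = colorbar_rgb(6.0, 3.0, aspec, RenderSpec(),
                                     height=241, bg_gray=0.5)
        row_theta = int(np.argmin(np.abs(values - 3.0)))
        row_zero = int(np.argmin(np.abs(values)))
        from lucidmap.rendering import _overlay_rgb
        pure = _overlay_rgb(values[:, None], "RdBu_r", 6.0)[:, 0, :]
        np.testing.assert_allclose(strip[row_theta, 0], pure[row_theta],
                                   atol=1e-9)
        expected = 0.25 * pure[row_zero] + 0.75 * 0.5
        np.testing.assert_allclose(strip[row_zero, 0], expected, atol=1e-9)


class TestRenderPanel:
    def test_writes_montage_and_colorbar(self, tmp_path):
        maps, under, tspec = _quartet_scene()
        paths = render_panel(maps[0], None, under, tspec, AlphaSpec(),
                             RenderSpec(color_range=5.0),
                             tmp_path / "panel")
        assert paths["montage"].exists() and paths["colorbar"].exists()

    def test_opaque_and_transparent_differ_with_subthreshold_signal(self, tmp_path):
        maps, under, tspec = _quartet_scene()
        p1 = render_panel(maps[0], None, under, tspec, AlphaSpec(),
                          RenderSpec(color_range=5.0), tmp_path / "tr")
        p2 = render_panel(maps[0], None, under, tspec,
                          AlphaSpec(mode="opaque"),
                          RenderSpec(color_range=5.0), tmp_path / "op")
        assert p1["montage"].read_bytes() != p2["montage"].read_bytes()

    def test_rendering_is_deterministic(self, tmp_path):
        maps, under, tspec = _quartet_scene()
        p1 = render_panel(maps[0], None, under, tspec, AlphaSpec(),
                          RenderSpec(color_range=5.0), tmp_path / "a")
        p2 = render_panel(maps[0], None, under, tspec, AlphaSpec(),
                          RenderSpec(color_range=5.0), tmp_path / "b")
        assert p1["montage"].read_bytes() == p2["montage"].read_bytes()

    def test_before_after_pair_has_two_montages(self, tmp_path):
        maps, under, _ = _quartet_scene()
        pre = ThresholdSpec(stat_threshold=3.0)
        post = ThresholdSpec(stat_threshold=3.0, min_cluster_size=10)
        montages = render_adjustment_pair(maps[0], None, under, pre, post,
                                          AlphaSpec(), RenderSpec(color_range=5.0),
                                          tmp_path / "pair")
        assert len(montages) == 2
        assert all(p.exists() for p in montages)

    def test_effect_overlay_requires_effect_volume(self, tmp_path):
        maps, under, tspec = _quartet_scene()
        with pytest.raises(ValueError, match="effect"):
            render_panel(maps[0], None, under, tspec, AlphaSpec(),
                         RenderSpec(overlay_source="effect"), tmp_path / "x")
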