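import numpy as np
import pytest

from ishquant.profile_extraction import (
    BoundaryMorphology,
    EditMask,
    GeometryError,
    ProfileRejected,
    RawProfile,
    edit_profile,
    extract_profile,
    segment_cell_layer,
    segment_mean_intensity,
    standardize_profile,
)
from ishquant.synthetic_data import ArchetypeSpec, ShapeParams, generate_embryo_image

from _oracles import pixels_in_quad, rasterized_band_area


def half_annulus(r_in=10.0, r_out=20.0, n=5, center=(32.3171, 31.6483)):
    # generic center: no pixel center falls exactly on a segment edge
    theta = np.linspace(-np.pi / 2, np.pi / 2, n)
    unit = np.column_stack([np.cos(theta), np.sin(theta)])
    return BoundaryMorphology(
        inner=np.asarray(center) + r_in * unit,
        outer=np.asarray(center) + r_out * unit,
    )


def shoelace(poly):
    x, y = poly[:, 0], poly[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


class TestSegmentCellLayer:
    def test_concentric_circles_positions_and_areas(self):
        """Four equal segments of a concentric half-annulus sit at midline
        positions 1/8, 3/8, 5/8, 7/8."""
        segments = segment_cell_layer(half_annulus())
        assert len(segments) == 4
        np.testing.assert_allclose(
            [pos for _, pos in segments], [0.125, 0.375, 0.625, 0.875], atol=1e-12
        )
        for quad, _ in segments:
            assert shoelace(quad) > 0

    def test_three_pairs_two_quads(self):
        segments = segment_cell_layer(half_annulus(n=3), n_segments=2)
        assert len(segments) == 2

    def test_resampling_to_requested_segment_count(self):
        segments = segment_cell_layer(half_annulus(n=5), n_segments=16)
        assert len(segments) == 16
        positions = np.array([p for _, p in segments])
        assert (np.diff(positions) > 0).all()

    def test_quad_areas_match_rasterized_band_area(self):
        """Sum of quad areas equals the area between the polylines, measured
        by brute-force fine-grid rasterization."""
        morph = half_annulus(r_in=8.0, r_out=15.0, n=17)
        segments = segment_cell_layer(morph)
        total = sum(shoelace(q) for q, _ in segments)
        oracle = rasterized_band_area(morph.inner, morph.outer, step=0.2)
        assert abs(total - oracle) / oracle < 0.02

    def test_degenerate_quad_names_segment(self):
        inner = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
        outer = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 1.0]])  # quad 0 collapsed
        with pytest.raises(GeometryError, match="segment 0"):
            segment_cell_layer(BoundaryMorphology(inner, outer))

    def test_orientation_flag_reverses_positions(self):
        m = half_annulus()
        flipped = BoundaryMorphology(m.inner[::-1], m.outer[::-1], oral_pole="end")
        pos_a = [p for _, p in segment_cell_layer(m)]
        pos_b = [p for _, p in segment_cell_layer(flipped)]
        np.testing.assert_allclose(pos_a, pos_b, atol=1e-12)


class TestSegmentMeanIntensity:
    def test_uniform_image_gives_constant_profile(self):
        image = np.full((64, 64), 0.5)
        raw = segment_mean_intensity(image, segment_cell_layer(half_annulus()))
        np.testing.assert_allclose(raw.intensities, 0.5)
        assert (raw.pixel_counts >= 1).all()

    def test_step_image_means_match_pixel_enumeration(self):
        """Per-segment means agree exactly with an independent shapely
        enumeration of in-quad pixel centers."""
        rng = np.random.default_rng(7)
        image = rng.random((64, 64))
        segments = segment_cell_layer(half_annulus(n=9))
        raw = segment_mean_intensity(image, segments)
        assert len(raw.positions) == len(segments)
        for (quad, _), mean in zip(segments, raw.intensities):
            pix = pixels_in_quad(quad, image.shape)
            expected = np.mean([image[y, x] for y, x in pix])
            assert mean == pytest.approx(expected, abs=1e-12)

    def test_subpixel_segment_dropped_with_warning(self):
        image = np.ones((64, 64))
        # 80 segments over a 3-px-thick sliver: some wedges contain no center
        morph = half_annulus(r_in=10.0, r_out=10.8, n=81)
        with pytest.warns(UserWarning, match="dropped"):
            raw = segment_mean_intensity(image, segment_cell_layer(morph))
        assert (np.diff(raw.positions) > 0).all()

    def test_disjoint_image_errors(self):
        with pytest.raises(ValueError, match="empty"):
            segment_mean_intensity(
                np.ones((5, 5)), segment_cell_layer(half_annulus(center=(500, 500)))
            )


class TestEditProfile:
    def test_empty_mask_is_identity(self):
        raw = RawProfile([0.1, 0.5, 0.9], [1.0, 2.0, 3.0], [4, 4, 4])
        out = edit_profile(raw, EditMask([]))
        np.testing.assert_array_equal(out.intensities, raw.intensities)

    def test_interior_spike_interpolated_away(self):
        raw = RawProfile(
            [0.1, 0.3, 0.5, 0.7, 0.9], [1.0, 1.0, 9.0, 1.0, 1.0], [1] * 5
        )
        out = edit_profile(raw, EditMask([(0.45, 0.55)]))
        np.testing.assert_allclose(out.intensities, 1.0)

    def test_masked_end_takes_nearest_value(self):
        raw = RawProfile([0.1, 0.5, 0.9], [7.0, 2.0, 3.0], [1, 1, 1])
        out = edit_profile(raw, EditMask([(0.0, 0.2)]))
        np.testing.assert_allclose(out.intensities, [2.0, 2.0, 3.0])

    def test_full_mask_rejected(self):
        raw = RawProfile([0.1, 0.9], [1.0, 2.0], [1, 1])
        with pytest.raises(ValueError, match="whole profile"):
            edit_profile(raw, EditMask([(0.0, 1.0)]))

    def test_masking_recorded_artifact_recovers_clean_extraction(self):
        """Editing out the recorded artifact interval reproduces the
        artifact-free twin scene's profile."""
        arch = ArchetypeSpec([("Cd", 0.0, 0.3)])
        shape = ShapeParams()
        clean = generate_embryo_image(shape, arch, seed=3)
        dirty = generate_embryo_image(
            shape, arch, seed=3, artifact_spec=[(0.75, 0.04, 2.0)]
        )
        (interval,) = dirty.artifact_regions
        # pad by one segment width: segments straddling the interval edge
        # pick up artifact pixels although their midpoint lies just outside
        pad = 1.0 / 256
        with pytest.warns(UserWarning):
            p_clean = extract_profile(clean.image, clean.true_morphology)
            p_fixed = extract_profile(
                dirty.image,
                dirty.true_morphology,
                edit_mask=EditMask([(interval[0] - pad, interval[1] + pad)]),
            )
        # artifact sits on flat background, so interpolation is exact
        np.testing.assert_allclose(p_fixed.values, p_clean.values, atol=1e-6)


class TestStandardizeProfile:
    def test_output_is_always_100_points(self):
        raw = RawProfile([0.2, 0.8], [1.0, 2.0], [1, 1])
        prof = standardize_profile(raw)
        assert prof.values.shape == (100,)
        assert prof.values.max() == pytest.approx(1.0, abs=1e-12)

    def test_constant_profile_scales_to_ones(self):
        raw = RawProfile([0.1, 0.5, 0.9], [0.37, 0.37, 0.37], [1, 1, 1])
        np.testing.assert_allclose(standardize_profile(raw).values, 1.0)

    def test_irregular_ramp_matches_closed_form(self):
        positions = np.array([0.0, 0.07, 0.2, 0.33, 0.5, 0.81, 1.0])
        raw = RawProfile(positions, 2.0 * positions + 1.0, np.ones(7, int))
        grid = np.linspace(0, 1, 100)
        np.testing.assert_allclose(
            standardize_profile(raw).values, (2.0 * grid + 1.0) / 3.0, atol=1e-12
        )

    def test_all_zero_profile_rejected(self):
        raw = RawProfile([0.1, 0.9], [0.0, 0.0], [1, 1])
        with pytest.raises(ProfileRejected):
            standardize_profile(raw)


class TestRoundTrip:
    @pytest.mark.parametrize(
        "shape",
        [
            ShapeParams(),
            ShapeParams(invagination_depth=10.0, aspect=1.15),
        ],
        ids=["blastula-like", "gastrula-like"],
    )
    def test_noise_free_extraction_recovers_truth(self, shape):
        """Standardized extracted profile deviates < 0.05 from the generating
        truth on noise-free scenes."""
        arch = ArchetypeSpec([("Cd", 0.0, 0.3), ("Er", 0.5, 0.7)], amplitudes=[1.0, 0.6])
        scene = generate_embryo_image(shape, arch, noise_sd=0.0, seed=1)
        with pytest.warns(UserWarning):
            extracted = extract_profile(scene.image, scene.true_morphology)
        truth = scene.true_standardized()
        assert np.abs(extracted.values - truth.values).max() < 0.05

    def test_scale_invariance(self):
        scene = generate_embryo_image(ShapeParams(), ArchetypeSpec([("Cd", 0.0, 0.3)]), seed=2)
        with pytest.warns(UserWarning):
            base = extract_profile(scene.image, scene.true_morphology)
            pow2 = extract_profile(scene.image * 4.0, scene.true_morphology)
            other = extract_profile(scene.image * 3.7, scene.true_morphology)
        np.testing.assert_array_equal(base.values, pow2.values)
        np.testing.assert_allclose(base.values, other.values, atol=1e-12)

    def test_inverted_polarity_round_trips(self):
        """A dark-stain-on-light image quantifies identically via invert."""
        scene = generate_embryo_image(
            ShapeParams(), ArchetypeSpec([("Cd", 0.0, 0.3)]), seed=4, background=0.0
        )
        inverted = scene.image.max() - scene.image
        with pytest.warns(UserWarning):
            direct = extract_profile(scene.image, scene.true_morphology)
            via_flag = extract_profile(inverted, scene.true_morphology, invert=True)
        np.testing.assert_allclose(direct.values, via_flag.values, atol=1e-12)
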