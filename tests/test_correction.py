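"""Flat-field correction, checker sampling and polynomial colour correction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phytochroma import correction as corr
from phytochroma import synthetic as syn
from phytochroma.image import ShapeError, clip_round

triples = st.tuples(*[st.integers(0, 255)] * 3)


# ---------------------------------------------------------------------------
# reference CSV
# ---------------------------------------------------------------------------

class TestReferenceCSV:
    def test_roundtrip_preserves_order(self, tmp_path, reference):
        path = tmp_path / "ref.csv"
        corr.write_reference_swatches(reference, path)
        loaded = corr.load_reference_swatches(path)
        np.testing.assert_allclose(loaded.reference_rgb, reference.reference_rgb)
        assert loaded.order_convention == corr.ORDER_CONVENTION

    def test_wrong_row_count_reported(self, tmp_path):
        path = tmp_path / "short.csv"
        rows = "\n".join(f"{i},{i},{i}" for i in range(23))
        path.write_text("R,G,B\n" + rows + "\n")
        with pytest.raises(corr.FormatError, match="23 rows"):
            corr.load_reference_swatches(path)

    def test_out_of_range_value_names_row(self, tmp_path):
        rows = [f"{i},{i},{i}" for i in range(24)]
        rows[7] = "300,10,10"
        path = tmp_path / "bad.csv"
        path.write_text("R,G,B\n" + "\n".join(rows) + "\n")
        with pytest.raises(ValueError, match="row 7"):
            corr.load_reference_swatches(path)

    def test_duplicate_swatches_rejected(self):
        arr = np.tile(np.arange(3), (24, 1))
        with pytest.raises(ValueError, match="distinct"):
            corr.SwatchSet(arr)


# ---------------------------------------------------------------------------
# background (flat-field) correction
# ---------------------------------------------------------------------------

class TestBackgroundCorrect:
    def test_uniform_background_is_identity(self):
        img = np.full((40, 60, 3), 200, np.uint8)
        assert np.array_equal(corr.background_correct(img, img), img)

    def test_flattens_vignetted_field(self):
        field = syn.vignette_field(120, 180, 0.3)[..., None]
        img = clip_round(np.full((120, 180, 3), 200.0) * field)
        bg = clip_round(np.full((120, 180, 3), 255.0) * field)
        out = corr.background_correct(img, bg).astype(float)
        for c in range(3):
            ch = out[..., c]
            assert ch.std() / ch.mean() < 0.01

    def test_quotient_clipped_at_255(self):
        img = np.full((20, 20, 3), 250, np.uint8)
        bg = np.full((20, 20, 3), 128, np.uint8)  # field ≈ 0.5 ⇒ quotient ≈ 500
        bg[0, 0] = 255  # channel maxima
        out = corr.background_correct(img, bg)
        assert out.max() == 255
        assert out[10, 10].tolist() == [255, 255, 255]

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ShapeError):
            corr.background_correct(
                np.zeros((10, 10, 3), np.uint8), np.zeros((10, 12, 3), np.uint8)
            )

    def test_idempotent_under_uniform_background(self):
        rng = np.random.default_rng(0)
        img = rng.integers(0, 256, (30, 30, 3)).astype(np.uint8)
        bg = np.full((30, 30, 3), 180, np.uint8)
        once = corr.background_correct(img, bg)
        assert np.array_equal(corr.background_correct(once, np.full_like(bg, 255)), once)


# ---------------------------------------------------------------------------
# checker sampling
# ---------------------------------------------------------------------------

class TestSampleChecker:
    def test_clean_scene_sampled_exactly(self, clean_scene, reference):
        img, truth = clean_scene
        grid = corr.sample_checker(img)
        assert np.abs(grid.observed_rgb - truth.swatch_rgb).max() <= 2.0

    @pytest.mark.parametrize("k", [0, 1, 2, 3])
    def test_all_four_orientations_resolved(self, clean_scene, reference, k):
        img, truth = clean_scene
        grid = corr.sample_checker(np.rot90(img, k).copy())
        assert np.abs(grid.observed_rgb - truth.swatch_rgb).max() <= 2.0

    def test_hint_bypasses_detection(self, clean_scene):
        img, truth = clean_scene
        grid = corr.sample_checker(img, hint=truth.card_corners)
        assert np.abs(grid.observed_rgb - truth.swatch_rgb).max() <= 2.0

    def test_all_white_image_raises(self):
        blank = np.full((200, 300, 3), 255, np.uint8)
        with pytest.raises(corr.DetectionError):
            corr.sample_checker(blank)

    def test_rotated_card_advises_cropping(self, clean_scene):
        from scipy import ndimage

        img, _ = clean_scene
        rotated = ndimage.rotate(img, 30, reshape=False, cval=255, order=0)
        with pytest.raises(corr.DetectionError, match="crop"):
            corr.sample_checker(rotated)


# ---------------------------------------------------------------------------
# polynomial regression fit / apply
# ---------------------------------------------------------------------------

def _grid(values):
    return corr.SwatchGrid(values, np.zeros((24, 4, 2)))


class TestFitColourCorrection:
    def test_identity_data_gives_perfect_fit(self, reference):
        model = corr.fit_colour_correction(_grid(reference.reference_rgb), reference)
        np.testing.assert_allclose(model.r2_per_channel, 1.0, atol=1e-12)
        fixed = corr.correct_colours(reference.reference_rgb, model)
        assert np.abs(fixed - reference.reference_rgb).max() < 1.0

    def test_halved_channels_recovered(self, reference):
        observed = reference.reference_rgb / 2.0
        model = corr.fit_colour_correction(_grid(observed), reference)
        fixed = corr.correct_colours(observed, model)
        assert np.abs(fixed - reference.reference_rgb).max() < 1.0

    def test_known_cubic_cast_recovered(self, reference):
        observed = np.clip(syn.apply_cast(reference.reference_rgb, syn.DEFAULT_CAST), 0, 255)
        model = corr.fit_colour_correction(_grid(observed), reference)
        assert model.r2_per_channel.min() > 0.95
        fixed = corr.correct_colours(observed, model)
        assert np.abs(fixed - reference.reference_rgb).max() < 1.0

    def test_rank_deficient_design_raises(self, reference):
        observed = np.tile(np.array([100.0, 100.0, 100.0]), (24, 1))
        observed += np.arange(24)[:, None] * 1e-12  # distinct but collinear
        grid = corr.SwatchGrid(observed, np.zeros((24, 4, 2)))
        with pytest.raises(corr.FitError):
            corr.fit_colour_correction(grid, reference)

    def test_identity_model_leaves_image_unchanged(self, rng):
        img = rng.integers(0, 256, (20, 20, 3)).astype(np.uint8)
        out = corr.apply_colour_correction(img, corr.CorrectionModel.identity())
        assert np.array_equal(out, img)

    def test_zero_model_gives_black(self, rng):
        img = rng.integers(0, 256, (20, 20, 3)).astype(np.uint8)
        model = corr.CorrectionModel(np.zeros((3, 9)), np.zeros(3))
        assert corr.apply_colour_correction(img, model).max() == 0

    def test_fit_then_apply_round_trip_on_image(self, reference):
        observed = reference.reference_rgb / 2.0
        model = corr.fit_colour_correction(_grid(observed), reference)
        halved_img = clip_round(np.tile(observed[:, None, :], (1, 5, 1)))
        fixed = corr.apply_colour_correction(halved_img, model).astype(float)
        target = np.tile(reference.reference_rgb[:, None, :], (1, 5, 1))
        assert np.abs(fixed - target).max() <= 1.5  # 8-bit quantisation of the input


# ---------------------------------------------------------------------------
# ΔRGB metric and diagnostics
# ---------------------------------------------------------------------------

class TestDeltaRGB:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ((0, 0, 0), (0, 0, 0), 0.0),
            ((3, 0, 4), (0, 0, 0), 5.0),
            ((255, 255, 255), (0, 0, 0), 441.673),
        ],
    )
    def test_known_distances(self, a, b, expected):
        assert corr.delta_rgb(a, b) == pytest.approx(expected, abs=5e-4)

    @given(a=triples, b=triples, c=triples)
    @settings(max_examples=200, deadline=None)
    def test_metric_axioms(self, a, b, c):
        dab = corr.delta_rgb(a, b)
        assert dab >= 0
        assert dab == corr.delta_rgb(b, a)
        assert (dab == 0) == (a == b)
        assert dab <= corr.delta_rgb(a, c) + corr.delta_rgb(c, b) + 1e-9
        assert dab <= 255 * np.sqrt(3) + 1e-9


class TestSwatchError:
    def test_zero_for_identical(self, reference):
        assert corr.mean_swatch_error(reference.reference_rgb, reference) == 0.0

    def test_constant_offset_mean(self, reference):
        observed = reference.reference_rgb + np.array([6.0, 8.0, 0.0])  # each ΔRGB = 10
        assert corr.mean_swatch_error(observed, reference) == pytest.approx(10.0)

    def test_correction_reduces_error_on_distorted_scene(self, distorted_scene, reference):
        img, _ = distorted_scene
        grid = corr.sample_checker(img)
        before = corr.mean_swatch_error(grid, reference)
        model = corr.fit_colour_correction(grid, reference)
        after = corr.mean_swatch_error(
            np.clip(corr.correct_colours(grid.observed_rgb, model), 0, 255), reference
        )
        assert after < before

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_ols_never_increases_summed_squared_error(self, seed):
        """The 9-term basis contains the identity map, so the fitted sum of
        squared swatch errors cannot exceed the uncorrected one."""
        ref = corr.default_reference_swatches()
        rng = np.random.default_rng(seed)
        observed = rng.uniform(0, 255, (24, 3))
        model = corr.fit_colour_correction(_grid(observed), ref)
        fixed = corr.correct_colours(observed, model)
        sse_fixed = ((fixed - ref.reference_rgb) ** 2).sum()
        sse_raw = ((observed - ref.reference_rgb) ** 2).sum()
        assert sse_fixed <= sse_raw + 1e-6


class TestWhiteSaturation:
    @pytest.mark.parametrize(
        "triple,expected",
        [
            ((255, 250, 248), True),
            ((250, 250, 250), False),
            ((255, 255, 255), True),
        ],
    )
    def test_flags_channel_at_ceiling(self, triple, expected):
        flagged, logged = corr.check_white_saturation(triple)
        assert flagged is expected
        assert logged == tuple(float(v) for v in triple)
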