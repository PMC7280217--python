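"""Stimulus factory: Michelson rescaling, triangle geometry, symmetry."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import spearmanr

from apostim import (
    RDParams,
    StimulusSpec,
    generate_category,
    make_stimulus,
    measure_contrast,
    mirror_and_crop,
    rescale_to_michelson,
    simulate,
    triangle_mask,
)

# small, fast solver settings for factory tests (defaults are exercised in
# the acceptance suite)
FAST_RD = RDParams(grid_height=64, grid_width=64, n_steps=4000)


def michelson(vals):
    return (vals.max() - vals.min()) / (vals.max() + vals.min())


class TestRescaleToMichelson:
    def test_low_contrast_band(self, rng):
        out = rescale_to_michelson(rng.random((40, 40)), 0.15, 0.5)
        assert out.min() == pytest.approx(0.425, abs=1e-12)
        assert out.max() == pytest.approx(0.575, abs=1e-12)

    def test_full_contrast_reaches_zero(self, rng):
        out = rescale_to_michelson(rng.random((40, 40)), 1.0, 0.5)
        assert out.min() == pytest.approx(0.0, abs=1e-12)
        assert out.max() == pytest.approx(1.0, abs=1e-12)

    def test_zero_contrast_is_constant(self, rng):
        out = rescale_to_michelson(rng.random((10, 10)), 0.0, 0.37)
        assert np.all(out == 0.37)

    def test_constant_field_rejected(self):
        with pytest.raises(ValueError, match="[Cc]onstant"):
            rescale_to_michelson(np.full((8, 8), 0.2), 0.5, 0.5)

    def test_infeasible_pair_names_feasible_range(self):
        with pytest.raises(ValueError, match="feasible mean range"):
            rescale_to_michelson(np.random.default_rng(0).random((8, 8)), 1.0, 0.8)

    @given(
        target=st.floats(0.01, 1.0),
        mean=st.floats(0.05, 0.45),
        seed=st.integers(0, 10_000),
    )
    def test_rank_preserving_and_exact(self, target, mean, seed):
        vals = np.random.default_rng(seed).random(200)
        out = rescale_to_michelson(vals, target, mean)
        assert michelson(out) == pytest.approx(target, abs=1e-9)
        assert (out.max() + out.min()) / 2 == pytest.approx(mean, abs=1e-9)
        assert spearmanr(vals, out).statistic == pytest.approx(1.0)


class TestGeometry:
    def test_pixel_dimensions_from_physical_size(self):
        # recomputed independently: px = round(mm / 25.4 * 600)
        spec = StimulusSpec(contrast_level=1.0, pattern_class="spots")
        assert spec.px_width == round(44 / 25.4 * 600) == 1039
        assert spec.px_height == round(37 / 25.4 * 600) == 874

    def test_mask_bounding_box_and_area(self):
        spec = StimulusSpec(contrast_level=1.0, pattern_class="spots")
        mask = triangle_mask(spec)
        assert mask.shape == (874, 1039)
        rows = np.flatnonzero(mask.any(axis=1))
        cols = np.flatnonzero(mask.any(axis=0))
        assert rows[-1] - rows[0] + 1 == 874
        assert cols[-1] - cols[0] + 1 == 1039
        # triangle fills half the bounding box, within rasterization error
        assert mask.mean() == pytest.approx(0.5, abs=0.01)

    def test_mask_apex_up_base_down(self):
        mask = triangle_mask(StimulusSpec(contrast_level=1.0, pattern_class="spots"))
        assert mask[0].sum() < mask[-1].sum()
        assert mask[-1].all()


class TestMirrorAndCrop:
    def test_output_is_mirror_symmetric(self, rng):
        spec = StimulusSpec(contrast_level=1.0, pattern_class="spots",
                            triangle_base_mm=10, triangle_height_mm=8, dpi=150)
        raster = rng.random((spec.px_height, spec.px_width))
        img = mirror_and_crop(raster, spec)
        flipped = img.pixels[:, ::-1]
        assert np.array_equal(img.pixels[img.mask], flipped[img.mask])
        assert np.array_equal(img.mask, img.mask[:, ::-1])

    def test_outside_mask_is_white(self, rng):
        spec = StimulusSpec(contrast_level=1.0, pattern_class="spots",
                            triangle_base_mm=10, triangle_height_mm=8, dpi=150)
        img = mirror_and_crop(rng.random((spec.px_height, spec.px_width)), spec)
        assert np.all(img.pixels[~img.mask] == 1.0)

    def test_too_small_raster_reports_requirement(self):
        spec = StimulusSpec(contrast_level=1.0, pattern_class="spots")
        with pytest.raises(ValueError, match="at least"):
            mirror_and_crop(np.zeros((874, 100)), spec)
        with pytest.raises(ValueError, match="at least"):
            mirror_and_crop(np.zeros((100, 1039)), spec)


class TestMeasureContrast:
    def _image(self, masked_values):
        spec = StimulusSpec(contrast_level=0.15, pattern_class="spots",
                            triangle_base_mm=4, triangle_height_mm=4, dpi=100)
        mask = triangle_mask(spec)
        pixels = np.ones(mask.shape)
        pixels[mask] = np.resize(masked_values, mask.sum())
        from apostim import StimulusImage

        return StimulusImage(pixels, mask, spec, 0.0, 0.0)

    def test_constant_pattern_zero_contrast(self):
        m = measure_contrast(self._image([0.5]))
        assert m["michelson"] == 0.0
        assert m["mean"] == 0.5

    def test_two_level_pattern_matches_formula(self):
        m = measure_contrast(self._image([0.425, 0.575]))
        assert m["michelson"] == pytest.approx(0.15, abs=1e-12)

    def test_empty_mask_rejected(self):
        from apostim import StimulusImage

        spec = StimulusSpec(contrast_level=0.15, pattern_class="spots",
                            triangle_base_mm=4, triangle_height_mm=4, dpi=100)
        img = StimulusImage(np.ones((4, 4)), np.zeros((4, 4), bool), spec, 0, 0)
        with pytest.raises(ValueError, match="mask"):
            measure_contrast(img)


class TestGenerateCategory:
    SMALL = StimulusSpec(contrast_level=1.0, pattern_class="spots",
                         triangle_base_mm=11, triangle_height_mm=9.25, dpi=300)

    def test_single_variant_manifest(self):
        imgs, manifest = generate_category(
            "spots", 1.0, n_variants=1, base_seed=3, spec=self.SMALL, rd_params=FAST_RD
        )
        assert len(imgs) == 1 and len(manifest) == 1
        assert manifest.loc[0, "seed"] == 3
        assert manifest.loc[0, "px_width"] == round(11 / 25.4 * 300)

    def test_deterministic_across_calls(self):
        a_imgs, a_man = generate_category(
            "spots", 0.15, n_variants=2, base_seed=9, spec=self.SMALL, rd_params=FAST_RD
        )
        b_imgs, b_man = generate_category(
            "spots", 0.15, n_variants=2, base_seed=9, spec=self.SMALL, rd_params=FAST_RD
        )
        assert a_man.equals(b_man)
        for a, b in zip(a_imgs, b_imgs):
            assert np.array_equal(a.pixels, b.pixels)

    @pytest.mark.parametrize("contrast", [0.15, 1.0])
    def test_contrast_and_mean_hit_targets(self, contrast):
        imgs, _ = generate_category(
            "spots", contrast, n_variants=2, base_seed=1, spec=self.SMALL, rd_params=FAST_RD
        )
        for img in imgs:
            assert img.achieved_contrast == pytest.approx(contrast, abs=0.01)
            assert img.achieved_mean == pytest.approx(0.5, abs=0.005)

    def test_mean_matched_across_contrast_conditions(self):
        low, _ = generate_category("spots", 0.15, 2, base_seed=1,
                                   spec=self.SMALL, rd_params=FAST_RD)
        high, _ = generate_category("spots", 1.0, 2, base_seed=1,
                                    spec=self.SMALL, rd_params=FAST_RD)
        mlow = np.mean([i.achieved_mean for i in low])
        mhigh = np.mean([i.achieved_mean for i in high])
        assert abs(mlow - mhigh) < 0.01

    def test_rank_preservation_field_to_stimulus(self):
        """Tone normalization plus the affine map never reorders pixels."""
        fld = simulate(RDParams(grid_height=64, grid_width=64, n_steps=4000, seed=2))
        img = make_stimulus(fld, self.SMALL)
        # compare pre-quantization monotonicity through the pipeline on the
        # masked upsampled field values
        from apostim.stimulus import _field_to_raster, _mirror

        raster = _field_to_raster(fld, self.SMALL)
        full = _mirror(raster, self.SMALL.px_width)
        rho = spearmanr(full[img.mask], img.pixels[img.mask]).statistic
        assert rho > 0.9999

    def test_bad_n_variants(self):
        with pytest.raises(ValueError):
            generate_category("spots", 1.0, n_variants=0)


class TestStimulusSpecValidation:
    def test_infeasible_mean_contrast_pair(self):
        with pytest.raises(ValueError, match="feasible"):
            StimulusSpec(contrast_level=1.0, pattern_class="spots", mean_reflectance=0.7)

    @pytest.mark.parametrize("kwargs", [
        {"contrast_level": 1.2, "pattern_class": "spots"},
        {"contrast_level": 0.5, "pattern_class": "zigzag"},
        {"contrast_level": 0.5, "pattern_class": "spots", "mean_reflectance": 0.0},
    ])
    def test_invalid_spec(self, kwargs):
        with pytest.raises(ValueError):
            StimulusSpec(**kwargs)
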