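"""Pixel draws, normalization, patch stacks and dihedral augmentation."""

import numpy as np
import pytest

from bbseg.params import ParamSet
from bbseg.sampling import (
    MultiScaleExtractor,
    SampleBudget,
    dihedral,
    draw_samples,
    extract_stack,
    normalize_image,
)


class TestNormalize:
    def test_constant_image_maps_to_zero(self):
        assert not normalize_image(np.full((8, 8), 3.7)).any()

    def test_zero_mean_unit_variance(self, rng):
        norm = normalize_image(rng.uniform(10, 200, (40, 30)))
        assert abs(norm.mean()) < 1e-6
        assert abs(norm.std() - 1) < 1e-5

    def test_invariant_to_positive_affine_rescale(self, rng):
        img = rng.uniform(0, 1, (25, 25))
        assert np.allclose(
            normalize_image(img), normalize_image(3.2 * img + 17.0), atol=1e-5
        )

    def test_rgb_luma_collapses_to_single_channel(self, rng):
        img = rng.uniform(0, 255, (10, 10, 3))
        assert normalize_image(img, "luma").shape == (10, 10)
        assert normalize_image(img, "keep3").shape == (10, 10, 3)


class TestExtractStack:
    def test_constant_image_gives_constant_channels(self):
        norm = np.zeros((60, 60), np.float32)
        stack = extract_stack(norm, (30, 30), (1, 3, 9), 25)
        assert stack.shape == (25, 25, 3)
        assert not stack.any()

    def test_scale1_channel_is_the_literal_window(self):
        norm = np.arange(80 * 80, dtype=np.float32).reshape(80, 80)
        stack = extract_stack(norm, (40, 37), (1, 3), 25)
        assert np.array_equal(stack[:, :, 0], norm[40 - 12 : 40 + 13, 37 - 12 : 37 + 13])

    def test_four_scales_give_four_channels(self, rng):
        norm = rng.normal(size=(100, 100)).astype(np.float32)
        assert extract_stack(norm, (50, 50), (1, 3, 9, 27), 25).shape == (25, 25, 4)

    def test_invalid_scale_rejected(self):
        with pytest.raises(ValueError):
            extract_stack(np.zeros((30, 30), np.float32), (5, 5), (0, 1), 25)

    def test_fast_extractor_matches_reference(self, rng):
        norm = rng.normal(size=(50, 41)).astype(np.float32)
        scales = (1, 3, 9)
        ex = MultiScaleExtractor(norm, scales, 25)
        rows = rng.integers(0, 50, 25)
        cols = rng.integers(0, 41, 25)
        fast = ex.stacks(rows, cols)
        for i in range(len(rows)):
            ref = extract_stack(norm, (rows[i], cols[i]), scales, 25)
            assert np.allclose(fast[i], ref, atol=1e-5)


class TestDihedral:
    def test_k0_is_identity(self, rng):
        stack = rng.normal(size=(25, 25, 2)).astype(np.float32)
        assert np.array_equal(dihedral(stack, 0), stack)

    def test_quarter_turn_has_order_four(self, rng):
        stack = rng.normal(size=(25, 25, 2)).astype(np.float32)
        out = stack
        for _ in range(4):
            out = dihedral(out, 1)
        assert np.array_equal(out, stack)

    def test_eight_outputs_pairwise_distinct_on_asymmetric_patch(self, rng):
        stack = rng.normal(size=(25, 25, 1)).astype(np.float32)
        outs = [dihedral(stack, k) for k in range(8)]
        for i in range(8):
            for j in range(i + 1, 8):
                assert not np.array_equal(outs[i], outs[j])

    def test_applied_identically_to_every_channel(self, rng):
        stack = rng.normal(size=(25, 25, 3)).astype(np.float32)
        out = dihedral(stack, 5)
        for c in range(3):
            assert np.array_equal(out[:, :, c], dihedral(stack[:, :, c : c + 1], 5)[:, :, 0])


def _scene(rng, h=40, w=25, n_fg=100):
    """A small labeled scene: one blob of ~n_fg pixels in a h x w image."""
    norm = rng.normal(size=(h, w)).astype(np.float32)
    lab = np.zeros((h, w), np.int32)
    side = int(np.sqrt(n_fg))
    lab[5 : 5 + side, 5 : 5 + side] = 1
    return norm, lab


class TestDrawSamples:
    def test_full_fraction_unbalanced_covers_every_aoi_pixel_once(self, rng):
        norm, lab = _scene(rng)
        params = ParamSet(fraction=1.0, balance_classes=False, scales=(1,))
        draw, budget = draw_samples([norm], [lab], None, params, rng)
        assert budget.M == norm.size
        assert len(draw) == norm.size
        seen = set(zip(draw.rows.tolist(), draw.cols.tolist()))
        assert len(seen) == norm.size

    def test_balanced_draw_splits_classes_within_one(self, rng):
        # 1000 eligible pixels: 900 outies, 100 innies; F=0.5 -> 500 draws
        norm = rng.normal(size=(40, 25)).astype(np.float32)
        lab = np.zeros((40, 25), np.int32)
        lab[:4, :25] = 1  # 100 innie pixels
        params = ParamSet(fraction=0.5, balance_classes=True, scales=(1,))
        draw, budget = draw_samples([norm], [lab], None, params, rng)
        assert len(draw) == 500
        n_in = int(draw.class_label.sum())
        assert abs(n_in - (500 - n_in)) <= 1

    def test_aoi_exclusion_is_absolute(self, rng):
        norm, lab = _scene(rng)
        aoi = np.ones_like(lab, bool)
        aoi[:, : lab.shape[1] // 2] = False  # exclude the left half
        params = ParamSet(fraction=1.0, balance_classes=False, scales=(1,))
        draw, _ = draw_samples([norm], [lab], [aoi], params, rng)
        assert (draw.cols >= lab.shape[1] // 2).all()

    def test_identical_seed_gives_identical_stream(self, rng):
        norm, lab = _scene(rng)
        params = ParamSet(fraction=0.3, scales=(1, 3))
        d1, _ = draw_samples([norm], [lab], None, params, np.random.default_rng(7))
        d2, _ = draw_samples([norm], [lab], None, params, np.random.default_rng(7))
        for attr in ("image_index", "rows", "cols", "class_label", "dist_label"):
            assert np.array_equal(getattr(d1, attr), getattr(d2, attr))

    def test_outie_samples_have_zero_distance_label(self, rng):
        norm, lab = _scene(rng)
        params = ParamSet(fraction=1.0, balance_classes=False, scales=(1,))
        draw, _ = draw_samples([norm], [lab], None, params, rng)
        assert not draw.dist_label[draw.class_label == 0].any()

    def test_empty_aoi_is_an_error(self, rng):
        norm, lab = _scene(rng)
        aoi = np.zeros_like(lab, bool)
        with pytest.raises(ValueError, match="eligible"):
            draw_samples([norm], [lab], [aoi], ParamSet(scales=(1,)), rng)


class TestBudget:
    @pytest.mark.parametrize(
        "M, F, E",
        [(1000, 1.0, 2), (1000, 0.01, 2), (1030, 0.01, 2), (977, 0.37, 3), (50, 1.0, 1)],
    )
    def test_T_is_round_EFM(self, M, F, E):
        b = SampleBudget(M=M, F=F, E=E)
        assert b.T == round(E * F * M)
        assert abs(b.EF - b.T / b.M) < 1e-12
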