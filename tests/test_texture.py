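"""Tamura and GLTP descriptors against naive per-pixel oracles."""

import numpy as np
import pytest

from hemotex.errors import ParameterError, ValidationError
from hemotex.imaging_io import IntensityImage, Mask
from hemotex.texture import (
    NEIGHBOR_OFFSETS,
    GradientField,
    extract_features,
    gltp_descriptor,
    gltp_encode,
    gltp_histogram,
    gltp_split_codes,
    sobel_gradients,
    tamura_coarseness,
    tamura_contrast,
    tamura_directionality,
)


def naive_gltp(gmag, t):
    """Brute-force double-loop GLTP: the oracle the fast path must match."""
    M, N = gmag.shape
    h_n = np.zeros(256)
    h_p = np.zeros(256)
    for r in range(1, M - 1):
        for c in range(1, N - 1):
            gc = gmag[r, c]
            n_code = p_code = 0
            for b, (dr, dc) in enumerate(NEIGHBOR_OFFSETS):
                nb = gmag[r + dr, c + dc]
                if nb < gc - t:
                    n_code += 2**b
                elif nb > gc + t:
                    p_code += 2**b
            h_n[n_code] += 1
            h_p[p_code] += 1
    return h_n, h_p


class TestSobel:
    def test_constant_image_zero_gradient(self):
        f = sobel_gradients(IntensityImage(np.full((8, 8), 0.3)))
        assert np.allclose(f.Gmag, 0.0)

    def test_additive_shift_invariance(self, rng):
        px = rng.random((16, 16)) * 0.8
        a = sobel_gradients(IntensityImage(px))
        b = sobel_gradients(IntensityImage(px + 0.1))
        np.testing.assert_allclose(a.Gmag, b.Gmag, atol=1e-12)

    def test_vertical_step_edge_response(self):
        # hand-convolved 3x3 Sobel on a 0|1 step: 1+2+1 = 4 at the edge
        px = np.zeros((8, 8))
        px[:, 4:] = 1.0
        f = sobel_gradients(IntensityImage(px))
        assert f.Gmag.max() == pytest.approx(4.0)
        edge_cols = np.flatnonzero(np.abs(f.Gi).max(axis=0) == 4.0)
        assert set(edge_cols) == {3, 4}
        assert np.allclose(f.Gj[:, 3:5], 0.0)


class TestGLTPEncode:
    def test_band_quantization_forced_cases(self):
        g = np.full((3, 3), 100.0)
        for nb_val, expected in [(85.0, -1), (105.0, 0), (120.0, +1)]:
            g2 = g.copy()
            g2[0, 0] = nb_val  # top-left neighbor = bit 0
            field = GradientField(Gi=g2, Gj=np.zeros_like(g2), Gmag=g2)
            codes = gltp_encode(field, t_gltp=10.0).codes
            assert codes[0, 0, 0] == expected

    def test_constant_field_all_zero_codes(self):
        g = np.full((6, 6), 5.0)
        field = GradientField(Gi=g, Gj=g, Gmag=g)
        assert np.all(gltp_encode(field, 0.5).codes == 0)

    def test_ramp_with_zero_band_splits_left_right(self):
        g = np.tile(np.arange(8, dtype=float), (8, 1))  # increasing ramp
        field = GradientField(Gi=g, Gj=g, Gmag=g)
        codes = gltp_encode(field, 0.0).codes
        # bits 2,3,4 look rightward (larger), bits 0,6,7 leftward (smaller)
        assert np.all(codes[:, :, [2, 3, 4]] == 1)
        assert np.all(codes[:, :, [0, 6, 7]] == -1)
        assert np.all(codes[:, :, [1, 5]] == 0)

    def test_negative_threshold_rejected(self):
        g = np.zeros((4, 4))
        with pytest.raises(ParameterError):
            gltp_encode(GradientField(g, g, g), -0.1)


class TestSplitCodes:
    @pytest.mark.parametrize("ternary,expected", [
        (np.zeros(8), (0, 0)),
        (np.ones(8), (0, 255)),
        (-np.ones(8), (255, 0)),
        # +1 at bit 0, -1 at bit 3 -> n = 2^3 = 8, p = 2^0 = 1
        (np.array([1, 0, 0, -1, 0, 0, 0, 0]), (8, 1)),
    ])
    def test_binary_expansion(self, ternary, expected):
        from hemotex.texture import TernaryCodeImage

        codes = np.asarray(ternary, dtype=np.int8).reshape(1, 1, 8)
        pair = gltp_split_codes(TernaryCodeImage(codes=codes, t_gltp=0.0))
        assert (pair.n_codes[0, 0], pair.p_codes[0, 0]) == expected


class TestGLTPHistogram:
    def test_all_zero_codes_single_bin(self):
        img = IntensityImage(np.full((10, 10), 0.5))
        h = gltp_descriptor(img, normalize_hist=False)
        assert h.h_n[0] == 64 and h.h_p[0] == 64  # 8x8 interior
        assert h.h_n[1:].sum() == 0 and h.h_p[1:].sum() == 0

    def test_conservation_and_bit_disjointness(self, rng):
        for _ in range(5):
            img = IntensityImage(rng.random((20, 20)))
            field = sobel_gradients(img)
            pair = gltp_split_codes(gltp_encode(field, 0.1))
            assert not np.any(pair.n_codes & pair.p_codes)
            h = gltp_histogram(pair)
            assert h.h_n.sum() == h.h_p.sum() == 18 * 18

    def test_matches_naive_double_loop_bit_exactly(self, rng):
        for _ in range(3):
            img = IntensityImage(rng.random((16, 16)))
            gmag = sobel_gradients(img).Gmag
            gmag = gmag / gmag.max()
            t = 0.05
            field = GradientField(gmag, gmag, gmag)
            pair = gltp_split_codes(gltp_encode(field, t))
            h = gltp_histogram(pair)
            h_n, h_p = naive_gltp(gmag, t)
            assert np.array_equal(h.h_n, h_n)
            assert np.array_equal(h.h_p, h_p)

    def test_descriptor_invariant_to_intensity_shift(self, rng):
        px = rng.random((24, 24)) * 0.8
        a = gltp_descriptor(IntensityImage(px))
        b = gltp_descriptor(IntensityImage(px + 0.1))
        np.testing.assert_allclose(a.fused, b.fused, atol=1e-12)

    def test_descriptor_not_invariant_to_contrast_scaling(self, rng):
        px = rng.random((24, 24))
        a = gltp_descriptor(IntensityImage(px), rescale_gmag=False)
        b = gltp_descriptor(IntensityImage(px * 0.3), rescale_gmag=False)
        assert not np.allclose(a.fused, b.fused)


class TestTamura:
    def test_coarseness_constant_image_is_one(self):
        assert tamura_coarseness(IntensityImage(np.full((40, 40), 0.5))) == 1.0

    def test_coarseness_increases_with_checker_size(self):
        def board(cell):
            idx = np.add.outer(np.arange(64) // cell, np.arange(64) // cell)
            return IntensityImage((idx % 2).astype(float))

        assert tamura_coarseness(board(4)) > tamura_coarseness(board(1))

    def test_coarseness_at_least_one(self, rng):
        img = IntensityImage(rng.random((40, 40)))
        assert tamura_coarseness(img) >= 1.0

    def test_contrast_constant_is_zero(self):
        assert tamura_contrast(IntensityImage(np.full((8, 8), 0.7))) == 0.0

    def test_contrast_half_zero_half_one_closed_form(self):
        px = np.zeros((8, 8))
        px[:4] = 1.0
        # sigma = 0.5, mu4 = 0.0625, kurtosis = 1 -> contrast 0.5
        assert tamura_contrast(IntensityImage(px)) == pytest.approx(0.5)

    def test_contrast_scales_linearly_with_intensity(self, rng):
        px = rng.random((16, 16))
        c1 = tamura_contrast(IntensityImage(px))
        c2 = tamura_contrast(IntensityImage(px * 0.5))
        assert c2 == pytest.approx(0.5 * c1, rel=1e-10)

    def test_directionality_stripes_beat_noise(self, rng):
        stripes = IntensityImage(
            np.tile((np.arange(32) // 4 % 2).astype(float), (32, 1)))
        noise = IntensityImage(rng.random((32, 32)))
        d_stripes = tamura_directionality(stripes)
        d_noise = tamura_directionality(noise)
        assert d_stripes > d_noise
        assert d_stripes > 0.9

    def test_directionality_constant_is_zero(self):
        assert tamura_directionality(IntensityImage(np.full((16, 16), 0.2))) == 0.0

    def test_directionality_rotation_invariant(self):
        stripes = np.tile((np.arange(32) // 4 % 2).astype(float), (32, 1))
        a = tamura_directionality(IntensityImage(stripes))
        b = tamura_directionality(IntensityImage(np.rot90(stripes).copy()))
        assert a == pytest.approx(b, abs=1e-6)


class TestExtractFeatures:
    def _sample(self):
        from hemotex.phantom import PhantomSpec, Subtype, generate_slice

        return generate_slice(PhantomSpec(subtype=Subtype.EPIDURAL, seed=3))

    def test_fused_length_is_3b2_plus_512(self):
        s = self._sample()
        fv = extract_features(s.image, s.lesion_mask, block_grid=4)
        assert len(fv) == 3 * 16 + 512
        assert len(fv.names) == 560

    def test_name_provenance_ordering(self):
        s = self._sample()
        fv = extract_features(s.image, s.lesion_mask)
        assert fv.names[0].startswith("tamura_")
        assert fv.names[48] == "gltp_n_000"
        assert fv.names[-1] == "gltp_p_255"

    def test_deterministic(self):
        s = self._sample()
        a = extract_features(s.image, s.lesion_mask)
        b = extract_features(s.image, s.lesion_mask)
        assert np.array_equal(a.values, b.values)

    def test_gltp_half_invariant_to_clip_free_shift(self):
        s = self._sample()
        base = s.image.pixels * 0.5  # leave headroom for the shift
        m = s.lesion_mask
        a = extract_features(IntensityImage(base), m)
        b = extract_features(IntensityImage(base + 0.1), m)
        np.testing.assert_allclose(a.values[48:], b.values[48:], atol=1e-12)

    def test_empty_mask_rejected(self):
        s = self._sample()
        with pytest.raises(ValidationError):
            extract_features(s.image, Mask(np.zeros(s.image.shape)))
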