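"""Otsu segmentation, the complex wavelet pyramid, and the CW-SSI index."""

import numpy as np
import pytest

from angioqa.phantom import PhantomSpec, add_noise, build_vessel_tree, project_dsa_like, rasterize
from angioqa.edges import mip
from angioqa.similarity import (
    SimilarityConfig,
    compare_modality,
    cwssi,
    cwssi_band,
    cwssi_band_factored,
    cwt_forward,
    cwt_inverse,
    otsu_threshold,
)
from angioqa.volume import Image2D


def brute_force_otsu(data, n_bins=256):
    """Independent oracle: scan every split of the 256-bin histogram,
    scoring each split with exact rational arithmetic (Fraction) so that
    plateau ties resolve to the lowest threshold, not by float noise."""
    from fractions import Fraction

    counts, edges = np.histogram(data.ravel(), bins=n_bins, range=(data.min(), data.max()))
    counts = [int(v) for v in counts]
    best_t, best_v = 0, Fraction(-1)
    for t in range(n_bins - 1):
        w0, w1 = sum(counts[: t + 1]), sum(counts[t + 1 :])
        if w0 == 0 or w1 == 0:
            continue
        # bin indices are affine in intensity -> same argmax as bin centers
        m0 = Fraction(sum(i * c for i, c in enumerate(counts[: t + 1])), w0)
        m1 = Fraction(sum(i * c for i, c in enumerate(counts) if i > t), w1)
        v = w0 * w1 * (m0 - m1) ** 2
        if v > best_v:  # strict: ties stay at the lower threshold
            best_t, best_v = t, v
    return float(edges[best_t + 1])


class TestOtsu:
    def test_bimodal_separation_recovers_classes(self):
        rng = np.random.default_rng(0)
        data = rng.permutation(np.concatenate([np.full(500, 10.0), np.full(500, 200.0)]))
        img = Image2D(data.reshape(25, 40))
        t = otsu_threshold(img)
        assert 10.0 <= t < 200.0
        assert np.array_equal(img.data > t, img.data == 200.0)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_brute_force_scan(self, seed):
        rng = np.random.default_rng(seed)
        data = np.concatenate([rng.normal(40, 12, 600), rng.normal(160, 25, 400)])
        img = Image2D(data.reshape(40, 25))
        assert otsu_threshold(img) == brute_force_otsu(img.data)

    def test_intensity_inversion_gives_complementary_classes(self):
        rng = np.random.default_rng(1)
        data = np.concatenate([rng.normal(30, 5, 500), rng.normal(170, 10, 500)]).reshape(25, 40)
        fg = data > otsu_threshold(Image2D(data))
        inv = data.max() - data
        fg_inv = inv > otsu_threshold(Image2D(inv))
        assert np.mean(fg == ~fg_inv) > 0.99  # complement up to bin-edge pixels

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError):
            otsu_threshold(Image2D(np.full((10, 10), 5.0)))


class TestPyramid:
    def test_zero_image_gives_zero_coefficients(self):
        sb = cwt_forward(np.zeros((64, 64)))
        assert all(np.all(b == 0) for b in sb.bands.values())
        assert np.all(sb.lowpass == 0) and np.all(sb.highpass == 0)

    def test_round_trip_reconstruction(self, rng):
        img = rng.normal(size=(96, 128))
        rec = cwt_inverse(cwt_forward(img))
        rel = np.sqrt(np.mean((rec - img) ** 2)) / np.sqrt(np.mean(img**2))
        assert rel < 1e-6

    def test_parseval_energy_conservation(self, rng):
        img = rng.normal(size=(64, 64))
        sb = cwt_forward(img)
        e_bands = sum(float(np.sum(np.abs(b) ** 2)) for b in sb.bands.values())
        e_total = e_bands + float(np.sum(sb.highpass**2)) + float(np.sum(sb.lowpass**2))
        assert e_total == pytest.approx(float(np.sum(img**2)), rel=0.01)

    def test_dyadic_shrink_of_band_grids(self, rng):
        sb = cwt_forward(rng.normal(size=(64, 64)))
        for (scale, _), band in sb.bands.items():
            assert band.shape == (64 // 2 ** (scale - 1), 64 // 2 ** (scale - 1))

    def test_band_energy_stable_under_shift(self, mip_fine):
        """A 1-px translation must not shuffle energy between sub-bands (the
        near-shift-invariance a critically-sampled wavelet transform lacks)."""
        sa = cwt_forward(mip_fine)
        sb = cwt_forward(np.roll(mip_fine, 1, axis=0))
        for key in sa.bands:
            ea = float(np.mean(np.abs(sa.bands[key]) ** 2))
            eb = float(np.mean(np.abs(sb.bands[key]) ** 2))
            assert eb == pytest.approx(ea, rel=0.05)

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError):
            cwt_forward(np.zeros((8, 8)), SimilarityConfig(n_levels=4))


class TestCwssiBand:
    def test_identity_is_exactly_one(self, rng):
        cx = rng.normal(size=(32, 32)) + 1j * rng.normal(size=(32, 32))
        assert cwssi_band(cx, cx, 1e-8) == 1.0

    def test_global_phase_invariance(self, rng):
        cx = rng.normal(size=(32, 32)) + 1j * rng.normal(size=(32, 32))
        cx /= np.sqrt(np.sum(np.abs(cx) ** 2))  # unit energy
        cy = cx * np.exp(1j * 0.83)
        assert cwssi_band(cx, cy, 1e-8) == pytest.approx(1.0, abs=1e-6)

    def test_direct_formula_on_independent_grids(self, rng):
        cx = rng.normal(size=(64, 64)) + 1j * rng.normal(size=(64, 64))
        cy = rng.normal(size=(64, 64)) + 1j * rng.normal(size=(64, 64))
        K = 0.7
        # independent summation route
        num = 2.0 * abs(sum(cx.ravel()[i] * np.conj(cy.ravel()[i]) for i in range(0, cx.size, 1))) + K
        den = float(sum(abs(v) ** 2 for v in cx.ravel()) + sum(abs(v) ** 2 for v in cy.ravel())) + K
        assert cwssi_band(cx, cy, K) == pytest.approx(num / den, abs=1e-12)

    @pytest.mark.parametrize("seed", range(6))
    def test_two_printed_forms_agree(self, seed):
        rng = np.random.default_rng(seed)
        cx = rng.normal(size=(16, 16)) + 1j * rng.normal(size=(16, 16))
        cy = rng.normal(size=(16, 16)) + 1j * rng.normal(size=(16, 16))
        assert abs(cwssi_band(cx, cy, 0.01) - cwssi_band_factored(cx, cy, 0.01)) < 1e-12

    def test_magnitude_term_alone_ignores_phase(self, rng):
        cx = rng.normal(size=(16, 16)) + 1j * rng.normal(size=(16, 16))
        cy = np.abs(cx) * np.exp(1j * rng.uniform(0, 2 * np.pi, (16, 16)))  # |cy| = |cx|
        K = 1e-9
        mags = 2.0 * float(np.sum(np.abs(cx) * np.abs(cy))) + K
        energy = float(np.sum(np.abs(cx) ** 2) + np.sum(np.abs(cy) ** 2)) + K
        assert mags / energy == pytest.approx(1.0, abs=1e-9)
        assert cwssi_band(cx, cy, K) < 0.9  # but the full index sees the phases

    def test_boundedness_over_random_pairs(self, rng):
        for _ in range(200):
            cx = rng.normal(size=(8, 8)) + 1j * rng.normal(size=(8, 8))
            cy = rng.normal(size=(8, 8)) + 1j * rng.normal(size=(8, 8))
            v = cwssi_band(cx, cy, 0.5)
            assert 0.0 < v <= 1.0 + 1e-12

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            cwssi_band(np.zeros((4, 4), complex), np.zeros((4, 5), complex), 1.0)


class TestCwssiImages:
    def test_identical_images_score_one(self, mip_fine):
        assert cwssi(mip_fine, mip_fine).cwssi == 1.0

    def test_small_shifts_stay_high_and_beat_pixelwise_ssim(self, mip_fine):
        from skimage.metrics import structural_similarity

        for d in (1, 2, 3):
            shifted = np.roll(mip_fine, d, axis=0)
            v = cwssi(mip_fine, shifted).cwssi
            assert v >= 0.9
            if d == 2:
                assert v >= 0.95
                assert v > structural_similarity(mip_fine, shifted, data_range=1.0)

    def test_three_degree_rotation_stays_high(self, mip_fine):
        from scipy import ndimage

        rot = ndimage.rotate(mip_fine, 3.0, reshape=False, order=1)
        assert cwssi(mip_fine, rot).cwssi >= 0.85

    def test_independent_noise_scores_low(self, mip_fine):
        for seed in range(10):
            noise = np.random.default_rng(100 + seed).random(mip_fine.shape)
            assert cwssi(mip_fine, noise).cwssi < 0.3

    def test_k_robustness(self, mip_fine):
        """Halving the auto stabilizer changes the index by < 1e-3 on a
        non-degenerate pair: K matters only near zero energy."""
        shifted = np.roll(mip_fine, 2, axis=0)
        v1 = cwssi(mip_fine, shifted, SimilarityConfig(k_fraction=0.01)).cwssi
        v2 = cwssi(mip_fine, shifted, SimilarityConfig(k_fraction=0.005)).cwssi
        assert abs(v1 - v2) < 1e-3

    def test_global_aggregation_stays_bounded(self, mip_fine):
        cfg = SimilarityConfig(aggregation="global_per_band_mean")
        v = cwssi(mip_fine, np.roll(mip_fine, 1, axis=1), cfg).cwssi
        assert 0.0 < v <= 1.0


class TestCompareModality:
    @staticmethod
    def phantom_volume(seed):
        tree = build_vessel_tree(seed=seed, n_branch_levels=4, extent_mm=(26.0, 26.0, 13.0))
        spec = PhantomSpec(grid_shape=(128, 128, 26), voxel_size=(0.2, 0.2, 0.5))
        return add_noise(rasterize(tree, spec, subsamples=2), 10.0, seed + 1000)

    def test_identical_image_scores_one(self, mip_fine):
        img = Image2D(mip_fine)
        assert compare_modality(img, img).cwssi == 1.0

    @pytest.mark.parametrize("seed", range(10))
    def test_same_anatomy_beats_different_anatomy(self, seed):
        vol = self.phantom_volume(seed)
        other = self.phantom_volume(seed + 50)
        dsa_same = project_dsa_like(vol, "axial", 2.0, 1.0, 1.5, seed=1, noise_sigma=0.01)
        dsa_other = project_dsa_like(other, "axial", 2.0, 1.0, 1.5, seed=1, noise_sigma=0.01)
        mra = mip(vol, "axial")
        assert compare_modality(mra, dsa_same).cwssi > compare_modality(mra, dsa_other).cwssi

    def test_left_right_flip_decreases_similarity(self):
        vol = self.phantom_volume(3)
        mra = mip(vol, "axial")
        dsa = project_dsa_like(vol, "axial", 2.0, 1.0, 1.5, seed=1, noise_sigma=0.01)
        flipped = Image2D(dsa.data[::-1, :].copy(), dsa.pixel_size)
        assert compare_modality(mra, flipped).cwssi < compare_modality(mra, dsa).cwssi

    def test_constant_image_raises_named_error(self, mip_fine):
        with pytest.raises(ValueError, match="dsa"):
            compare_modality(Image2D(mip_fine), Image2D(np.full((64, 64), 3.0)))

    def test_preprocessing_is_logged(self, mip_fine):
        res = compare_modality(Image2D(mip_fine), Image2D(mip_fine[:96, :96].copy()))
        assert "resample" in res.preprocessing_log
        assert "otsu" in res.preprocessing_log
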