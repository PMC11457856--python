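"""EIT synthesis, tidal images, center of ventilation, relative aeration,
and unventilated-fraction metrics."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import ventwave as vw


def _rect_mask(shape=(10, 10), pad=1):
    mask = np.zeros(shape, dtype=bool)
    mask[pad:shape[0] - pad, pad:shape[1] - pad] = True
    return mask


def _uniform_map(shape=(10, 10)):
    mask = _rect_mask(shape)
    share = np.where(mask, 1.0 / mask.sum(), 0.0)
    return vw.RegionalMap(regional_share=share, lung_mask=mask)


def _image(amplitude, mask):
    return vw.TidalImage(amplitude=np.asarray(amplitude, float),
                         lung_mask=np.asarray(mask, bool))


class TestSynthesizeEIT:
    def test_uniform_map_pixels_track_global_volume(self, rec_clean):
        rmap = _uniform_map()
        frames = vw.synthesize_eit(rec_clean, rmap)
        vol = np.interp(frames.times, rec_clean.time, rec_clean.volume)
        r, c = 4, 4
        pix = frames.frames[:, r, c]
        expected = vol * rmap.regional_share[r, c]
        np.testing.assert_allclose(pix, expected, rtol=1e-12)

    def test_null_left_lung_has_zero_amplitude(self, rec_clean):
        mask = _rect_mask()
        share = np.where(mask, 1.0, 0.0)
        share[:, 5:] = 0.0  # zero the left half (cols >= 5)
        share /= share.sum()
        rmap = vw.RegionalMap(regional_share=share, lung_mask=mask)
        frames = vw.synthesize_eit(rec_clean, rmap)
        assert np.all(frames.frames[:, :, 5:] == 0.0)

    def test_lung_sum_conserves_global_volume(self, rec_clean):
        frames = vw.synthesize_eit(rec_clean, _uniform_map())
        vol = np.interp(frames.times, rec_clean.time, rec_clean.volume)
        g = frames.global_signal()
        assert np.corrcoef(g, vol)[0, 1] > 0.999
        np.testing.assert_allclose(g, vol, rtol=1e-9, atol=1e-9)

    def test_share_must_sum_to_one(self):
        mask = _rect_mask()
        with pytest.raises(ValueError, match="sum to 1"):
            vw.RegionalMap(regional_share=np.where(mask, 1.0, 0.0),
                           lung_mask=mask)

    def test_default_map_is_right_and_ventral_weighted(self):
        rmap = vw.make_regional_map((32, 32), right_share=0.55,
                                    ventral_dorsal_bias=0.3)
        cols = (np.arange(32) + 0.5) / 32
        right = rmap.lung_mask & (cols[None, :] < 0.5)
        assert rmap.regional_share[right].sum() == pytest.approx(0.55, abs=1e-9)
        rows_top = rmap.regional_share[:16, :].sum()
        rows_bot = rmap.regional_share[16:, :].sum()
        assert rows_top > rows_bot


class TestTidalImage:
    def test_uniform_map_gives_uniform_amplitudes(self, rec_clean):
        frames = vw.synthesize_eit(rec_clean, _uniform_map())
        img = vw.tidal_image(frames)
        amps = img.amplitude[img.lung_mask]
        assert amps.std() / amps.mean() < 1e-9

    def test_amplitude_sum_matches_tidal_volume(self, rec_clean, segs_clean):
        """Sum of pixel tidal amplitudes ~ global V_T within 2%."""
        frames = vw.synthesize_eit(rec_clean, _uniform_map())
        img = vw.tidal_image(frames)
        m = vw.breath_mechanics(rec_clean, segs_clean[3])
        assert img.amplitude.sum() == pytest.approx(m.V_T, rel=0.02)

    def test_flat_signal_raises(self):
        mask = _rect_mask()
        frames = vw.EITFrameSeries(
            frames=np.ones((100, *mask.shape)), times=np.arange(100) / 48.0,
            frame_rate=48.0, lung_mask=mask)
        with pytest.raises(ValueError, match="no breath|flat"):
            vw.tidal_image(frames)


class TestCenterOfVentilation:
    def test_uniform_symmetric_phantom_is_50(self):
        mask = _rect_mask((12, 12))
        img = _image(np.where(mask, 3.7, 0.0), mask)
        assert vw.center_of_ventilation(img, "VD") == pytest.approx(50.0)
        assert vw.center_of_ventilation(img, "RL") == pytest.approx(50.0)
        assert vw.uniform_cov(mask, "VD") == pytest.approx(50.0)

    def test_two_pixel_hand_centroid(self):
        """Pixels at 25% and 75% with weights 1 and 3: CoV = 62.5%."""
        mask = np.zeros((2, 1), dtype=bool)
        mask[:, 0] = True
        amp = np.array([[1.0], [3.0]])
        img = _image(amp, mask)
        assert vw.center_of_ventilation(img, "VD") == pytest.approx(62.5)

    def test_point_mass_at_dorsal_extreme(self):
        mask = _rect_mask((10, 10))
        amp = np.zeros((10, 10))
        amp[8, :] = 1.0  # most dorsal mask row
        img = _image(np.where(mask, amp, 0.0), mask)
        rows = np.flatnonzero(mask.any(axis=1))
        expected = (8 - rows[0] + 0.5) / (rows[-1] - rows[0] + 1) * 100
        assert vw.center_of_ventilation(img, "VD") == pytest.approx(expected)

    @given(st.integers(0, 2 ** 31 - 1))
    def test_mirror_identity_and_scale_invariance(self, seed):
        rng = np.random.default_rng(seed)
        mask = _rect_mask((9, 11))
        amp = np.where(mask, rng.uniform(0.1, 2.0, mask.shape), 0.0)
        img = _image(amp, mask)
        cov = vw.center_of_ventilation(img, "VD")
        flipped = _image(amp[::-1], mask[::-1])
        assert vw.center_of_ventilation(flipped, "VD") == pytest.approx(
            100.0 - cov, abs=1e-9)
        scaled = _image(amp * 37.2, mask)
        assert vw.center_of_ventilation(scaled, "VD") == pytest.approx(
            cov, abs=1e-9)

    def test_all_zero_image_raises(self):
        mask = _rect_mask()
        img = _image(np.zeros(mask.shape), mask)
        with pytest.raises(ValueError, match="all-zero"):
            vw.center_of_ventilation(img, "VD")


class TestRelativeAeration:
    def test_uniform_is_one_everywhere(self):
        mask = _rect_mask((12, 12))
        img = _image(np.where(mask, 1.0, 0.0), mask)
        regions = vw.standard_regions(mask)["VD"]
        for ratio in vw.relative_aeration(img, regions).values():
            assert ratio == pytest.approx(1.0)

    def test_ratio_arithmetic(self):
        """Region with 50% of pixels but 60% of signal: ratio 1.2."""
        mask = np.zeros((2, 10), dtype=bool)
        mask[:, :] = True
        amp = np.ones((2, 10))
        amp[0] = 1.2  # top row carries 60% of the signal
        amp[1] = 0.8
        img = _image(amp, mask)
        regions = {"top": np.vstack([np.ones(10, bool), np.zeros(10, bool)]),
                   "bottom": np.vstack([np.zeros(10, bool), np.ones(10, bool)])}
        ratios = vw.relative_aeration(img, regions)
        assert ratios["top"] == pytest.approx(1.2)
        assert ratios["bottom"] == pytest.approx(0.8)

    def test_ground_truth_right_share_recovered(self, rec_clean):
        """Map built with 60% right-lung signal and equal pixel counts gives
        relative aeration 1.2 right, 0.8 left."""
        mask = _rect_mask((10, 10))
        share = np.where(mask, 1.0, 0.0)
        cols = np.arange(10)
        right = mask & (cols[None, :] < 5)
        share[right] *= 0.6 / share[right].sum()
        share[mask & ~right] *= 0.4 / share[mask & ~right].sum()
        rmap = vw.RegionalMap(regional_share=share, lung_mask=mask)
        frames = vw.synthesize_eit(rec_clean, rmap)
        img = vw.tidal_image(frames)
        ratios = vw.relative_aeration(img, {"right": right,
                                            "left": mask & ~right})
        assert ratios["right"] == pytest.approx(1.2, rel=1e-6)
        assert ratios["left"] == pytest.approx(0.8, rel=1e-6)

    @given(st.integers(0, 2 ** 31 - 1))
    def test_pixel_weighted_mean_is_one(self, seed):
        rng = np.random.default_rng(seed)
        mask = _rect_mask((12, 12))
        amp = np.where(mask, rng.uniform(0.0, 3.0, mask.shape), 0.0)
        img = _image(amp, mask)
        regions = vw.standard_regions(mask)["VD"]
        assert vw.weighted_mean_relative_aeration(img, regions) == pytest.approx(
            1.0, abs=1e-9)

    def test_partition_validation(self):
        mask = _rect_mask()
        img = _image(np.where(mask, 1.0, 0.0), mask)
        with pytest.raises(ValueError, match="empty"):
            vw.relative_aeration(img, {"a": mask, "b": np.zeros_like(mask)})
        with pytest.raises(ValueError, match="partition"):
            vw.relative_aeration(img, {"a": mask, "b": mask})


class TestUnventilatedFraction:
    def test_uniform_image_zero_percent(self):
        mask = _rect_mask()
        img = _image(np.where(mask, 2.0, 0.0), mask)
        assert vw.unventilated_fraction(img) == 0.0

    def test_ten_percent_silent_phantom(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[:, :] = True
        amp = np.ones((10, 10))
        amp.flat[:10] = 0.0  # 10 of 100 lung pixels silent
        img = _image(amp, mask)
        assert vw.unventilated_fraction(img, 0.10) == pytest.approx(10.0)

    def test_zero_threshold_returns_zero(self):
        mask = _rect_mask()
        amp = np.where(mask, 1.0, 0.0)
        amp[2, 2] = 0.0
        img = _image(amp, mask)
        assert vw.unventilated_fraction(img, 0.0) == 0.0

    def test_all_zero_image_raises(self):
        mask = _rect_mask()
        with pytest.raises(ValueError, match="all-zero"):
            vw.unventilated_fraction(_image(np.zeros(mask.shape), mask))


def test_regional_summary_keys(rec_clean):
    rmap = vw.make_regional_map((16, 16))
    frames = vw.synthesize_eit(rec_clean, rmap)
    img = vw.tidal_image(frames)
    out = vw.regional_summary(img)
    for key in ("CoV_VD", "CoV_RL", "uniform_CoV_VD", "uniform_CoV_RL",
                "unventilated_pct", "rel_aeration_ventral",
                "rel_aeration_dorsal", "rel_aeration_right",
                "rel_aeration_left"):
        assert key in out
    assert 0.0 <= out["CoV_VD"] <= 100.0
    # default map favours the ventral and right lung
    assert out["CoV_VD"] < out["uniform_CoV_VD"]
    assert out["rel_aeration_right"] > 1.0 > out["rel_aeration_left"]
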