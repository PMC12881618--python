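import numpy as np
import pytest
from scipy.special import erf
from skimage.draw import disk

from spiralpam import AcquisitionSettings, AScan, MapImage
from spiralpam.quantify import (
    GAUSSIAN_FWHM,
    axial_resolution,
    diameter_split,
    lateral_resolution,
    snr_db,
    timeseries_quantify,
    vessel_mask,
    vessel_metrics,
)

from conftest import gabor_pulse


def _edge_image(sigma_m, pixel, n=128, noise=0.0, rng=None, flipped=False):
    x = (np.arange(n) - n / 2 + 0.3) * pixel
    profile = 0.5 * (1 + erf(x / (sigma_m * np.sqrt(2))))
    if flipped:
        profile = profile[::-1]
    img = np.tile(profile, (32, 1)).T  # edge perpendicular to axis 0
    if noise:
        img = img + rng.normal(0, noise, img.shape)
    return MapImage(img, "map", pixel_size=pixel)


class TestLateralResolution:
    def test_known_gaussian_blur_recovered(self):
        res = lateral_resolution(
            _edge_image(3e-6, 1e-6), (slice(None), slice(None)), 1e-6
        )
        assert res.fwhm == pytest.approx(GAUSSIAN_FWHM * 3e-6, rel=1e-3)
        assert res.fwhm == pytest.approx(7.06e-6, rel=1e-2)

    def test_flipped_edge_same_fwhm(self):
        a = lateral_resolution(_edge_image(3e-6, 1e-6), (slice(None), slice(None)), 1e-6)
        b = lateral_resolution(
            _edge_image(3e-6, 1e-6, flipped=True), (slice(None), slice(None)), 1e-6
        )
        assert a.fwhm == pytest.approx(b.fwhm, rel=1e-6)

    def test_unreliable_fit_raises(self, rng):
        img = MapImage(rng.random((64, 16)), "map")
        with pytest.raises(ValueError, match="unreliable|contrast"):
            lateral_resolution(img, (slice(None), slice(None)), 1e-6)

    def test_noise_bias_under_20db_snr(self, rng):
        # edge amplitude 1, noise sigma 0.1 (20 dB): mean bias < 5%
        fwhms = []
        for _ in range(100):
            img = _edge_image(3e-6, 1e-6, noise=0.1, rng=rng)
            fwhms.append(
                lateral_resolution(img, (slice(None), slice(None)), 1e-6).fwhm
            )
        assert abs(np.mean(fwhms) - GAUSSIAN_FWHM * 3e-6) / (GAUSSIAN_FWHM * 3e-6) < 0.05


class TestAxialResolution:
    SETTINGS = AcquisitionSettings(record_length=2048)

    def test_analytic_gaussian_envelope(self):
        fs = self.SETTINGS.sampling_rate
        sigma_t = 20e-9
        pulse = gabor_pulse(80e6, sigma_t, fs, 2048)
        res = axial_resolution(AScan(pulse), self.SETTINGS)
        expected = GAUSSIAN_FWHM * sigma_t * self.SETTINGS.speed_of_sound
        assert res.fwhm == pytest.approx(expected, rel=1e-6)

    def test_carrier_phase_invariance(self):
        fs = self.SETTINGS.sampling_rate
        t = np.arange(2048) / fs
        t0 = 1024 / fs
        g = np.exp(-((t - t0) ** 2) / (2 * 20e-9**2))
        results = []
        for phase in (0.0, 0.7, 1.9):
            pulse = g * np.cos(2 * np.pi * 80e6 * (t - t0) + phase)
            results.append(axial_resolution(AScan(pulse), self.SETTINGS).fwhm)
        assert np.ptp(results) / results[0] < 1e-6

    def test_printed_resolution_from_matching_impulse(self):
        # a transducer impulse whose envelope FWHM is 31.3 ns yields ~47 um
        fs = self.SETTINGS.sampling_rate
        sigma_t = 47e-6 / 1500.0 / GAUSSIAN_FWHM  # 13.3 ns
        pulse = gabor_pulse(80e6, sigma_t, fs, 2048)
        res = axial_resolution(AScan(pulse), self.SETTINGS)
        assert res.fwhm == pytest.approx(47e-6, rel=0.01)


class TestSnr:
    def test_forty_db_case(self):
        img = np.zeros((32, 32))
        img[4, 4] = 100.0
        img[16:, :] = np.where(np.indices((16, 32)).sum(axis=0) % 2 == 0, 1.0, -1.0)
        val = snr_db(img, (slice(0, 8), slice(0, 8)), (slice(16, 32), slice(None)))
        assert val == pytest.approx(40.0, abs=1e-6)

    def test_gain_invariance(self, rng):
        img = rng.normal(size=(32, 32))
        img[2, 2] = 50
        roi_s = (slice(0, 4), slice(0, 4))
        roi_n = (slice(16, 32), slice(None))
        assert snr_db(img, roi_s, roi_n) == pytest.approx(
            snr_db(7.3 * img, roi_s, roi_n)
        )

    def test_zero_noise_rejected(self):
        img = np.zeros((8, 8))
        img[0, 0] = 1
        with pytest.raises(ValueError):
            snr_db(img, (slice(0, 2), slice(0, 2)), (slice(4, 8), slice(4, 8)))

    def test_constructed_noise_level_recovered(self, rng):
        sigma = 0.05
        img = rng.normal(0, sigma, (256, 256))
        peak = 3.0
        img[10, 10] = peak
        val = snr_db(img, (slice(0, 20), slice(0, 20)), (slice(128, None), slice(None)))
        assert val == pytest.approx(20 * np.log10(peak / sigma), abs=0.5)


class TestVesselMask:
    def test_constant_image_rejected_for_otsu(self):
        with pytest.raises(ValueError):
            vessel_mask(np.ones((16, 16)), method="otsu")

    def test_fixed_threshold_identity_on_binary(self):
        img = (np.arange(64).reshape(8, 8) % 2).astype(float)
        mask = vessel_mask(img, method="fixed", threshold=0.5)
        assert np.array_equal(mask, img.astype(bool))


class TestVesselMetrics:
    def test_full_frame_mask(self):
        m = vessel_metrics(np.ones((64, 64), bool), 5e-6)
        assert m.vad == 1.0

    def test_disc_vci_near_unity(self):
        mask = np.zeros((256, 256), bool)
        rr, cc = disk((128, 128), 100)
        mask[rr, cc] = True
        m = vessel_metrics(mask, 5e-6)
        assert abs(m.vci - 1.0) < 0.05

    def test_vci_approaches_unity_with_radius(self):
        devs = []
        for r in (20, 60, 100):
            mask = np.zeros((2 * r + 40, 2 * r + 40), bool)
            rr, cc = disk((r + 20, r + 20), r)
            mask[rr, cc] = True
            devs.append(abs(vessel_metrics(mask, 1e-6).vci - 1.0))
        assert devs[2] <= devs[0]

    def test_straight_bar_diameter_and_skeleton(self):
        pixel = 5e-6
        mask = np.zeros((440, 60), bool)
        mask[20:420, 20:40] = True  # 400 x 20 px bar
        m = vessel_metrics(mask, pixel)
        assert m.vdi == pytest.approx(20 * pixel, rel=0.10)  # ~100 um
        expected_vsd = (400 * pixel) / (mask.size * pixel**2)
        assert m.vsd == pytest.approx(expected_vsd, rel=0.10)

    def test_identity_vdi_vsd_vad(self, rng):
        for _ in range(5):
            mask = rng.random((64, 64)) < 0.2
            from scipy import ndimage

            mask = ndimage.binary_dilation(mask, iterations=2)
            m = vessel_metrics(mask, 3e-6)
            assert m.vdi * m.vsd == pytest.approx(m.vad, rel=1e-12)

    def test_vad_rotation_invariance(self, rng):
        mask = rng.random((64, 64)) < 0.3
        a = vessel_metrics(mask, 1e-6).vad
        b = vessel_metrics(np.rot90(mask), 1e-6).vad
        assert a == b

    def test_empty_mask(self):
        m = vessel_metrics(np.zeros((16, 16), bool), 1e-6)
        assert m.vad == 0.0
        assert np.isnan(m.vdi) and np.isnan(m.vci)


class TestDiameterSplit:
    def _bar(self, width_px, shape=(64, 200)):
        mask = np.zeros(shape, bool)
        lo = shape[0] // 2 - width_px // 2
        mask[lo : lo + width_px, 10:-10] = True
        return mask

    def test_thin_bar_entirely_micro(self):
        mask = self._bar(10)  # 50 um at 5 um pixels
        macro, micro = diameter_split(mask, 5e-6)
        assert macro.sum() == 0
        assert micro.sum() == mask.sum()

    def test_wide_bar_entirely_macro(self):
        mask = self._bar(30)  # 150 um
        macro, micro = diameter_split(mask, 5e-6)
        assert micro.sum() == 0
        assert macro.sum() == mask.sum()

    def test_two_bar_partition(self):
        shape = (128, 200)
        mask = np.zeros(shape, bool)
        mask[20:32, 10:-10] = True  # 60 um bar (12 px)
        mask[70:102, 10:-10] = True  # 160 um bar (32 px)
        macro, micro = diameter_split(mask, 5e-6)
        micro_truth = np.zeros(shape, bool)
        micro_truth[20:32, 10:-10] = True
        mixing = np.logical_xor(micro, micro_truth).sum() / mask.sum()
        assert mixing <= 0.02


class TestTimeseries:
    def test_identical_frames(self):
        frame = np.zeros((64, 64))
        frame[20:40, 20:40] = 1.0
        fs = timeseries_quantify([frame] * 4, mask_method="fixed", fixed_threshold=0.5)
        assert np.allclose(fs.vessel_density, fs.vessel_density[0])
        assert np.allclose(fs.mean_amplitude_db, 0.0)

    def test_half_amplitude_is_minus_six_db(self):
        frame = np.zeros((64, 64))
        frame[20:40, 20:40] = 1.0
        fs = timeseries_quantify(
            [frame, 0.5 * frame], mask_method="fixed", fixed_threshold=0.1
        )
        assert fs.mean_amplitude_db[1] == pytest.approx(20 * np.log10(0.5), abs=1e-9)

    def test_constriction_sequence_density_drop(self):
        # bars shrunk to 40% width: recovered density drop within 5 points
        def frame(width):
            img = np.zeros((128, 128))
            for row in range(10, 128, 32):
                img[row : row + width, :] = 1.0
            return img

        frames = [frame(20), frame(14), frame(8)]
        fs = timeseries_quantify(frames, mask_method="fixed", fixed_threshold=0.5)
        drop = 1.0 - fs.vessel_density[-1] / fs.vessel_density[0]
        assert abs(drop - 0.6) < 0.05
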