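import numpy as np
import pytest

from spiralpam.klm import (
    BandMetrics,
    Layer,
    LayerStack,
    design_thickness,
    default_frequency_grid,
    extract_band_metrics,
    klm_two_way_response,
    tut_design_stack,
)
from spiralpam.materials import MATERIALS, MaterialSpec

from oracles import mason_input_impedance_unloaded, mason_transfer


def _random_plate(rng):
    d = rng.uniform(40e-6, 200e-6)
    v = rng.uniform(3500.0, 8000.0)
    rho = rng.uniform(2500.0, 8000.0)
    kt = rng.uniform(0.2, 0.6)
    eps = rng.uniform(10.0, 60.0)
    zb = rng.uniform(1e6, 10e6)
    return d, v, rho, kt, eps, zb


def _plate_stack(d, v, rho, kt, eps, zb):
    piezo = MaterialSpec("piezo", v, rho, kt=kt, clamped_permittivity=eps)
    backing = MaterialSpec("backing", 2000.0, zb / 2000.0)
    return LayerStack(
        piezo=piezo,
        piezo_thickness=d,
        area=36e-6,
        front_layers=(),
        backing=backing,
        front_load=MATERIALS["water"],
    )


class TestAgainstMasonOracle:
    def test_one_way_transfer_matches_mason_on_random_plates(self, rng):
        for _ in range(10):
            d, v, rho, kt, eps, zb = _random_plate(rng)
            f0 = v / (2 * d)
            f = np.linspace(0.05 * f0, 2.5 * f0, 900)
            resp = klm_two_way_response(_plate_stack(d, v, rho, kt, eps, zb), f)
            ht_mason, _ = mason_transfer(
                f, d, v, rho, kt, eps, 36e-6, z_front=1.48e6, z_back=zb
            )
            a = np.abs(resp.one_way)
            b = np.abs(ht_mason)
            peak_klm = f[np.argmax(a)]
            peak_mason = f[np.argmax(b)]
            assert abs(peak_klm - peak_mason) <= 0.01 * peak_mason
            assert np.max(np.abs(a / a.max() - b / b.max())) < 0.03

    def test_receive_is_reciprocal_scaling_of_transmit(self, rng):
        d, v, rho, kt, eps, zb = _random_plate(rng)
        f = np.linspace(1e6, 2.2 * v / (2 * d), 400)
        ht, hr = mason_transfer(f, d, v, rho, kt, eps, 36e-6, z_front=1.48e6, z_back=zb)
        zf = 1.48e6 * 36e-6
        assert np.allclose(hr, (2 * 50.0 / zf) * ht, rtol=1e-8)

    def test_input_impedance_closed_form_layerless_plate(self):
        # air on both faces: the KLM circuit must reduce to the textbook Zin
        d, v, rho, kt, eps = 94e-6, 7340.0, 4640.0, 0.49, 39.0
        f = np.linspace(5e6, 70e6, 200)
        ht, _ = mason_transfer(
            f, d, v, rho, kt, eps, 36e-6, z_front=413.0, z_back=413.0
        )
        z = mason_input_impedance_unloaded(f, d, v, rho, kt, eps, 36e-6)
        assert np.all(np.isfinite(z))
        # sanity: the unloaded plate's transfer is tiny into an air load
        assert np.max(np.abs(ht)) < 1e-3

    def test_bare_half_wave_plate_peaks_below_unloaded_resonance(self):
        d, v, rho, kt, eps = 94e-6, 7340.0, 4640.0, 0.49, 39.0
        f0 = v / (2 * d)
        f = np.linspace(2e6, 2.0 * f0, 1200)
        resp = klm_two_way_response(_plate_stack(d, v, rho, kt, eps, 413.0), f)
        ht_mason, _ = mason_transfer(
            f, d, v, rho, kt, eps, 36e-6, z_front=1.48e6, z_back=413.0
        )
        peak = f[np.argmax(np.abs(resp.one_way))]
        peak_oracle = f[np.argmax(np.abs(ht_mason))]
        assert peak < f0
        assert abs(peak - peak_oracle) <= 0.01 * peak_oracle


class TestDesignThickness:
    def test_quarter_wave_epoxy_matches_printed_layer(self):
        t = design_thickness(MATERIALS["epoxy"], "quarter_wave", 33.5e6)
        assert t == pytest.approx(19.8e-6, rel=1e-2)
        assert abs(t - 19e-6) / 19e-6 < 0.10  # within 10% of the printed 19 um

    def test_half_wave_is_twice_quarter_wave(self):
        m = MATERIALS["silica_epoxy_composite"]
        assert design_thickness(m, "half_wave", 40e6) == pytest.approx(
            2 * design_thickness(m, "quarter_wave", 40e6)
        )

    def test_inverting_half_wave_for_printed_lno_thickness(self):
        # t = v / (2 f) = 94 um -> unloaded thickness-mode estimate ~39 MHz
        f = MATERIALS["lno_36y"].longitudinal_velocity / (2 * 94e-6)
        assert f == pytest.approx(39.0e6, rel=0.02)

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            design_thickness(MATERIALS["epoxy"], "quarter_wave", -1.0)
        with pytest.raises(ValueError):
            design_thickness(MATERIALS["epoxy"], "third_wave", 1e6)


class TestBandMetrics:
    def test_gaussian_closed_form(self):
        f0, sigma = 35e6, 8e6
        f = np.linspace(0, 150e6, 20001)
        mag = np.exp(-((f - f0) ** 2) / (2 * sigma**2))
        bm = extract_band_metrics(f, mag)
        half_width = sigma * np.sqrt(0.6 * np.log(10.0))  # -6 dB half-width
        assert bm.center_frequency == pytest.approx(f0, rel=1e-6)
        assert bm.fractional_bandwidth == pytest.approx(2 * half_width / f0, rel=1e-4)

    def test_flat_top(self):
        a, b = 20e6, 60e6
        f = np.linspace(0, 100e6, 100001)
        mag = np.where((f >= a) & (f <= b), 1.0, 1e-6)
        bm = extract_band_metrics(f, mag)
        df = f[1] - f[0]
        assert bm.center_frequency == pytest.approx((a + b) / 2, abs=2 * df)
        assert bm.fractional_bandwidth == pytest.approx((b - a) / ((a + b) / 2), rel=1e-3)

    def test_never_crossed_raises(self):
        f = np.linspace(0, 1e6, 100)
        with pytest.raises(ValueError):
            extract_band_metrics(f, np.ones_like(f))

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            BandMetrics(10e6, 0.5, 20e6, 30e6)


class TestStackResponse:
    def test_design_stack_band_metrics(self):
        resp = klm_two_way_response(tut_design_stack())
        bm = extract_band_metrics(resp.frequencies, np.abs(resp.two_way))
        fc_mhz = bm.center_frequency / 1e6
        bw_pct = bm.fractional_bandwidth * 100
        assert 25.0 < fc_mhz < 45.0
        assert 40.0 < bw_pct < 100.0
        assert np.all(np.isfinite(resp.two_way))
        assert np.isfinite(np.sum(resp.waveform**2))  # finite pulse energy

    def test_two_way_proportional_to_one_way_squared(self):
        resp = klm_two_way_response(tut_design_stack())
        zf = MATERIALS["water"].acoustic_impedance * 36e-6
        assert np.allclose(resp.two_way, (2 * 50.0 / zf) * resp.one_way**2, rtol=1e-10)

    def test_thickness_scaling_shifts_band(self):
        stack = tut_design_stack()
        resp1 = klm_two_way_response(stack, default_frequency_grid(4096, 150e6))
        bm1 = extract_band_metrics(resp1.frequencies, np.abs(resp1.two_way))
        s = 2.0
        resp2 = klm_two_way_response(stack.scaled(s), default_frequency_grid(4096, 150e6 / s))
        bm2 = extract_band_metrics(resp2.frequencies, np.abs(resp2.two_way))
        assert bm2.center_frequency == pytest.approx(bm1.center_frequency / s, rel=5e-3)
        assert bm2.fractional_bandwidth == pytest.approx(bm1.fractional_bandwidth, rel=1e-2)

    def test_quarter_wave_matching_widens_band(self):
        matched = tut_design_stack()
        bare = LayerStack(
            piezo=matched.piezo,
            piezo_thickness=matched.piezo_thickness,
            area=matched.area,
            front_layers=(),
            backing=matched.backing,
            front_load=matched.front_load,
        )
        grid = default_frequency_grid()
        bm_matched = extract_band_metrics(
            grid, np.abs(klm_two_way_response(matched, grid).two_way)
        )
        bm_bare = extract_band_metrics(
            grid, np.abs(klm_two_way_response(bare, grid).two_way)
        )
        assert bm_matched.fractional_bandwidth > bm_bare.fractional_bandwidth

    def test_non_uniform_grid_rejected(self):
        f = np.concatenate([np.linspace(1e6, 50e6, 100), np.linspace(51e6, 150e6, 50)])
        with pytest.raises(ValueError):
            klm_two_way_response(tut_design_stack(), f)

    def test_zero_thickness_layer_rejected(self):
        with pytest.raises(ValueError):
            Layer(MATERIALS["epoxy"], 0.0)
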