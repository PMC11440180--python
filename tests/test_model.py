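"""Axes, Gaussian IRF and the analytic convolution forward model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from specflim import (
    ConfigurationError,
    DimensionError,
    DomainError,
    InstrumentModel,
    SpectralAxis,
    TimeAxis,
    make_gaussian_irf,
    model_cube_slice,
    model_decay,
)
from specflim.model import FWHM_TO_SIGMA

from conftest import simpson_convolution_oracle


class TestAxes:
    def test_time_axis_uniform_and_increasing(self):
        t = TimeAxis(n_bins=256, period_ns=12.5)
        centers = t.bin_centers_ns
        assert np.all(np.diff(centers) > 0)
        assert np.allclose(np.diff(centers), t.bin_width_ns, rtol=1e-12)
        assert centers.size == 256

    def test_time_axis_rejects_bad_inputs(self):
        with pytest.raises(ConfigurationError):
            TimeAxis(n_bins=8)
        with pytest.raises(ConfigurationError):
            TimeAxis(period_ns=0.0)

    def test_default_spectral_grid_spans_detector_range(self):
        s = SpectralAxis()
        assert s.n_channels == 16
        assert s.channel_centers_nm[0] == pytest.approx(388.1)
        assert s.channel_centers_nm[-1] == pytest.approx(573.6)
        assert np.all(np.diff(s.channel_centers_nm) > 0)

    def test_spectral_axis_rejects_unordered_centers(self):
        with pytest.raises(ConfigurationError):
            SpectralAxis(channel_centers_nm=np.array([500.0, 450.0]))

    def test_instrument_validates_irf_position(self):
        with pytest.raises(ConfigurationError):
            InstrumentModel(irf_t0_ns=13.0)
        with pytest.raises(ConfigurationError):
            InstrumentModel(irf_fwhm_ns=-0.1)

    def test_fwhm_to_sigma_conversion(self):
        # closed form: sigma = FWHM / (2 sqrt(2 ln 2)) = FWHM / 2.35482
        inst = InstrumentModel(irf_fwhm_ns=0.220)
        assert inst.irf_sigma_ns == pytest.approx(0.220 / 2.35482, abs=1e-6)
        assert inst.irf_sigma_ns == pytest.approx(0.0934, abs=1e-4)


class TestGaussianIRF:
    def test_normalized_and_centered(self, instrument):
        irf = make_gaussian_irf(instrument)
        assert irf.shape == (instrument.time.n_bins,)
        assert np.all(irf >= 0)
        assert irf.sum() == pytest.approx(1.0, abs=1e-9)
        peak_bin = int(np.argmax(irf))
        t0_bin = int(instrument.irf_t0_ns / instrument.time.bin_width_ns)
        assert peak_bin == t0_bin

    def test_translation_moves_irf_by_grid_shift(self):
        base = dict(time=TimeAxis(n_bins=250, period_ns=12.5))
        irf_a = make_gaussian_irf(InstrumentModel(irf_t0_ns=2.0, **base))
        irf_b = make_gaussian_irf(InstrumentModel(irf_t0_ns=3.0, **base))
        shift = int(round(1.0 / (12.5 / 250)))
        assert np.allclose(np.roll(irf_a, shift), irf_b, atol=1e-12)

    def test_unresolvable_irf_rejected(self):
        # sigma far below 1/50 of a bin width
        with pytest.raises(ConfigurationError):
            make_gaussian_irf(InstrumentModel(irf_fwhm_ns=1e-5))


class TestModelDecay:
    def test_delta_irf_limit_is_pure_exponential(self):
        inst = InstrumentModel(irf_fwhm_ns=1e-4 / FWHM_TO_SIGMA, wraparound=False)
        t = inst.time.bin_centers_ns
        m = model_decay([1.0], [1.0], inst)
        expected = np.where(t >= inst.irf_t0_ns, np.exp(-(t - inst.irf_t0_ns)), 0.0)
        assert np.max(np.abs(m - expected)) < 1e-6

    def test_matches_numeric_convolution_at_paper_irf(self):
        inst = InstrumentModel(wraparound=False)
        m = model_decay([1.0], [2.5], inst)
        oracle = simpson_convolution_oracle(2.5, inst.irf_sigma_ns, inst)
        assert np.max(np.abs(m - oracle)) / oracle.max() < 1e-4

    def test_matches_numeric_convolution_random_draws(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            tau = rng.uniform(0.2, 6.0)
            sigma = rng.uniform(0.05, 0.3)
            inst = InstrumentModel(irf_fwhm_ns=sigma / FWHM_TO_SIGMA, wraparound=False)
            m = model_decay([1.0], [tau], inst)
            oracle = simpson_convolution_oracle(tau, sigma, inst)
            assert np.max(np.abs(m - oracle)) / oracle.max() < 1e-4

    def test_linearity_in_amplitudes(self, instrument):
        m_a = model_decay([1.0], [0.8], instrument)
        m_b = model_decay([1.0], [3.0], instrument)
        m = model_decay([2.0, 3.0], [0.8, 3.0], instrument)
        assert np.allclose(m, 2 * m_a + 3 * m_b, rtol=1e-12)

    def test_rejects_invalid_parameters(self, instrument):
        with pytest.raises(DomainError):
            model_decay([1.0], [-0.5], instrument)
        with pytest.raises(DomainError):
            model_decay([-1.0], [1.0], instrument)
        with pytest.raises(DimensionError):
            model_decay([1.0, 2.0], [1.0], instrument)

    def test_no_overflow_for_tiny_lifetime(self, instrument):
        m = model_decay([1.0], [0.001], instrument)
        assert np.all(np.isfinite(m))

    @settings(max_examples=20, deadline=None)
    @given(
        tau=st.floats(0.3, 5.0),
        scale=st.floats(1.05, 1.5),
    )
    def test_centroid_increases_with_lifetime(self, tau, scale):
        inst = InstrumentModel(wraparound=False)
        t = inst.time.bin_centers_ns

        def centroid(tt):
            m = model_decay([1.0], [tt], inst)
            return float(np.dot(t, m) / m.sum())

        assert centroid(tau * scale) > centroid(tau)

    @pytest.mark.parametrize("tau", [0.37, 2.5, 5.0])
    @pytest.mark.parametrize("t0", [0.5, 1.25, 6.0])
    def test_wraparound_conserves_periodic_mass(self, tau, t0):
        # integrated over one period the wrapped model carries the full
        # steady-state mass tau (per unit amplitude), independent of t0
        inst = InstrumentModel(irf_t0_ns=t0, wraparound=True)
        m = model_decay([1.0], [tau], inst)
        mass = m.sum() * inst.time.bin_width_ns
        assert mass == pytest.approx(tau, rel=1e-6)


class TestModelCubeSlice:
    def test_channel_equals_model_decay(self, instrument):
        n_ch = instrument.spectral.n_channels
        amp = np.zeros((3, n_ch))
        amp[0, 4] = 1.0
        out = model_cube_slice(amp, [0.37, 2.5, 1.5], instrument)
        single = model_decay([1.0], [0.37], instrument)
        assert np.allclose(out[4], single, rtol=1e-12)
        assert np.allclose(out[[c for c in range(n_ch) if c != 4]], 0.0)

    def test_zero_flavin_component_reduces_to_two_components(self, instrument):
        rng = np.random.default_rng(0)
        n_ch = instrument.spectral.n_channels
        amp = rng.uniform(0.1, 1.0, size=(3, n_ch))
        amp[2] = 0.0
        out3 = model_cube_slice(amp, [0.37, 2.5, 1.5], instrument)
        out2 = model_cube_slice(amp[:2], [0.37, 2.5], instrument)
        assert np.allclose(out3, out2, rtol=1e-12)

    def test_channel_sum_equals_summed_amplitude_decay(self, instrument):
        rng = np.random.default_rng(1)
        amp = rng.uniform(0.0, 2.0, size=(3, instrument.spectral.n_channels))
        taus = [0.37, 2.5, 1.48]
        out = model_cube_slice(amp, taus, instrument)
        direct = model_decay(amp.sum(axis=1), taus, instrument)
        assert np.allclose(out.sum(axis=0), direct, rtol=1e-12)

    def test_shape_mismatch_raises(self, instrument):
        with pytest.raises(DimensionError):
            model_cube_slice(np.ones((3, 5)), [1.0, 2.0, 3.0], instrument)


class TestMeasuredIRF:
    def test_matches_analytic_path_for_gaussian_table(self, tmp_path, instrument):
        import pandas as pd

        from specflim import load_irf_csv, model_decay_measured_irf

        # tabulate the Gaussian IRF finely and feed it through the CSV path
        t_fine = np.arange(0.0, 12.5, 0.005)
        sigma = instrument.irf_sigma_ns
        dens = np.exp(-0.5 * ((t_fine - instrument.irf_t0_ns) / sigma) ** 2)
        path = tmp_path / "irf.csv"
        pd.DataFrame({"time_ns": t_fine, "weight": dens}).to_csv(path, index=False)
        weights = load_irf_csv(path, instrument.time)
        assert weights.sum() == pytest.approx(1.0, abs=1e-9)

        m_measured = model_decay_measured_irf(
            [1.0], [2.5], weights, instrument.time, wraparound=True
        )
        m_analytic = model_decay([1.0], [2.5], instrument)
        # the tabulated path works at bin resolution, so ~1% discretization
        # error on the IRF rising edge is expected
        assert np.max(np.abs(m_measured - m_analytic)) / m_analytic.max() < 2e-2

    def test_missing_columns_rejected(self, tmp_path, instrument):
        from specflim import load_irf_csv

        path = tmp_path / "bad.csv"
        path.write_text("a,b\n1,2\n")
        with pytest.raises(ConfigurationError):
            load_irf_csv(path, instrument.time)
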