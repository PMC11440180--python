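"""Constrained three-component global fitting and its derived descriptors."""

import numpy as np
import pytest

from specflim import (
    ComponentBasis,
    ConfigurationError,
    DomainError,
    GlobalFitOptions,
    InsufficientSignalError,
    SpectralAxis,
    fit_global,
    flavin_lambda_avg,
    model_cube_slice,
    nadh_mean_lifetime,
    normalize_amplitudes,
)

CONTROL = dict(ratio=2.7, tau_bound=2.5, flavin_fraction=0.12, tau_flavin=1.48)


def make_slice(instrument, basis, shapes, ratio, tau_bound, flavin_fraction,
               tau_flavin, total_photons):
    """Noiseless expected counts at the given generating parameters."""
    amp_bound = 1.0
    amp_free = ratio
    amp_fl = flavin_fraction * (amp_free + amp_bound) / (1.0 - flavin_fraction)
    amp = np.vstack(
        [amp_free * basis.free_spectrum, amp_bound * basis.bound_spectrum,
         amp_fl * shapes[2]]
    )
    slice_ = model_cube_slice(amp, [basis.tau_free_ns, tau_bound, tau_flavin], instrument)
    return slice_ * (total_photons / slice_.sum())


class TestNormalizeAmplitudes:
    def test_worked_arithmetic(self):
        a = np.array([2.0, 1.0, 0.5])
        b = np.array([1.0, 0.3, 0.2])
        c = np.array([0.0, 1.0, 0.6])
        assert normalize_amplitudes(a, b, c) == pytest.approx((0.5, 0.25, 0.25))

    def test_zero_flavins(self):
        f, b, fl = normalize_amplitudes([1.0], [1.0], [0.0])
        assert fl == 0.0
        assert f + b == pytest.approx(1.0)

    def test_sums_to_one_and_scale_invariant(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            s = rng.uniform(0, 5, size=(3, 16))
            triple = normalize_amplitudes(*s)
            assert sum(triple) == pytest.approx(1.0, abs=1e-12)
            scaled = normalize_amplitudes(*(7.3 * s))
            assert triple == pytest.approx(scaled, abs=1e-12)

    def test_all_zero_rejected(self):
        with pytest.raises(DomainError):
            normalize_amplitudes([0.0], [0.0], [0.0])


class TestNadhMeanLifetime:
    def test_control_scale_arithmetic(self):
        # ratio 2.7 with tau_free 0.37 and tau_bound 2.5 gives 0.946 ns
        tm = nadh_mean_lifetime(2.7, 1.0, 0.37, 2.5)
        assert tm == pytest.approx(0.9457, abs=5e-4)

    def test_pure_free_limit(self):
        assert nadh_mean_lifetime(1.0, 0.0, 0.37, 2.5) == pytest.approx(0.37)

    def test_equal_lifetimes_collapse(self):
        assert nadh_mean_lifetime(0.5, 0.5, 1.7, 1.7) == pytest.approx(1.7)


class TestFlavinLambdaAvg:
    def test_point_mass(self):
        axis = SpectralAxis()
        s = np.zeros(16)
        idx = int(np.argmin(np.abs(axis.channel_centers_nm - 535)))
        s[idx] = 3.0
        assert flavin_lambda_avg(s, axis) == pytest.approx(
            axis.channel_centers_nm[idx]
        )

    def test_symmetric_spectrum_returns_center(self):
        axis = SpectralAxis(channel_centers_nm=np.linspace(500, 560, 7))
        s = np.array([1, 2, 3, 4, 3, 2, 1.0])
        assert flavin_lambda_avg(s, axis) == pytest.approx(530.0)

    def test_translation_on_uniform_grid(self):
        axis = SpectralAxis()
        spacing = np.diff(axis.channel_centers_nm)[0]
        s = np.zeros(16)
        s[9:13] = [1.0, 3.0, 2.0, 0.5]
        shifted = np.roll(s, 1)
        assert flavin_lambda_avg(shifted, axis) - flavin_lambda_avg(s, axis) == (
            pytest.approx(spacing)
        )

    def test_zero_spectrum_is_missing(self):
        assert np.isnan(flavin_lambda_avg(np.zeros(16), SpectralAxis()))


class TestFitGlobal:
    def test_noiseless_inversion_at_control_medians(
        self, instrument, basis, component_shapes
    ):
        slice_ = make_slice(
            instrument, basis, component_shapes,
            CONTROL["ratio"], CONTROL["tau_bound"], CONTROL["flavin_fraction"],
            CONTROL["tau_flavin"], 5e5,
        )
        fit = fit_global(slice_, instrument, basis)
        assert fit.ratio_free_bound == pytest.approx(CONTROL["ratio"], rel=0.01)
        assert fit.tau_bound_ns == pytest.approx(CONTROL["tau_bound"], rel=0.01)
        assert fit.tau_flavin_ns == pytest.approx(CONTROL["tau_flavin"], rel=0.01)
        assert fit.a_flavins == pytest.approx(CONTROL["flavin_fraction"], rel=0.01)
        assert fit.converged

    def test_result_invariants(self, instrument, basis, component_shapes):
        slice_ = make_slice(
            instrument, basis, component_shapes, 2.0, 2.2, 0.10, 1.6, 3e5
        )
        fit = fit_global(slice_, instrument, basis)
        assert fit.a_free + fit.a_bound + fit.a_flavins == pytest.approx(1.0, abs=1e-9)
        lam = instrument.spectral.channel_centers_nm
        assert np.all(fit.flavin_spectrum[lam < basis.flavin_zero_below_nm] == 0.0)
        assert basis.tau_bound_bounds_ns[0] <= fit.tau_bound_ns <= basis.tau_bound_bounds_ns[1]
        assert fit.A1 == pytest.approx(fit.amp_free)
        assert fit.A2 == pytest.approx(fit.amp_bound)
        assert fit.A3 == pytest.approx(fit.flavin_spectrum.max())

    def test_null_flavin_component_recovered_as_zero(
        self, instrument, basis, component_shapes
    ):
        slice_ = make_slice(
            instrument, basis, component_shapes, 2.7, 2.5, 0.0, 1.48, 5e5
        )
        fit = fit_global(slice_, instrument, basis)
        assert fit.a_flavins < 0.02
        assert fit.ratio_free_bound == pytest.approx(2.7, rel=0.02)

    def test_poisson_recovery_at_cell_photon_counts(
        self, instrument, basis, component_shapes
    ):
        expected = make_slice(
            instrument, basis, component_shapes,
            CONTROL["ratio"], CONTROL["tau_bound"], CONTROL["flavin_fraction"],
            CONTROL["tau_flavin"], 5e5,
        )
        rng = np.random.default_rng(3)
        taus, ratios, fls = [], [], []
        for _ in range(10):
            fit = fit_global(rng.poisson(expected), instrument, basis)
            taus.append(fit.tau_bound_ns)
            ratios.append(fit.ratio_free_bound)
            fls.append(fit.a_flavins)
        assert np.median(taus) == pytest.approx(CONTROL["tau_bound"], rel=0.05)
        assert np.median(ratios) == pytest.approx(CONTROL["ratio"], rel=0.10)
        assert np.median(fls) == pytest.approx(CONTROL["flavin_fraction"], rel=0.15)

    def test_flavin_fraction_identifiable_across_sweep(
        self, instrument, basis, component_shapes
    ):
        rng = np.random.default_rng(5)
        truth = np.linspace(0.05, 0.30, 10)
        recovered = []
        for phi in truth:
            expected = make_slice(
                instrument, basis, component_shapes, 2.7, 2.5, phi, 1.48, 2e5
            )
            fit = fit_global(rng.poisson(expected), instrument, basis)
            recovered.append(fit.a_flavins)
        r = np.corrcoef(truth, recovered)[0, 1]
        assert r > 0.95

    def test_lambda_avg_monotone_in_flavin_fraction(
        self, instrument, basis, component_shapes
    ):
        lam = instrument.spectral.channel_centers_nm
        lam_avgs = []
        for phi in np.linspace(0.0, 0.4, 9):
            slice_ = make_slice(
                instrument, basis, component_shapes, 2.7, 2.5, phi, 1.48, 1e6
            )
            intensity = slice_.sum(axis=1)
            lam_avgs.append(np.dot(lam, intensity) / intensity.sum())
        assert np.all(np.diff(lam_avgs) > 0)

    def test_zero_flavin_agrees_with_two_component_fit(
        self, instrument, basis, component_shapes
    ):
        expected = make_slice(
            instrument, basis, component_shapes, 2.7, 2.5, 0.0, 1.48, 5e5
        )
        rng = np.random.default_rng(9)
        k = rng.poisson(expected)
        fit3 = fit_global(k, instrument, basis)
        # two-component fit: flavins disabled via a cutoff beyond the grid
        basis2 = ComponentBasis(
            free_spectrum=basis.free_spectrum,
            bound_spectrum=basis.bound_spectrum,
            flavin_zero_below_nm=1000.0,
        )
        fit2 = fit_global(k, instrument, basis2)
        assert fit3.tau_bound_ns == pytest.approx(fit2.tau_bound_ns, abs=0.1)
        assert fit3.ratio_free_bound == pytest.approx(fit2.ratio_free_bound, rel=0.05)

    def test_insufficient_photons_rejected(self, instrument, basis):
        k = np.full((instrument.spectral.n_channels, instrument.time.n_bins), 0.1)
        with pytest.raises(InsufficientSignalError):
            fit_global(k, instrument, basis)

    def test_channel_mismatch_rejected(self, instrument, basis):
        k = np.ones((4, instrument.time.n_bins)) * 1e3
        with pytest.raises(Exception):
            fit_global(k, instrument, basis)

    def test_at_bound_flagging(self, instrument, component_shapes):
        # data generated at tau_bound = 2.5 but fitted with a box whose
        # upper end is below it must come back flagged at-bound
        narrow = ComponentBasis(
            free_spectrum=component_shapes[0],
            bound_spectrum=component_shapes[1],
            tau_bound_bounds_ns=(0.5, 1.5),
        )
        wide = ComponentBasis(
            free_spectrum=component_shapes[0],
            bound_spectrum=component_shapes[1],
        )
        slice_ = make_slice(
            instrument, wide, component_shapes, 2.7, 2.5, 0.12, 1.48, 3e5
        )
        fit = fit_global(slice_, instrument, narrow)
        assert "tau_bound" in fit.at_bound


class TestComponentBasis:
    def test_validates_normalization(self):
        with pytest.raises(ConfigurationError):
            ComponentBasis(
                free_spectrum=np.full(16, 0.5), bound_spectrum=np.ones(16)
            )

    def test_default_basis_matches_axis(self, instrument):
        b = ComponentBasis.default(instrument.spectral)
        assert b.n_channels == 16
        assert b.free_spectrum.max() == pytest.approx(1.0)
        assert b.tau_free_ns == 0.37
        lam = instrument.spectral.channel_centers_nm
        # free peaks redder than bound
        assert lam[np.argmax(b.free_spectrum)] > lam[np.argmax(b.bound_spectrum)]
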