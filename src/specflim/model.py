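"""Axes, instrument response and the IRF-convolved multi-exponential decay model.

A TCSPC measurement histograms photon arrival times into ``n_bins`` bins
spanning one laser period (12.5 ns at 80 MHz).  The measured decay is the
molecular multi-exponential decay convolved with the instrument response
function (IRF), modelled here as a Gaussian of given FWHM.  For a Gaussian
IRF the convolution with ``exp(-t/tau)`` has the exponentially-modified-
Gaussian closed form

    f(t) = 1/2 * exp(sigma^2/(2 tau^2) - (t - t0)/tau)
               * erfc((sigma/tau - (t - t0)/sigma) / sqrt(2)),

which this module evaluates in an overflow-safe way and uses as the basis
curve for all fitting.  At high repetition rates a long-lived decay does not
finish within one period; the tail of the previous pulse adds the geometric
factor exp(-T/tau) / (1 - exp(-T/tau)) applied to the exponential part
("incomplete decay" / wrap-around correction, enabled by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import erfc, erfcx, ndtr

from .exceptions import ConfigurationError, DimensionError, DomainError

__all__ = [
    "TimeAxis",
    "SpectralAxis",
    "InstrumentModel",
    "DecayCurve",
    "SpectralTemporalCube",
    "make_gaussian_irf",
    "load_irf_csv",
    "model_decay",
    "model_decay_measured_irf",
    "model_cube_slice",
    "FWHM_TO_SIGMA",
]

#: Conversion factor between Gaussian FWHM and standard deviation.
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

# Default spectral grid of the 16-channel PMT: first/last channel centers.
DEFAULT_LAMBDA_MIN_NM = 388.1
DEFAULT_LAMBDA_MAX_NM = 573.6
DEFAULT_N_CHANNELS = 16
DEFAULT_BANDWIDTH_NM = 12.5

_EXP_CLIP = 700.0  # exp argument beyond which float64 overflows


@dataclass(frozen=True)
class TimeAxis:
    """Uniform TCSPC time binning over one laser period.

    Parameters
    ----------
    n_bins
        Number of ADC time bins (>= 16).
    period_ns
        Laser repetition period in ns; 12.5 ns corresponds to 80 MHz.
    """

    n_bins: int = 256
    period_ns: float = 12.5

    def __post_init__(self) -> None:
        if self.n_bins < 16:
            raise ConfigurationError(f"n_bins must be >= 16, got {self.n_bins}")
        if not self.period_ns > 0:
            raise ConfigurationError(f"period_ns must be > 0, got {self.period_ns}")

    @property
    def bin_width_ns(self) -> float:
        return self.period_ns / self.n_bins

    @property
    def bin_centers_ns(self) -> np.ndarray:
        return (np.arange(self.n_bins) + 0.5) * self.bin_width_ns

    @property
    def bin_edges_ns(self) -> np.ndarray:
        return np.arange(self.n_bins + 1) * self.bin_width_ns


@dataclass(frozen=True)
class SpectralAxis:
    """Emission-wavelength channels of the multi-anode spectral detector."""

    channel_centers_nm: np.ndarray = field(
        default_factory=lambda: np.linspace(
            DEFAULT_LAMBDA_MIN_NM, DEFAULT_LAMBDA_MAX_NM, DEFAULT_N_CHANNELS
        )
    )
    bandwidth_nm: float = DEFAULT_BANDWIDTH_NM

    def __post_init__(self) -> None:
        centers = np.asarray(self.channel_centers_nm, dtype=float)
        object.__setattr__(self, "channel_centers_nm", centers)
        if centers.ndim != 1 or centers.size < 1:
            raise ConfigurationError("channel_centers_nm must be a 1-D sequence")
        if centers.size > 1 and not np.all(np.diff(centers) > 0):
            raise ConfigurationError("channel_centers_nm must be strictly increasing")

    @property
    def n_channels(self) -> int:
        return int(self.channel_centers_nm.size)


@dataclass(frozen=True)
class InstrumentModel:
    """Complete acquisition geometry: time axis, spectral axis and IRF.

    The IRF is a Gaussian of ``irf_fwhm_ns`` FWHM centered at ``irf_t0_ns``
    on the time axis.  ``wraparound`` enables the previous-pulse
    (incomplete-decay) correction; at 80 MHz the tail of a several-ns
    component wraps into the next period, so it is on by default.
    """

    time: TimeAxis = field(default_factory=TimeAxis)
    spectral: SpectralAxis = field(default_factory=SpectralAxis)
    irf_fwhm_ns: float = 0.220
    irf_t0_ns: float | None = None
    wraparound: bool = True

    def __post_init__(self) -> None:
        if self.irf_t0_ns is None:
            # default IRF position: 10% of the period into the window
            object.__setattr__(self, "irf_t0_ns", 0.1 * self.time.period_ns)
        if not self.irf_fwhm_ns > 0:
            raise ConfigurationError(f"irf_fwhm_ns must be > 0, got {self.irf_fwhm_ns}")
        if not 0 <= self.irf_t0_ns < self.time.period_ns:
            raise ConfigurationError(
                f"irf_t0_ns must lie in [0, period), got {self.irf_t0_ns}"
            )

    @property
    def irf_sigma_ns(self) -> float:
        return self.irf_fwhm_ns * FWHM_TO_SIGMA


@dataclass
class DecayCurve:
    """Photon-count histogram of a single decay."""

    counts: np.ndarray
    time: TimeAxis

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 1 or self.counts.size != self.time.n_bins:
            raise DimensionError(
                f"counts length {self.counts.size} != n_bins {self.time.n_bins}"
            )
        if np.any(self.counts < 0):
            raise DomainError("counts must be non-negative")

    @property
    def total_photons(self) -> float:
        return float(self.counts.sum())


@dataclass
class SpectralTemporalCube:
    """4-D photon-count histogram (rows, cols, channel, time bin)."""

    counts: np.ndarray
    instrument: InstrumentModel
    pixel_size_um: float = 1.0
    provenance: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 4:
            raise DimensionError(f"counts must be 4-D, got ndim={counts.ndim}")
        n_ch = self.instrument.spectral.n_channels
        n_t = self.instrument.time.n_bins
        if counts.shape[2] != n_ch or counts.shape[3] != n_t:
            raise DimensionError(
                f"cube shape {counts.shape} inconsistent with axes "
                f"({n_ch} channels, {n_t} bins)"
            )
        if np.any(counts < 0):
            raise DomainError("cube counts must be non-negative")
        self.counts = counts

    @property
    def shape(self) -> tuple[int, ...]:
        return self.counts.shape

    def pixel_decays(self, row: int, col: int) -> np.ndarray:
        """Per-channel decay histograms at one pixel, shape (n_channels, n_bins)."""
        return np.asarray(self.counts[row, col], dtype=float)


def make_gaussian_irf(instrument: InstrumentModel) -> np.ndarray:
    """Per-bin IRF weights: the Gaussian density integrated over each time bin.

    Returns a length-``n_bins`` non-negative array summing to 1.  Raises
    :class:`ConfigurationError` if the Gaussian is narrower than 1/50 of a
    bin and therefore unresolvable on the grid.
    """
    sigma = instrument.irf_sigma_ns
    time = instrument.time
    if sigma < time.bin_width_ns / 50.0:
        raise ConfigurationError(
            f"IRF sigma {sigma:.3g} ns unresolvable on {time.bin_width_ns:.3g} ns bins"
        )
    z = (time.bin_edges_ns - instrument.irf_t0_ns) / sigma
    weights = np.diff(ndtr(z))
    total = weights.sum()
    if total <= 0:
        raise ConfigurationError("IRF has no mass inside the measurement window")
    return weights / total


def load_irf_csv(path, time: TimeAxis) -> np.ndarray:
    """Read a measured IRF (CSV columns ``time_ns, weight``) onto a time axis.

    The tabulated response is linearly interpolated at the bin centers,
    clipped to non-negative values and normalized to unit sum, so it can be
    used directly by :func:`model_decay_measured_irf` in place of the
    Gaussian model.
    """
    import pandas as pd

    table = pd.read_csv(path)
    missing = {"time_ns", "weight"} - set(table.columns)
    if missing:
        raise ConfigurationError(f"IRF CSV missing columns: {sorted(missing)}")
    weights = np.interp(
        time.bin_centers_ns, table["time_ns"].to_numpy(), table["weight"].to_numpy(),
        left=0.0, right=0.0,
    )
    weights = np.clip(weights, 0.0, None)
    total = weights.sum()
    if total <= 0:
        raise ConfigurationError("measured IRF has no mass on the time axis")
    return weights / total


def model_decay_measured_irf(
    amplitudes: Sequence[float],
    lifetimes: Sequence[float],
    irf_weights: np.ndarray,
    time: TimeAxis,
    wraparound: bool = True,
) -> np.ndarray:
    """Multi-exponential decay convolved with a tabulated (measured) IRF.

    The convolution is circular over the laser period, which is the
    physically correct treatment for periodic excitation; with
    ``wraparound`` disabled the linear convolution is used instead.  The
    exponential is integrated exactly over each bin (value given as mean
    density per bin) so the result matches the analytic Gaussian path when
    ``irf_weights`` samples a Gaussian.
    """
    amplitudes = np.atleast_1d(np.asarray(amplitudes, dtype=float))
    lifetimes = np.atleast_1d(np.asarray(lifetimes, dtype=float))
    if amplitudes.shape != lifetimes.shape or amplitudes.size < 1:
        raise DimensionError("amplitudes and lifetimes must have equal nonzero length")
    if np.any(lifetimes <= 0):
        raise DomainError("lifetimes must be positive")
    irf = np.asarray(irf_weights, dtype=float)
    if irf.shape != (time.n_bins,):
        raise DimensionError("irf_weights length must equal n_bins")
    dt = time.bin_width_ns
    out = np.zeros(time.n_bins)
    lags = np.arange(time.n_bins)
    for a, tau in zip(amplitudes, lifetimes):
        if a == 0:
            continue
        # exponential panel means centered on the lag grid (half-open panel
        # at lag 0 holds the truncation at t = 0), so that convolving two
        # bin-center-aligned sequences stays bin-center aligned
        upper = np.exp(-np.minimum((lags + 0.5) * dt, np.inf) / tau)
        lower = np.exp(-np.maximum(lags - 0.5, 0.0) * dt / tau)
        e = (lower - upper) * tau / dt
        if wraparound:
            e = e / (1.0 - np.exp(-time.period_ns / tau))
            conv = np.real(np.fft.ifft(np.fft.fft(irf) * np.fft.fft(e)))
        else:
            conv = np.convolve(irf, e)[: time.n_bins]
        out += a * conv
    return out


def _exgauss_component(
    t: np.ndarray,
    tau: float,
    sigma: float,
    t0: float,
    period_ns: float | None,
) -> np.ndarray:
    """Unit-amplitude Gaussian(sigma) x exp(-t/tau) convolution at times ``t``.

    Evaluated as 0.5*erfcx(z)*exp(-u^2/(2 sigma^2)) where the argument
    z = (sigma/tau - u/sigma)/sqrt(2) is non-negative, and as
    0.5*exp(sigma^2/(2 tau^2) - u/tau)*erfc(z) otherwise; the two forms are
    identical but each is overflow-free in its branch.  If ``period_ns`` is
    given, the previous-pulse tail is added.
    """
    if not tau > 0:
        raise DomainError(f"lifetime must be > 0, got {tau}")
    if not sigma > 0:
        raise DomainError(f"IRF sigma must be > 0, got {sigma}")
    u = t - t0
    z = (sigma / tau - u / sigma) / np.sqrt(2.0)
    out = np.empty_like(u)
    pos = z >= 0
    if np.any(pos):
        up = u[pos]
        out[pos] = 0.5 * erfcx(z[pos]) * np.exp(-(up * up) / (2.0 * sigma * sigma))
    if np.any(~pos):
        arg = sigma * sigma / (2.0 * tau * tau) - u[~pos] / tau
        out[~pos] = 0.5 * np.exp(np.minimum(arg, _EXP_CLIP)) * erfc(z[~pos])
    if period_ns is not None:
        # previous-pulse (incomplete decay) tail: the exGaussian far past t0
        # is exp(sigma^2/2tau^2)*exp(-u/tau); summing over all earlier pulses
        # multiplies it by the geometric factor below.
        g = np.exp(-period_ns / tau)
        factor = g / (1.0 - g)
        arg = sigma * sigma / (2.0 * tau * tau) - u / tau
        out = out + factor * np.exp(np.minimum(arg, _EXP_CLIP))
    return out


def model_decay(
    amplitudes: Sequence[float],
    lifetimes: Sequence[float],
    instrument: InstrumentModel,
) -> np.ndarray:
    """IRF-convolved sum of exponentials evaluated at the bin centers.

    ``amplitudes[i]`` multiplies the pre-convolution decay
    ``exp(-t/lifetimes[i])``; the returned curve is in expected counts per
    bin up to the common bin-width factor (amplitudes carry the scale).
    """
    amplitudes = np.atleast_1d(np.asarray(amplitudes, dtype=float))
    lifetimes = np.atleast_1d(np.asarray(lifetimes, dtype=float))
    if amplitudes.shape != lifetimes.shape or amplitudes.size < 1:
        raise DimensionError("amplitudes and lifetimes must have equal nonzero length")
    if np.any(amplitudes < 0):
        raise DomainError("amplitudes must be non-negative")
    if np.any(lifetimes <= 0):
        raise DomainError("lifetimes must be positive")
    t = instrument.time.bin_centers_ns
    period = instrument.time.period_ns if instrument.wraparound else None
    out = np.zeros_like(t)
    for a, tau in zip(amplitudes, lifetimes):
        if a == 0:
            continue
        out += a * _exgauss_component(
            t, float(tau), instrument.irf_sigma_ns, instrument.irf_t0_ns, period
        )
    return out


def model_cube_slice(
    amplitude_spectra: np.ndarray,
    lifetimes: Sequence[float],
    instrument: InstrumentModel,
) -> np.ndarray:
    """Per-channel model decays for components with wavelength-dependent amplitudes.

    Parameters
    ----------
    amplitude_spectra
        Array of shape ``(n_components, n_channels)``; entry ``[i, c]`` is
        the amplitude of component ``i`` in spectral channel ``c``.
    lifetimes
        Shared lifetimes, one per component.

    Returns
    -------
    Array of shape ``(n_channels, n_bins)``.
    """
    amplitude_spectra = np.atleast_2d(np.asarray(amplitude_spectra, dtype=float))
    lifetimes = np.atleast_1d(np.asarray(lifetimes, dtype=float))
    n_comp, n_ch = amplitude_spectra.shape
    if lifetimes.size != n_comp:
        raise DimensionError(
            f"{n_comp} amplitude rows but {lifetimes.size} lifetimes"
        )
    if n_ch != instrument.spectral.n_channels:
        raise DimensionError(
            f"{n_ch} amplitude columns but spectral axis has "
            f"{instrument.spectral.n_channels} channels"
        )
    if np.any(amplitude_spectra < 0):
        raise DomainError("amplitudes must be non-negative")
    if np.any(lifetimes <= 0):
        raise DomainError("lifetimes must be positive")
    t = instrument.time.bin_centers_ns
    period = instrument.time.period_ns if instrument.wraparound else None
    curves = np.stack(
        [
            _exgauss_component(
                t, float(tau), instrument.irf_sigma_ns, instrument.irf_t0_ns, period
            )
            for tau in lifetimes
        ]
    )
    return amplitude_spectra.T @ curves
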