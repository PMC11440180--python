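"""Global three-component spectral-temporal decay unmixing.

All spectral channels of a decay set are fitted simultaneously with three
components — free NAD(P)H, bound NAD(P)H and flavins — whose lifetimes are
shared across channels:

    F(lambda, t) ~ IRF(t) (x) [ a1(lambda) e^{-t/tau1}
                              + a2(lambda) e^{-t/tau2}
                              + a3(lambda) e^{-t/tau3} ].

Constraints: the free and bound NAD(P)H spectral shapes are fixed
(max-normalized reference spectra) with only their overall amplitudes free;
tau_free = 0.37 ns is fixed; tau_bound is bounded in [0.5, 10] ns; the
flavin spectrum a3(lambda) is free per channel but identically zero below
490 nm; all amplitudes are non-negative.

Derived descriptors: with A_i the channel-maximum of component i, the
normalized contributions are a_i = A_i / (A1 + A2 + A3); the NAD(P)H mean
lifetime is tau_m = (a_free*tau_free + a_bound*tau_bound)/(a_free+a_bound);
the flavin emission position is its intensity-weighted mean wavelength.

Optimization is separable: at fixed lifetimes the model is linear in all
amplitudes and is solved by non-negative least squares; a Nelder-Mead
search (with a multi-start grid) runs over the two free lifetimes; a final
joint L-BFGS-B refinement polishes all parameters under the Poisson
maximum-likelihood objective.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy import optimize

from .exceptions import (
    ConfigurationError,
    DimensionError,
    DomainError,
    InsufficientSignalError,
)
from .model import InstrumentModel, SpectralAxis, _exgauss_component
from .perchannel import _pearson_chi2_reduced, _poisson_deviance, _wls_objective
from .spectra import load_reference_spectra, resample_spectrum

__all__ = [
    "ComponentBasis",
    "GlobalFitOptions",
    "GlobalFitResult",
    "fit_global",
    "normalize_amplitudes",
    "nadh_mean_lifetime",
    "flavin_lambda_avg",
]

logger = logging.getLogger(__name__)

TAU_FREE_NS = 0.37  # fixed free-NAD(P)H lifetime
FLAVIN_CUTOFF_NM = 490.0


@dataclass(frozen=True)
class ComponentBasis:
    """Fixed spectral shapes and lifetime constraints for the three components."""

    free_spectrum: np.ndarray
    bound_spectrum: np.ndarray
    tau_free_ns: float = TAU_FREE_NS
    tau_bound_bounds_ns: tuple[float, float] = (0.5, 10.0)
    tau_flavin_bounds_ns: tuple[float, float] = (0.3, 6.0)
    flavin_zero_below_nm: float = FLAVIN_CUTOFF_NM

    def __post_init__(self) -> None:
        for name in ("free_spectrum", "bound_spectrum"):
            s = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, s)
            if s.ndim != 1 or s.size < 1:
                raise ConfigurationError(f"{name} must be a 1-D array")
            if np.any(s < 0):
                raise ConfigurationError(f"{name} must be non-negative")
            if not np.isclose(s.max(), 1.0):
                raise ConfigurationError(f"{name} must be max-normalized to 1")
        if self.free_spectrum.size != self.bound_spectrum.size:
            raise ConfigurationError("free and bound spectra differ in length")
        for name in ("tau_bound_bounds_ns", "tau_flavin_bounds_ns"):
            lo, hi = getattr(self, name)
            if not (0 < lo < hi):
                raise ConfigurationError(f"{name} must satisfy 0 < lo < hi")
        if not self.tau_free_ns > 0:
            raise ConfigurationError("tau_free_ns must be positive")

    @property
    def n_channels(self) -> int:
        return int(self.free_spectrum.size)

    def flavin_channel_mask(self, spectral: SpectralAxis) -> np.ndarray:
        """Boolean mask of channels where the flavin amplitude may be nonzero."""
        return spectral.channel_centers_nm >= self.flavin_zero_below_nm

    @classmethod
    def from_spectra_table(cls, table, spectral: SpectralAxis, **kwargs) -> "ComponentBasis":
        """Build a basis from a reference-spectra table (see :mod:`specflim.spectra`)."""
        lam = table["wavelength_nm"].to_numpy()
        return cls(
            free_spectrum=resample_spectrum(lam, table["free_nadh"].to_numpy(), spectral),
            bound_spectrum=resample_spectrum(lam, table["bound_nadh"].to_numpy(), spectral),
            **kwargs,
        )

    @classmethod
    def from_csv(cls, path, spectral: SpectralAxis, **kwargs) -> "ComponentBasis":
        return cls.from_spectra_table(load_reference_spectra(path), spectral, **kwargs)

    @classmethod
    def default(cls, spectral: SpectralAxis, **kwargs) -> "ComponentBasis":
        """Basis from the packaged free/bound NAD(P)H reference spectra."""
        ref = resources.files("specflim.data").joinpath("reference_spectra.csv")
        with resources.as_file(ref) as path:
            return cls.from_csv(path, spectral, **kwargs)


@dataclass(frozen=True)
class GlobalFitOptions:
    """Options for the global three-component fit."""

    objective: str = "mle"
    min_photons_global: float = 2000.0
    multistart: bool = True
    fit_t0: bool = False
    init_tau_bound_ns: float = 2.0
    init_tau_flavin_ns: float = 2.0
    tau_bound_starts_ns: tuple[float, ...] = (1.0, 2.0, 3.5)
    tau_flavin_starts_ns: tuple[float, ...] = (0.8, 1.5, 3.0)

    def __post_init__(self) -> None:
        if self.objective not in ("mle", "wls"):
            raise DomainError(f"objective must be 'mle' or 'wls', got {self.objective!r}")


@dataclass(frozen=True)
class GlobalFitResult:
    """Result of the constrained three-component global fit."""

    amp_free: float
    amp_bound: float
    flavin_spectrum: np.ndarray
    tau_bound_ns: float
    tau_flavin_ns: float
    A1: float
    A2: float
    A3: float
    a_free: float
    a_bound: float
    a_flavins: float
    ratio_free_bound: float
    tau_m_nadh_ns: float
    lambda_avg_flavin_nm: float
    chi2_reduced: float
    n_photons: float
    converged: bool
    at_bound: tuple[str, ...] = ()
    message: str = ""


def normalize_amplitudes(
    a1_spectrum: np.ndarray,
    a2_spectrum: np.ndarray,
    a3_spectrum: np.ndarray,
) -> tuple[float, float, float]:
    """Normalized component contributions from the per-channel amplitude spectra.

    Each component is summarized by its channel maximum A_i; the returned
    triple is A_i / (A1 + A2 + A3), which sums to 1 and is invariant to a
    common rescaling of the spectra.
    """
    maxima = []
    for s in (a1_spectrum, a2_spectrum, a3_spectrum):
        s = np.asarray(s, dtype=float)
        if np.any(s < 0):
            raise DomainError("amplitude spectra must be non-negative")
        maxima.append(s.max() if s.size else 0.0)
    total = sum(maxima)
    if total <= 0:
        raise DomainError("all component spectra are zero")
    return tuple(m / total for m in maxima)  # type: ignore[return-value]


def nadh_mean_lifetime(
    a_free: float, a_bound: float, tau_free_ns: float, tau_bound_ns: float
) -> float:
    """Mean NAD(P)H lifetime, excluding the flavin component."""
    if a_free < 0 or a_bound < 0:
        raise DomainError("amplitudes must be non-negative")
    if a_free + a_bound <= 0:
        raise DomainError("NAD(P)H amplitude sum must be positive")
    return (a_free * tau_free_ns + a_bound * tau_bound_ns) / (a_free + a_bound)


def flavin_lambda_avg(flavin_spectrum: np.ndarray, spectral: SpectralAxis) -> float:
    """Intensity-weighted mean emission wavelength of the flavin component.

    Returns NaN for an all-zero spectrum (undefined).
    """
    s = np.asarray(flavin_spectrum, dtype=float)
    if s.size != spectral.n_channels:
        raise DimensionError("spectrum length does not match the spectral axis")
    if np.any(s < 0):
        raise DomainError("spectrum must be non-negative")
    total = s.sum()
    if total <= 0:
        return float("nan")
    return float(np.dot(spectral.channel_centers_nm, s) / total)


def _stack_basis(basis: ComponentBasis, instrument: InstrumentModel, tau_bound, tau_flavin, t0=None):
    """Component time curves (3, n_bins) at the given lifetimes."""
    t = instrument.time.bin_centers_ns
    sigma = instrument.irf_sigma_ns
    t0 = instrument.irf_t0_ns if t0 is None else t0
    period = instrument.time.period_ns if instrument.wraparound else None
    return np.stack(
        [
            _exgauss_component(t, basis.tau_free_ns, sigma, t0, period),
            _exgauss_component(t, float(tau_bound), sigma, t0, period),
            _exgauss_component(t, float(tau_flavin), sigma, t0, period),
        ]
    )


def _expected(
    amp_free: float,
    amp_bound: float,
    a3: np.ndarray,
    curves: np.ndarray,
    basis: ComponentBasis,
) -> np.ndarray:
    """Model counts (n_channels, n_bins) from amplitudes and time curves."""
    spectra = np.vstack(
        [amp_free * basis.free_spectrum, amp_bound * basis.bound_spectrum, a3]
    )
    return spectra.T @ curves


def _profile_amplitudes(k, curves, basis, flavin_mask):
    """Weighted NNLS for (amp_free, amp_bound, a3) at fixed lifetimes.

    Returns the amplitudes and the weighted residual norm.  The design has
    one column per global NAD(P)H amplitude plus one per flavin channel.
    """
    n_ch, n_bins = k.shape
    fl_idx = np.flatnonzero(flavin_mask)
    n_cols = 2 + fl_idx.size
    design = np.zeros((n_ch * n_bins, n_cols))
    design[:, 0] = (basis.free_spectrum[:, None] * curves[0]).ravel()
    design[:, 1] = (basis.bound_spectrum[:, None] * curves[1]).ravel()
    for j, c in enumerate(fl_idx):
        design[c * n_bins : (c + 1) * n_bins, 2 + j] = curves[2]
    w = 1.0 / np.sqrt(np.maximum(k.ravel(), 1.0))
    coef, rnorm = optimize.nnls(design * w[:, None], k.ravel() * w)
    a3 = np.zeros(n_ch)
    a3[fl_idx] = coef[2:]
    return coef[0], coef[1], a3, rnorm


def fit_global(
    channel_decays: np.ndarray,
    instrument: InstrumentModel,
    basis: ComponentBasis | None = None,
    options: GlobalFitOptions | None = None,
) -> GlobalFitResult:
    """Fit the constrained three-component model to all channels jointly.

    Parameters
    ----------
    channel_decays
        Photon counts, shape ``(n_channels, n_bins)``.
    basis
        Component constraints; defaults to the packaged reference spectra.
    """
    options = options or GlobalFitOptions()
    if basis is None:
        basis = ComponentBasis.default(instrument.spectral)
    k = np.asarray(channel_decays, dtype=float)
    n_ch = instrument.spectral.n_channels
    n_bins = instrument.time.n_bins
    if k.shape != (n_ch, n_bins):
        raise DimensionError(f"expected shape ({n_ch}, {n_bins}), got {k.shape}")
    if basis.n_channels != n_ch:
        raise ConfigurationError(
            f"basis has {basis.n_channels} channels, spectral axis has {n_ch}"
        )
    if basis.free_spectrum.max() <= 0 or basis.bound_spectrum.max() <= 0:
        raise ConfigurationError("basis spectra must not be all zero")
    n_photons = float(k.sum())
    if n_photons < options.min_photons_global:
        raise InsufficientSignalError(
            f"{n_photons:.0f} photons < min_photons_global="
            f"{options.min_photons_global:.0f}"
        )
    flavin_mask = basis.flavin_channel_mask(instrument.spectral)
    fl_idx = np.flatnonzero(flavin_mask)
    (tb_lo, tb_hi) = basis.tau_bound_bounds_ns
    (tf_lo, tf_hi) = basis.tau_flavin_bounds_ns

    # --- stage 1: profile-NNLS objective over the two shared lifetimes ---
    def profile_obj(log_taus: np.ndarray) -> float:
        tb = float(np.exp(log_taus[0]))
        tf = float(np.exp(log_taus[1]))
        penalty = 0.0
        if not tb_lo <= tb <= tb_hi:
            clipped = min(max(tb, tb_lo), tb_hi)
            penalty += 1e4 * (np.log(tb) - np.log(clipped)) ** 2
            tb = clipped
        if not tf_lo <= tf <= tf_hi:
            clipped = min(max(tf, tf_lo), tf_hi)
            penalty += 1e4 * (np.log(tf) - np.log(clipped)) ** 2
            tf = clipped
        curves = _stack_basis(basis, instrument, tb, tf)
        _, _, _, rnorm = _profile_amplitudes(k, curves, basis, flavin_mask)
        return rnorm * rnorm * (1.0 + penalty)

    starts = [(options.init_tau_bound_ns, options.init_tau_flavin_ns)]
    if options.multistart:
        starts += [
            (tb, tf)
            for tb in options.tau_bound_starts_ns
            for tf in options.tau_flavin_starts_ns
        ]
    start_vals = [(profile_obj(np.log(s)), s) for s in starts]
    # ties broken toward smaller tau_bound
    start_vals.sort(key=lambda sv: (sv[0], sv[1][0]))
    x0 = np.log(start_vals[0][1])
    nm = optimize.minimize(
        profile_obj, x0, method="Nelder-Mead",
        options={"xatol": 1e-4, "fatol": 1e-9 * max(start_vals[0][0], 1.0),
                 "maxiter": 300},
    )
    tau_bound = float(np.clip(np.exp(nm.x[0]), tb_lo, tb_hi))
    tau_flavin = float(np.clip(np.exp(nm.x[1]), tf_lo, tf_hi))
    curves = _stack_basis(basis, instrument, tau_bound, tau_flavin)
    amp_free, amp_bound, a3, _ = _profile_amplitudes(k, curves, basis, flavin_mask)

    # --- stage 2: joint refinement of amplitudes and lifetimes ---
    loss = _poisson_deviance if options.objective == "mle" else _wls_objective
    amp_floor = max(n_photons, 1.0) * 1e-12
    t0_init = instrument.irf_t0_ns

    def pack(af, ab, a3v, tb, tf, t0):
        x = [np.log(max(af, amp_floor)), np.log(max(ab, amp_floor))]
        x += [np.log(max(v, amp_floor)) for v in a3v[fl_idx]]
        x += [tb, tf]
        if options.fit_t0:
            x.append(t0)
        return np.asarray(x)

    def unpack(x):
        af, ab = np.exp(x[0]), np.exp(x[1])
        a3v = np.zeros(n_ch)
        a3v[fl_idx] = np.exp(x[2 : 2 + fl_idx.size])
        tb, tf = x[2 + fl_idx.size], x[3 + fl_idx.size]
        t0 = x[4 + fl_idx.size] if options.fit_t0 else t0_init
        return af, ab, a3v, tb, tf, t0

    def joint_obj(x):
        af, ab, a3v, tb, tf, t0 = unpack(x)
        cur = _stack_basis(basis, instrument, tb, tf, t0)
        return loss(k, _expected(af, ab, a3v, cur, basis))

    log_amp_bounds = (np.log(amp_floor), np.log(max(n_photons, 1.0) * 1e6))
    bounds = [log_amp_bounds, log_amp_bounds]
    bounds += [log_amp_bounds] * fl_idx.size
    bounds += [(tb_lo, tb_hi), (tf_lo, tf_hi)]
    if options.fit_t0:
        bounds += [(0.0, 0.5 * instrument.time.period_ns)]
    x0 = pack(amp_free, amp_bound, a3, tau_bound, tau_flavin, t0_init)
    res = optimize.minimize(
        joint_obj, x0, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 1000, "ftol": 1e-13, "gtol": 1e-10},
    )
    amp_free, amp_bound, a3, tau_bound, tau_flavin, t0_fit = unpack(res.x)
    tau_bound = float(tau_bound)
    tau_flavin = float(tau_flavin)
    a3[a3 <= 2 * amp_floor] = 0.0  # amplitudes pinned at the floor are zero

    at_bound = []
    for name, val, lo, hi in (
        ("tau_bound", tau_bound, tb_lo, tb_hi),
        ("tau_flavin", tau_flavin, tf_lo, tf_hi),
    ):
        if val - lo < 1e-6 * (hi - lo) or hi - val < 1e-6 * (hi - lo):
            at_bound.append(name)

    a_free, a_bound, a_flavins = normalize_amplitudes(
        amp_free * basis.free_spectrum, amp_bound * basis.bound_spectrum, a3
    )
    final_curves = _stack_basis(basis, instrument, tau_bound, tau_flavin, t0_fit)
    final_model = _expected(amp_free, amp_bound, a3, final_curves, basis)
    return GlobalFitResult(
        amp_free=float(amp_free),
        amp_bound=float(amp_bound),
        flavin_spectrum=a3,
        tau_bound_ns=tau_bound,
        tau_flavin_ns=tau_flavin,
        A1=float(amp_free),
        A2=float(amp_bound),
        A3=float(a3.max()),
        a_free=a_free,
        a_bound=a_bound,
        a_flavins=a_flavins,
        ratio_free_bound=float(amp_free / amp_bound) if amp_bound > 0 else float("inf"),
        tau_m_nadh_ns=nadh_mean_lifetime(a_free, a_bound, basis.tau_free_ns, tau_bound),
        lambda_avg_flavin_nm=flavin_lambda_avg(a3, instrument.spectral),
        chi2_reduced=_pearson_chi2_reduced(k, final_model, len(x0)),
        n_photons=n_photons,
        converged=bool(res.success),
        at_bound=tuple(at_bound),
        message="" if res.success else str(res.message),
    )
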