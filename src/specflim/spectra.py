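"""Log-normal emission band shapes and reference-spectrum handling.

Fluorescence emission bands are well described phenomenologically by
asymmetric log-normal functions (Siano & Metzler form): a Gaussian in
``ln(1 + (lambda - peak)*(rho^2 - 1)/(fwhm*rho))`` with asymmetry ``rho``.
The free/bound NAD(P)H reference shapes shipped with the package and the
synthetic component spectra both come from this family.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, DomainError
from .model import SpectralAxis

__all__ = ["lognormal_band", "load_reference_spectra", "resample_spectrum"]

# Band parameters used for the packaged reference spectra: peaks from the
# free (~475 nm) and LDH-bound (~450 nm) NADH solution emission maxima.
FREE_NADH_PEAK_NM = 475.0
BOUND_NADH_PEAK_NM = 450.0
FLAVIN_PEAK_NM = 535.0
_NADH_FWHM_NM = 80.0
_NADH_RHO = 1.4
FLAVIN_FWHM_NM = 70.0
FLAVIN_RHO = 1.3


def lognormal_band(
    wavelength_nm: np.ndarray,
    peak_nm: float,
    fwhm_nm: float,
    rho: float = 1.4,
) -> np.ndarray:
    """Asymmetric log-normal emission band, max-normalized to 1 at the peak.

    ``rho > 1`` skews the band toward longer wavelengths, the usual shape of
    fluorophore emission.  Outside the band's support the value is 0.
    """
    if fwhm_nm <= 0 or rho <= 1.0:
        raise DomainError("fwhm_nm must be > 0 and rho > 1")
    lam = np.asarray(wavelength_nm, dtype=float)
    b = (rho * rho - 1.0) / (fwhm_nm * rho)
    arg = 1.0 + (lam - peak_nm) * b
    out = np.zeros_like(lam)
    ok = arg > 0
    ln_rho = np.log(rho)
    out[ok] = np.exp(-np.log(2.0) * (np.log(arg[ok]) / ln_rho) ** 2)
    return out


def nadh_reference_spectra(wavelength_nm: np.ndarray) -> pd.DataFrame:
    """Free/bound NAD(P)H reference shapes on an arbitrary wavelength grid."""
    lam = np.asarray(wavelength_nm, dtype=float)
    return pd.DataFrame(
        {
            "wavelength_nm": lam,
            "free_nadh": lognormal_band(lam, FREE_NADH_PEAK_NM, _NADH_FWHM_NM, _NADH_RHO),
            "bound_nadh": lognormal_band(lam, BOUND_NADH_PEAK_NM, _NADH_FWHM_NM, _NADH_RHO),
        }
    )


def load_reference_spectra(path) -> pd.DataFrame:
    """Read a reference-spectra CSV (wavelength_nm, free_nadh, bound_nadh)."""
    table = pd.read_csv(path)
    missing = {"wavelength_nm", "free_nadh", "bound_nadh"} - set(table.columns)
    if missing:
        raise ConfigurationError(
            f"reference spectra CSV missing columns: {sorted(missing)}"
        )
    if not table["wavelength_nm"].is_monotonic_increasing:
        raise ConfigurationError("reference spectra wavelengths must be increasing")
    return table


def resample_spectrum(
    wavelength_nm: np.ndarray,
    values: np.ndarray,
    spectral: SpectralAxis,
) -> np.ndarray:
    """Linear interpolation of a spectrum onto the channel grid, max-normalized."""
    resampled = np.interp(spectral.channel_centers_nm, wavelength_nm, values)
    resampled = np.clip(resampled, 0.0, None)
    peak = resampled.max()
    if peak <= 0:
        raise ConfigurationError("spectrum has no mass on the spectral axis")
    return resampled / peak
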