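import numpy as np
import pytest

from specflim import ComponentBasis, InstrumentModel, generate_component_spectra


@pytest.fixture(scope="session")
def instrument() -> InstrumentModel:
    """Default acquisition: 256 bins over 12.5 ns, 16 channels, 220 ps IRF."""
    return InstrumentModel()


@pytest.fixture(scope="session")
def basis(instrument) -> ComponentBasis:
    return ComponentBasis.default(instrument.spectral)


@pytest.fixture(scope="session")
def component_shapes(instrument) -> np.ndarray:
    """(3, 16) max-normalized free/bound/flavin emission shapes."""
    return generate_component_spectra(instrument.spectral)


def simpson_convolution_oracle(tau, sigma, inst, oversample=10):
    """Brute-force numeric Gaussian(x)exponential convolution at bin centers.

    Simpson's rule on an ``oversample``-times finer grid whose nodes include
    the integrand breakpoint s = t; independent of the analytic closed form
    used by the model.
    """
    from scipy.integrate import simpson

    ds = inst.time.bin_width_ns / oversample
    t = inst.time.bin_centers_ns
    out = np.empty_like(t)
    lo = inst.irf_t0_ns - 12 * sigma
    norm = 1.0 / (sigma * np.sqrt(2 * np.pi))
    for i, ti in enumerate(t):
        if ti <= lo:
            out[i] = 0.0
            continue
        n = max(int(np.ceil((ti - lo) / ds)), 8)
        n += n % 2
        s = np.linspace(ti - n * ds, ti, n + 1)
        f = norm * np.exp(-0.5 * ((s - inst.irf_t0_ns) / sigma) ** 2) * np.exp(-(ti - s) / tau)
        out[i] = simpson(f, dx=ds)
    return out
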