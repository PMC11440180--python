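"""Global three-component unmixing of a single cell's multispectral decay.

Simulates the cell-integrated decay set of a control-like cell (free/bound
NAD(P)H ratio 2.7, bound lifetime 2.5 ns, 12% flavins at 1.48 ns), then
fits all 16 spectral channels simultaneously with shared lifetimes and
prints the recovered metabolic descriptors next to the ground truth.
"""

import numpy as np

from specflim import ComponentBasis, InstrumentModel, fit_global
from specflim.synthetic import expected_cell_slice

instrument = InstrumentModel()
basis = ComponentBasis.default(instrument.spectral)

truth = dict(ratio=2.7, tau_bound=2.5, flavins=0.12, tau_flavin=1.48)
expected = expected_cell_slice(
    instrument, truth["ratio"], truth["tau_bound"], truth["flavins"],
    truth["tau_flavin"], total_photons=5e5,
)
counts = np.random.default_rng(1).poisson(expected)

fit = fit_global(counts, instrument, basis)

print(f"{'parameter':<22}{'truth':>8}{'fitted':>9}")
print(f"{'free/bound ratio':<22}{truth['ratio']:>8.2f}{fit.ratio_free_bound:>9.2f}")
print(f"{'tau_bound (ns)':<22}{truth['tau_bound']:>8.2f}{fit.tau_bound_ns:>9.2f}")
print(f"{'a_flavins':<22}{truth['flavins']:>8.3f}{fit.a_flavins:>9.3f}")
print(f"{'tau_flavin (ns)':<22}{truth['tau_flavin']:>8.2f}{fit.tau_flavin_ns:>9.2f}")
print(f"{'tau_m NAD(P)H (ns)':<22}{'':>8}{fit.tau_m_nadh_ns:>9.2f}")
print(f"{'lambda_avg flavin':<22}{'':>8}{fit.lambda_avg_flavin_nm:>9.1f}")
print()
print("The three normalized amplitudes sum to 1; a_flavins is the flavin")
print("share of the signal, and the free/bound ratio tracks the balance")
print("between glycolytic (high) and oxidative (low) metabolism.")
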