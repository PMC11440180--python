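"""Per-channel bi-exponential analysis of a solution-phase NADH decay.

Builds a noiseless free-NADH decay (80% of a 0.36 ns component plus 20% of
a 0.89 ns component, convolved with the 220 ps Gaussian IRF), adds Poisson
noise, fits it, and prints the recovered lifetimes and the
amplitude-weighted mean lifetime tau_m.
"""

import numpy as np

from specflim import DecayCurve, InstrumentModel, fit_biexponential, model_decay

instrument = InstrumentModel()  # 256 bins over 12.5 ns, 220 ps IRF
expected = model_decay([0.80, 0.20], [0.36, 0.89], instrument)
expected *= 1e5 / expected.sum()  # 100k photons, a typical solution decay

rng = np.random.default_rng(0)
curve = DecayCurve(rng.poisson(expected), instrument.time)
fit = fit_biexponential(curve, instrument)

print(f"tau1 = {fit.tau1_ns:.3f} ns  (a1 = {fit.a1:.2f})")
print(f"tau2 = {fit.tau2_ns:.3f} ns  (a2 = {fit.a2:.2f})")
print(f"tau_m = {fit.tau_m_ns:.3f} ns   chi2_r = {fit.chi2_reduced:.2f}")
print()
print("tau_m is the amplitude-weighted mean lifetime; for free NADH it")
print("sits near 0.47 ns, far below the ~1.4 ns of enzyme-bound NADH.")
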