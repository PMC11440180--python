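# Methods

This note records the model, the numerical choices and the limits of what
the synthetic validation shows. It is written for users who want to judge
whether the defaults fit their instrument and for developers changing the
fit internals.

## Forward model

A TCSPC histogram over one laser period (12.5 ns at 80 MHz; 256 bins of
~48.8 ps by default) measures the molecular decay convolved with the
instrument response. The IRF is modeled as a Gaussian with FWHM 220 ps
(σ = FWHM/2.355 ≈ 93.4 ps), positioned at t₀ = 10% of the period by
default. Real multi-anode PMT responses are slightly non-Gaussian — a
220 ps-FWHM Gaussian has 93 ps RMS whereas such detectors are usually
quoted nearer 96 ps — so a measured IRF can be supplied as a CSV
(`time_ns, weight`), resampled onto the bin grid and used through the
discrete circular-convolution forward path (`model_decay_measured_irf`).
The packaged fitters use the Gaussian model: it admits a closed-form
convolution, and the tabulated path carries ~1% bin-resolution error on
the IRF rising edge.

Each decay component is evaluated analytically as the exponentially
modified Gaussian

    f(t) = ½ exp(σ²/2τ² − (t−t₀)/τ) · erfc((σ/τ − (t−t₀)/σ)/√2),

computed in two algebraically identical but numerically complementary
branches: where the erfc argument is non-negative the scaled form
`½·erfcx(z)·exp(−(t−t₀)²/2σ²)` avoids overflow for τ ≪ σ; elsewhere the
plain form is safe. Exponents are clipped at 700 as a final guard. A
discrete oversampled convolution exists in the test suite as an independent
oracle; the analytic path is what the fitters use (no oversampling
artifacts, ~100× faster).

At 80 MHz a several-ns component does not decay out within one period, so
the tail of the previous pulse overlaps the next window. With period T the
steady-state correction multiplies the exponential part by
exp(−T/τ)/(1 − exp(−T/τ)) — exact up to terms of order
exp(−(T−t₀)²/2σ²), which is ≪ 10⁻³⁰ for realistic geometries. The
correction is on by default; integrated over one period each unit-amplitude
component then carries exactly τ of mass (times the bin-width
normalization), which the tests verify to 10⁻⁶.

## Spectral axis and reference spectra

The 16 detector channels are modeled with centers spanning 388.1–573.6 nm
uniformly (spacing ≈ 12.37 nm). The nominal 12.5 nm channel bandwidth is
kept as descriptive metadata only: with 16 channels it implies a 200 nm
span that is inconsistent with the stated endpoints, and treating the
endpoints as first/last channel *centers* is the reading that keeps the
grid uniform.

Free and bound NAD(P)H reference shapes are asymmetric log-normal bands
(Siano–Metzler form) peaking at 475 and 450 nm with 80 nm FWHM and
asymmetry ρ = 1.4, shipped as a versioned CSV on a 2 nm grid and linearly
interpolated onto the channel grid, then max-normalized. Solution-measured
spectra can be substituted through the same CSV interface. The synthetic
flavin band peaks at 535 nm (70 nm FWHM, ρ = 1.3) and is truncated below
490 nm.

## Fitting

**Objective.** Poisson deviance (C-statistic) 2Σ[m − k + k ln(k/m)] by
default — the correct likelihood at TCSPC count levels, and well defined
for the non-integer "counts" of noiseless model inversions. A
1/max(k,1)-weighted least-squares objective is available for parity with
conventional FLIM software. Goodness of fit is reported separately as
Pearson χ² per degree of freedom over bins with model counts ≥ 1; on
correctly specified simulations at 10⁵ photons its median sits in
[0.9, 1.1].

**Per-channel bi-exponential fit.** Initialization τ₁ = 0.4 ns,
τ₂ = 2.0 ns; amplitudes solved by weighted non-negative least squares at
the starting lifetimes; joint refinement with L-BFGS-B over log-amplitudes
and log-lifetimes (box [0.02, 12] ns); a τ₂ ∈ {1, 2, 4} ns multi-start on
non-convergence; lifetimes swapped post-fit so τ₁ ≤ τ₂. Decays under 500
photons are rejected rather than fitted.

**Global three-component fit.** The model is linear in all amplitudes at
fixed lifetimes, and the amplitude block (2 global NAD(P)H scalars + one
flavin amplitude per channel ≥ 490 nm) is solved by weighted NNLS inside a
Nelder–Mead search over (log τ_bound, log τ_flavin); bound violations are
clipped with a quadratic penalty. A 3×3 multi-start grid
{1.0, 2.0, 3.5} × {0.8, 1.5, 3.0} ns seeds the search (ties toward smaller
τ_bound), then all parameters are refined jointly under the Poisson
objective with L-BFGS-B, lifetimes boxed to their physical bounds
(τ_bound ∈ [0.5, 10] ns as is standard for bound NAD(P)H; τ_flavins ∈
[0.3, 6] ns spanning quenched-FAD to FMN literature values). Amplitudes
live in log space with a floor at 10⁻¹² of the photon count; amplitudes
pinned at the floor are reported as exactly zero. Lifetimes within 10⁻⁶ of
a bound are flagged `at_bound`; cell-integrated decay sets under 2000
photons are rejected. The parameterization uses max-normalized fixed
shapes, so the channel-maximum Aᵢ of each NAD(P)H component equals its
fitted scalar and the normalized triple Aᵢ/ΣA is invariant to overall
scale. The flavin component is a single shared exponential; real flavin
decays are multi-exponential, so the fitted τ_flavins is an effective
value (see Limitations).

An optional shared IRF-position parameter t₀ can be fitted
(`fit_t0=True`); per-channel IRF color shift is not modeled.

## Imaging pipeline

Spatial binning sums counts over a (2b+1)×(2b+1) window per pixel
(b = 5 → the conventional 11×11 window), implemented with an exact
integral-image sum and *clipped* windows at image edges — padding would
fabricate photons. Cell-level analysis sums the member-pixel histograms
into one decay set per labelled cell and fits that sum once; this is
bit-identical to fitting the aggregate signal, not an average of per-pixel
fits. Distance to the spheroid border is the Euclidean distance transform
of the spheroid foreground evaluated at each cell's centroid (the natural
reference point produced by segmentation pipelines), scaled by the pixel
pitch. The per-pixel mean-emission-wavelength map uses the time-integrated
channel intensities; empty pixels are NaN, never zero.

## Statistics

Groups are summarized by median and interquartile range and compared with
the two-sided Mann–Whitney U test — the match for median/IQR reporting of
skewed single-cell distributions. Raw p-values are reported by default;
Holm's step-down is available by flag. Correlation is Pearson's r (most
relationships of interest here are near-linear) with a Spearman option.
Depth profiles bin cells by distance to border (10 µm default) and flag
bins with fewer than 3 cells.

## Synthetic data: what it does and does not emulate

The generator draws Poisson counts from the same three-component forward
model the fitters assume, on elliptical non-overlapping "cells" placed on a
jittered grid (geometry is invented; segmentation ground truth is exported
so mask-consuming code is testable without a segmentation algorithm).
Group presets place per-cell parameters on median-preserving lognormal
distributions (CV 10%, chosen to make population spread realistic without
degenerate boxplots) around: control — ratio 2.7, τ_bound 2.5 ns, flavins
12%, τ_flavins 1.48 ns; rotenone — 3.3, 2.1 ns, 7.6%, 1.85 ns; 3BP — 2.65,
2.35 ns, 11.5%, 1.72 ns. Flavin emission peaks are 535 nm for control and
red-shifted to 545/542 nm for the inhibitor groups. The spheroid phantom
ramps ground truth linearly with depth from the border to 80 µm: ratio
5.3 → 4.0, flavin fraction 0.125 → 0.16, and a NAD(P)H mean-lifetime
gradient 0.84 → 0.86 ns realized by inverting the τ_m definition for
τ_bound at the local ratio (3.33 → 2.82 ns); spheroid truth carries no
per-cell dispersion so the profiles are monotone by construction.
`simulate_cell_decays` draws at the cell-integrated intensity — by Poisson
additivity distributionally identical to simulating the cube and summing
over the mask — and is used where only cell-level decays are needed.

Because generator and fitter share the forward model, passing round trips
demonstrate correct inversion, identifiability under photon noise, and the
statistical power of the pipeline at the stated effect sizes. They do not
probe model misspecification: real data add non-Gaussian IRF tails,
detector afterpulsing and pile-up, optical blur and depth-dependent
scattering (none simulated), background fluorophores beyond the three
components, and reference spectra that differ from the solution-phase
shapes. The fixed-spectrum constraint is also a real-world approximation:
bound-NAD(P)H spectra shift with the binding enzyme.

## Problem sizes

Round-trip suites run at sizes chosen to keep the full validation quick on
one CPU while leaving comfortable statistical margins: 20 Poisson
replicates at 5×10⁵ photons for parameter recovery, 200 cells per group for
the control/rotenone separation, a 100 µm-radius spheroid at 2 µm pixels
(≈150 cells, ≈4×10⁴ photons per cell) for the depth profile, and 500 null
replicates for the type-I-error check. Precision scales as √N in photons
and cells; users validating modified fit internals may want to raise both.

## Known limitations

* One effective flavin exponential; FAD vs FMN (or stacked vs unstacked
  conformers) are not separated, and NADH vs NADPH are spectrally
  indistinguishable here by construction.
* Gaussian IRF by default (see above); supply a measured IRF for detectors
  with heavy tails.
* No reader for vendor binary formats (e.g. .sdt); convert to the HDF5
  container first.
* Per-pixel global fits are serial Python; expect ~0.1–0.2 s per fitted
  (binned) pixel. Cell-level analysis is the intended operating point.
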