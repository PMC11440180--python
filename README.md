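# specflim

Global spectral–temporal unmixing of multispectral FLIM data.

Autofluorescence lifetime imaging of the metabolic cofactors NAD(P)H and
flavins is a label-free readout of cellular metabolism: the amplitude ratio
of free to protein-bound NAD(P)H tracks the balance between glycolysis and
oxidative phosphorylation, while flavins report the oxidized side of the
redox couple. When decays are recorded in a single spectral window the
flavin signal contaminates the NAD(P)H fit. `specflim` implements the
remedy: record time-correlated single-photon-counting (TCSPC) decays in
many emission channels at once (16 channels, 388.1–573.6 nm) and fit all
channels *simultaneously* with a constrained three-component model, so each
component is pinned down jointly by its emission spectrum and its lifetime.

It is written for microscopists and image analysts working with
multispectral TCSPC data of cells, and ships a photon-realistic simulator
so every stage can be validated against known ground truth without a
microscope.

## The model

The measured decay in channel λ is the instrument response function (IRF,
Gaussian, 220 ps FWHM) convolved with a tri-exponential decay whose
lifetimes are shared across channels:

    F(λ, t) ∼ IRF(t) ⊗ Σᵢ aᵢ(λ) exp(−t / τᵢ),   i ∈ {free, bound, flavins}

with the constraints

* a₁(λ), a₂(λ) fixed to reference free/bound NAD(P)H emission shapes
  (max-normalized), only their overall amplitudes free;
* τ_free = 0.37 ns fixed; τ_bound ∈ [0.5, 10] ns; τ_flavins ∈ [0.3, 6] ns;
* the flavin spectrum a₃(λ) free per channel but ≡ 0 below 490 nm;
* all amplitudes ≥ 0.

The Gaussian⊗exponential convolution is evaluated with its analytic
(exponentially modified Gaussian) closed form, including a previous-pulse
correction for lifetimes that do not decay out within the 12.5 ns period of
an 80 MHz laser. With Aᵢ = max_λ aᵢ(λ), the normalized contributions
aᵢ = Aᵢ / (A₁ + A₂ + A₃) sum to one; derived descriptors are the free/bound
ratio A₁/A₂, the mean NAD(P)H lifetime
τ_m = (a_free τ_free + a_bound τ_bound)/(a_free + a_bound), the
intensity-weighted mean emission wavelength λ_avg, and the flavin λ_avg.
Fitting minimizes the Poisson deviance (correct at photon-counting noise
levels) with a separable strategy: non-negative least squares in the
amplitudes inside a two-dimensional search over the shared lifetimes,
followed by a joint refinement.

## Worked example

Simulate the cell-integrated multispectral decay of a control-like cell and
unmix it (`examples/global_unmixing.py`):

```text
parameter                truth   fitted
free/bound ratio          2.70     2.70
tau_bound (ns)            2.50     2.50
a_flavins                0.120    0.120
tau_flavin (ns)           1.48     1.48
tau_m NAD(P)H (ns)                 0.95
lambda_avg flavin                 537.6
```

At 5×10⁵ photons the constrained global fit recovers all four generating
parameters; `a_flavins = 0.120` means flavins carry 12% of the unmixed
signal amplitude, and τ_m ≈ 0.95 ns is the amplitude-weighted NAD(P)H mean
lifetime implied by ratio 2.7 and τ_bound 2.5 ns.

The other examples follow the same pattern: `solution_biexponential.py`
(per-channel bi-exponential fit of a free-NADH solution decay, τ_m ≈ 0.47
ns), `group_comparison.py` (control vs rotenone populations, Mann–Whitney
comparisons) and `spheroid_profile.py` (depth-resolved profiles across a
tumor-spheroid phantom, free/bound ratio falling ~5.2 → 4.0 from shell to
core while the flavin share rises ~0.13 → 0.16).

## Command line

For shell use the same pipeline is exposed as a thin CLI:

```sh
specflim simulate --scene groups --seed 1 --out-dir run/      # phantom bundle
specflim fit --cube run/control_cube.h5 --mask run/control_mask.tif \
    --truth run/truth.csv --group control --out-dir run/fit   # cell table
specflim report run/fit/cell_table.csv --out-dir run/report   # statistics
specflim irf-check                                            # axes summary
```

Cubes travel as self-describing HDF5 (counts plus axes metadata), masks as
integer-label TIFF, tables and spectra as CSV, configuration as validated
YAML embedded into every output's provenance.

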