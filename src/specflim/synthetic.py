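"""Photon-realistic phantoms: multispectral TCSPC cubes with known ground truth.

Scenes are built from elliptical "cells" on a dark background; every cell
carries the biochemical parameters the analysis estimates (free/bound
NAD(P)H amplitude ratio, bound-NAD(P)H lifetime, flavin contribution and
lifetime, flavin emission peak).  Expected per-pixel counts follow the same
IRF-convolved three-component forward model the fitters assume, and
observed counts are independent Poisson draws, so the generator provides
exact, seeded ground truth for round-trip validation.

Group parameter presets (medians):

================  ======  =========  ==========  =========
group             ratio   tau_bound  a_flavins   tau_flavin
================  ======  =========  ==========  =========
control           2.7     2.5 ns     0.12        1.48 ns
rotenone          3.3     2.1 ns     0.076       1.85 ns
3BP               2.65    2.35 ns    0.115       1.72 ns
================  ======  =========  ==========  =========

Rotenone (complex-I inhibitor) raises the free/bound ratio and shortens
tau_bound; 3-bromopyruvate (glycolysis inhibitor) shifts cells toward
oxidative metabolism.  Per-cell parameters are drawn from median-preserving
lognormal distributions (default CV 10%).  The spheroid phantom lays cells
on a disk with linear radial gradients between the shell (depth 0) and
80 um depth: ratio 5.3 -> 4.0, flavin fraction 0.125 -> 0.16, and a
NAD(P)H mean lifetime ramp 0.84 -> 0.86 ns realized through tau_bound.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, DomainError
from .globalfit import TAU_FREE_NS, nadh_mean_lifetime
from .model import InstrumentModel, SpectralAxis, SpectralTemporalCube, model_cube_slice
from .spectra import (
    BOUND_NADH_PEAK_NM,
    FLAVIN_FWHM_NM,
    FLAVIN_PEAK_NM,
    FLAVIN_RHO,
    FREE_NADH_PEAK_NM,
    lognormal_band,
    nadh_reference_spectra,
    resample_spectrum,
)

__all__ = [
    "GROUP_MEDIANS",
    "ScenePhantom",
    "expected_cell_slice",
    "generate_component_spectra",
    "simulate_cube",
    "simulate_cell_decays",
    "make_group_scene",
    "make_spheroid_scene",
]

#: Median per-cell parameters for each experimental group.
GROUP_MEDIANS: dict[str, dict[str, float]] = {
    "control": dict(
        ratio_free_bound=2.7, tau_bound_ns=2.5, flavin_fraction=0.12,
        tau_flavin_ns=1.48, flavin_peak_nm=535.0,
    ),
    "rotenone": dict(
        ratio_free_bound=3.3, tau_bound_ns=2.1, flavin_fraction=0.076,
        tau_flavin_ns=1.85, flavin_peak_nm=545.0,
    ),
    "3BP": dict(
        ratio_free_bound=2.65, tau_bound_ns=2.35, flavin_fraction=0.115,
        tau_flavin_ns=1.72, flavin_peak_nm=542.0,
    ),
}

#: Spheroid radial-profile endpoints (shell at depth 0 -> 80 um depth).
SPHEROID_PROFILE = dict(
    max_depth_um=80.0,
    ratio_free_bound=(5.3, 4.0),
    flavin_fraction=(0.125, 0.16),
    tau_m_nadh_ns=(0.84, 0.86),
    tau_flavin_ns=(1.6, 1.5),
    flavin_peak_nm=535.0,
)

TRUTH_COLUMNS = [
    "cell_id", "group", "ratio_free_bound", "tau_bound_ns", "flavin_fraction",
    "tau_flavin_ns", "flavin_peak_nm", "brightness", "border_distance_um",
]


@dataclass
class ScenePhantom:
    """A labelled scene with per-cell ground truth.

    ``cell_masks`` is an integer label image (0 = background, cells are
    contiguous positive labels); ``truth`` has one row per label with the
    generating parameters.
    """

    shape: tuple[int, int]
    cell_masks: np.ndarray
    truth: pd.DataFrame
    group_label: str
    pixel_size_um: float = 1.0
    region_mask: np.ndarray | None = None  # spheroid foreground disk, if any

    def __post_init__(self) -> None:
        self.cell_masks = np.asarray(self.cell_masks)
        if self.cell_masks.shape != tuple(self.shape):
            raise ConfigurationError("cell_masks shape disagrees with scene shape")
        labels = np.unique(self.cell_masks)
        labels = labels[labels > 0]
        expected = np.arange(1, labels.size + 1)
        if not np.array_equal(labels, expected):
            raise ConfigurationError("labels must be contiguous positive integers")
        if not np.array_equal(np.sort(self.truth["cell_id"].to_numpy()), expected):
            raise ConfigurationError("ground truth must cover every label exactly once")
        frac = self.truth["flavin_fraction"]
        if ((frac < 0) | (frac > 1)).any():
            raise ConfigurationError("flavin fractions must lie in [0, 1]")

    @property
    def n_cells(self) -> int:
        return int(self.truth.shape[0])


def generate_component_spectra(
    spectral: SpectralAxis,
    flavin_peak_nm: float = FLAVIN_PEAK_NM,
    flavin_cutoff_nm: float = 490.0,
) -> np.ndarray:
    """Max-normalized component shapes (3, n_channels): free, bound, flavin.

    Free NAD(P)H peaks near 475 nm, bound near 450 nm; the flavin band
    peaks at ``flavin_peak_nm`` and is truncated to zero below the cutoff.
    """
    lam_range = (spectral.channel_centers_nm.min(), spectral.channel_centers_nm.max())
    if not lam_range[0] <= flavin_peak_nm <= lam_range[1]:
        raise DomainError(
            f"flavin peak {flavin_peak_nm} nm outside spectral range {lam_range}"
        )
    fine = np.arange(350.0, 700.0, 1.0)
    ref = nadh_reference_spectra(fine)
    free = resample_spectrum(fine, ref["free_nadh"].to_numpy(), spectral)
    bound = resample_spectrum(fine, ref["bound_nadh"].to_numpy(), spectral)
    flavin = lognormal_band(
        spectral.channel_centers_nm, flavin_peak_nm, FLAVIN_FWHM_NM, FLAVIN_RHO
    )
    flavin[spectral.channel_centers_nm < flavin_cutoff_nm] = 0.0
    peak = flavin.max()
    if peak > 0:
        flavin = flavin / peak
    return np.vstack([free, bound, flavin])


def _component_amplitudes(ratio: float, flavin_fraction: float) -> tuple[float, float, float]:
    """(amp_free, amp_bound, amp_flavin) realizing the requested ratio and
    normalized flavin contribution on max-normalized shapes."""
    if not 0 <= flavin_fraction < 1:
        raise DomainError("flavin_fraction must lie in [0, 1)")
    amp_bound = 1.0
    amp_free = ratio
    amp_flavin = flavin_fraction * (amp_free + amp_bound) / (1.0 - flavin_fraction)
    return amp_free, amp_bound, amp_flavin


def expected_cell_slice(
    instrument: InstrumentModel,
    ratio_free_bound: float,
    tau_bound_ns: float,
    flavin_fraction: float,
    tau_flavin_ns: float,
    flavin_peak_nm: float = FLAVIN_PEAK_NM,
    total_photons: float = 1.0,
) -> np.ndarray:
    """Noise-free expected counts (n_channels, n_bins) for one cell.

    The forward model evaluated at the given biochemical parameters, scaled
    to ``total_photons``; Poisson-sampling this array is exactly what the
    cube simulator does per pixel.
    """
    shapes = generate_component_spectra(instrument.spectral, flavin_peak_nm)
    af, ab, afl = _component_amplitudes(ratio_free_bound, flavin_fraction)
    amp = np.vstack([af * shapes[0], ab * shapes[1], afl * shapes[2]])
    slice_ = model_cube_slice(
        amp, [TAU_FREE_NS, tau_bound_ns, tau_flavin_ns], instrument
    )
    return slice_ * (total_photons / slice_.sum())


def _cell_expected_slice(
    row: pd.Series, instrument: InstrumentModel, spectra_cache: dict
) -> np.ndarray:
    """Unit-normalized expected (n_channels, n_bins) counts for one cell."""
    peak = float(row["flavin_peak_nm"])
    key = round(peak, 2)
    if key not in spectra_cache:
        spectra_cache[key] = generate_component_spectra(instrument.spectral, peak)
    shapes = spectra_cache[key]
    af, ab, afl = _component_amplitudes(
        float(row["ratio_free_bound"]), float(row["flavin_fraction"])
    )
    amp = np.vstack([af * shapes[0], ab * shapes[1], afl * shapes[2]])
    lifetimes = [TAU_FREE_NS, float(row["tau_bound_ns"]), float(row["tau_flavin_ns"])]
    slice_ = model_cube_slice(amp, lifetimes, instrument)
    return slice_ / slice_.sum()


def simulate_cube(
    phantom: ScenePhantom,
    instrument: InstrumentModel,
    total_photon_budget: float | None = None,
    dark_rate_per_bin: float = 0.0,
    seed: int | None = None,
) -> SpectralTemporalCube:
    """Draw a Poisson photon-count cube from a phantom's ground truth.

    Expected pixel counts follow the three-component forward model at the
    pixel's cell parameters, scaled so each cell receives ``brightness``
    expected photons per pixel (or so the whole cube totals
    ``total_photon_budget`` if given).  Counts are independent Poisson
    draws; identical seeds give bit-identical cubes.
    """
    if seed is None:
        raise ConfigurationError("simulate_cube requires an explicit seed")
    rng = np.random.default_rng(seed)
    n_ch = instrument.spectral.n_channels
    n_bins = instrument.time.n_bins
    rows, cols = phantom.shape
    expected = np.zeros((rows, cols, n_ch, n_bins))
    brightness = phantom.truth.set_index("cell_id")["brightness"]
    scale = 1.0
    if total_photon_budget is not None:
        pix_per_cell = np.bincount(phantom.cell_masks.ravel())
        nominal = sum(
            brightness.get(cid, 0.0) * pix_per_cell[cid]
            for cid in brightness.index if cid < pix_per_cell.size
        )
        nominal += dark_rate_per_bin * rows * cols * n_ch * n_bins
        if nominal > 0:
            scale = total_photon_budget / nominal
    cache: dict = {}
    for row in phantom.truth.itertuples():
        mask = phantom.cell_masks == row.cell_id
        if not mask.any():
            continue
        slice_ = _cell_expected_slice(
            phantom.truth.loc[phantom.truth["cell_id"] == row.cell_id].iloc[0],
            instrument, cache,
        )
        expected[mask] = slice_ * (row.brightness * scale)
    expected += dark_rate_per_bin * scale
    provenance = {
        "generator": "specflim.synthetic.simulate_cube",
        "seed": int(seed),
        "group_label": phantom.group_label,
        "n_cells": phantom.n_cells,
    }
    min_per_pixel = expected.sum(axis=(2, 3))[phantom.cell_masks > 0].min() \
        if (phantom.cell_masks > 0).any() else 0.0
    if min_per_pixel < 10:
        provenance["warning"] = (
            f"low photon budget: min expected photons/pixel = {min_per_pixel:.2f}"
        )
    counts = rng.poisson(expected).astype(np.uint32)
    return SpectralTemporalCube(
        counts=counts,
        instrument=instrument,
        pixel_size_um=phantom.pixel_size_um,
        provenance=provenance,
    )


def simulate_cell_decays(
    phantom: ScenePhantom,
    instrument: InstrumentModel,
    photons_per_cell: float,
    seed: int | None = None,
) -> np.ndarray:
    """Poisson cell-integrated decay sets, shape (n_cells, n_channels, n_bins).

    Drawing at the cell-integrated expected intensity is distributionally
    identical to simulating the full cube and summing counts over each
    cell's mask (Poisson additivity), and much faster when only cell-level
    decays are needed.
    """
    if seed is None:
        raise ConfigurationError("simulate_cell_decays requires an explicit seed")
    rng = np.random.default_rng(seed)
    cache: dict = {}
    out = np.empty(
        (phantom.n_cells, instrument.spectral.n_channels, instrument.time.n_bins)
    )
    truth = phantom.truth.sort_values("cell_id").reset_index(drop=True)
    for i, (_, row) in enumerate(truth.iterrows()):
        expected = _cell_expected_slice(row, instrument, cache) * photons_per_cell
        out[i] = rng.poisson(expected)
    return out


def _draw_lognormal(rng: np.random.Generator, median: float, cv: float, n: int) -> np.ndarray:
    """Median-preserving lognormal draws with the given coefficient of variation."""
    if cv <= 0:
        return np.full(n, median)
    s = np.sqrt(np.log1p(cv * cv))
    return median * np.exp(rng.normal(0.0, s, size=n))


def _pack_cells(
    shape: tuple[int, int],
    centers: np.ndarray,
    rng: np.random.Generator,
    radius_range: tuple[float, float] = (3.0, 5.0),
) -> np.ndarray:
    """Paint non-overlapping ellipses at the given centers (first come wins)."""
    rows, cols = shape
    yy, xx = np.mgrid[0:rows, 0:cols]
    mask = np.zeros(shape, dtype=np.int32)
    label = 0
    for cy, cx in centers:
        a = rng.uniform(*radius_range)
        b = rng.uniform(*radius_range)
        theta = rng.uniform(0, np.pi)
        dy, dx = yy - cy, xx - cx
        u = dx * np.cos(theta) + dy * np.sin(theta)
        v = -dx * np.sin(theta) + dy * np.cos(theta)
        inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        inside &= mask == 0
        if inside.sum() < 3:
            continue
        label += 1
        mask[inside] = label
    return mask


def make_group_scene(
    group_label: str,
    n_cells: int,
    seed: int | None = None,
    shape: tuple[int, int] | None = None,
    brightness: float = 2000.0,
    cv: float = 0.10,
    pixel_size_um: float = 0.5,
) -> ScenePhantom:
    """Scene of dispersed cells whose parameters center on a group's medians.

    Per-cell parameters are lognormal around the preset medians with
    coefficient of variation ``cv``; cells are ellipses placed on a
    jittered grid so they never overlap.
    """
    if group_label not in GROUP_MEDIANS:
        raise ConfigurationError(
            f"unknown group {group_label!r}; choose from {sorted(GROUP_MEDIANS)}"
        )
    if n_cells < 1:
        raise DomainError("n_cells must be >= 1")
    if seed is None:
        raise ConfigurationError("make_group_scene requires an explicit seed")
    rng = np.random.default_rng(seed)
    pitch = 13  # grid pitch in px; > 2*max radius, guarantees separation
    side = int(np.ceil(np.sqrt(n_cells)))
    if shape is None:
        shape = (side * pitch + pitch, side * pitch + pitch)
    sites = [
        (pitch // 2 + r * pitch, pitch // 2 + c * pitch)
        for r in range(side + 1) for c in range(side + 1)
        if pitch // 2 + r * pitch < shape[0] - 5 and pitch // 2 + c * pitch < shape[1] - 5
    ]
    if len(sites) < n_cells:
        raise ConfigurationError(
            f"scene shape {shape} too small for {n_cells} cells"
        )
    order = rng.permutation(len(sites))[:n_cells]
    centers = np.asarray([sites[i] for i in order], dtype=float)
    centers += rng.uniform(-1.5, 1.5, size=centers.shape)
    mask = _pack_cells(shape, centers, rng)
    n_placed = int(mask.max())
    med = GROUP_MEDIANS[group_label]
    truth = pd.DataFrame(
        {
            "cell_id": np.arange(1, n_placed + 1),
            "group": group_label,
            "ratio_free_bound": _draw_lognormal(rng, med["ratio_free_bound"], cv, n_placed),
            "tau_bound_ns": _draw_lognormal(rng, med["tau_bound_ns"], cv, n_placed),
            "flavin_fraction": np.clip(
                _draw_lognormal(rng, med["flavin_fraction"], cv, n_placed), 0.0, 0.95
            ),
            "tau_flavin_ns": _draw_lognormal(rng, med["tau_flavin_ns"], cv, n_placed),
            "flavin_peak_nm": med["flavin_peak_nm"],
            "brightness": brightness,
            "border_distance_um": np.nan,
        }
    )
    return ScenePhantom(
        shape=shape, cell_masks=mask, truth=truth,
        group_label=group_label, pixel_size_um=pixel_size_um,
    )


def make_spheroid_scene(
    radius_um: float = 100.0,
    seed: int | None = None,
    pixel_size_um: float = 2.0,
    brightness: float = 2000.0,
) -> ScenePhantom:
    """Disk of packed cells with radial metabolic gradients.

    Ground-truth parameters follow the deterministic depth profiles in
    :data:`SPHEROID_PROFILE` (linear between depth 0 at the border and
    80 um, constant deeper), so truth profiles are monotone by
    construction.  ``border_distance_um`` is recorded per cell.
    """
    if seed is None:
        raise ConfigurationError("make_spheroid_scene requires an explicit seed")
    rng = np.random.default_rng(seed)
    radius_px = radius_um / pixel_size_um
    margin = 6
    half = int(np.ceil(radius_px)) + margin
    shape = (2 * half + 1, 2 * half + 1)
    if radius_px < 10:
        raise ConfigurationError("spheroid radius too small for the pixel size")
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    disk = np.hypot(yy - half, xx - half) <= radius_px
    pitch = 7  # dense packing so every depth bin holds several cells
    sites = []
    for r in range(pitch // 2, shape[0], pitch):
        for c in range(pitch // 2, shape[1], pitch):
            if np.hypot(r - half, c - half) <= radius_px - 2:
                sites.append((r, c))
    centers = np.asarray(sites, dtype=float) + rng.uniform(-1.0, 1.0, (len(sites), 2))
    mask = _pack_cells(shape, centers, rng, radius_range=(2.2, 3.2))
    mask[~disk] = 0  # border cells are clipped by the spheroid outline
    # relabel contiguously in case clipping removed a cell entirely
    old_labels = np.unique(mask)
    old_labels = old_labels[old_labels > 0]
    relabel = np.zeros(int(mask.max()) + 1, dtype=np.int32)
    relabel[old_labels] = np.arange(1, old_labels.size + 1)
    mask = relabel[mask]
    n_placed = int(mask.max())

    # ground-truth depth: distance from the border to the cell's outer edge,
    # so border-touching cells sit at depth 0
    depths = np.empty(n_placed)
    for lab in range(1, n_placed + 1):
        ys, xs = np.nonzero(mask == lab)
        d_px = radius_px - np.hypot(ys - half, xs - half).max()
        depths[lab - 1] = max(d_px, 0.0) * pixel_size_um

    prof = SPHEROID_PROFILE
    frac = np.clip(depths / prof["max_depth_um"], 0.0, 1.0)

    def ramp(key: str) -> np.ndarray:
        lo, hi = prof[key]
        return lo + (hi - lo) * frac

    ratio = ramp("ratio_free_bound")
    tau_m = ramp("tau_m_nadh_ns")
    # invert the mean-lifetime definition to get the tau_bound realizing the
    # tau_m ramp at the local ratio: tau_m = (r*tau_free + tau_bound)/(r + 1)
    tau_bound = tau_m * (ratio + 1.0) - ratio * TAU_FREE_NS
    truth = pd.DataFrame(
        {
            "cell_id": np.arange(1, n_placed + 1),
            "group": "spheroid",
            "ratio_free_bound": ratio,
            "tau_bound_ns": tau_bound,
            "flavin_fraction": ramp("flavin_fraction"),
            "tau_flavin_ns": ramp("tau_flavin_ns"),
            "flavin_peak_nm": prof["flavin_peak_nm"],
            "brightness": brightness,
            "border_distance_um": depths,
        }
    )
    # consistency: the generated tau_bound must reproduce the tau_m ramp
    check = nadh_mean_lifetime(ratio[0], 1.0, TAU_FREE_NS, tau_bound[0])
    assert abs(check - tau_m[0]) < 1e-9
    return ScenePhantom(
        shape=shape, cell_masks=mask, truth=truth,
        group_label="spheroid", pixel_size_um=pixel_size_um,
        region_mask=disk,
    )
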