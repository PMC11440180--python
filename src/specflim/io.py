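"""Readers and writers for the cube container, masks and tables.

The cube container is a self-describing HDF5 file:

* dataset ``counts`` — uint32 array (rows, cols, channels, time bins);
* root attributes ``period_ns, n_bins, channel_centers_nm, bandwidth_nm,
  irf_fwhm_ns, irf_t0_ns, wraparound, pixel_size_um``;
* group ``provenance`` with free-form string attributes.

Label masks are integer TIFF images; spectra and tables are plain CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from .exceptions import FormatError
from .model import InstrumentModel, SpectralAxis, SpectralTemporalCube, TimeAxis

__all__ = [
    "save_cube",
    "load_cube",
    "save_mask",
    "load_mask",
    "save_parameter_maps",
]


def save_cube(path, cube: SpectralTemporalCube) -> None:
    """Write a cube to the HDF5 container format."""
    inst = cube.instrument
    with h5py.File(path, "w") as f:
        f.create_dataset(
            "counts", data=np.asarray(cube.counts, dtype=np.uint32),
            compression="gzip", compression_opts=4,
        )
        f.attrs["period_ns"] = inst.time.period_ns
        f.attrs["n_bins"] = inst.time.n_bins
        f.attrs["channel_centers_nm"] = inst.spectral.channel_centers_nm
        f.attrs["bandwidth_nm"] = inst.spectral.bandwidth_nm
        f.attrs["irf_fwhm_ns"] = inst.irf_fwhm_ns
        f.attrs["irf_t0_ns"] = inst.irf_t0_ns
        f.attrs["wraparound"] = bool(inst.wraparound)
        f.attrs["pixel_size_um"] = cube.pixel_size_um
        prov = f.create_group("provenance")
        for key, value in dict(cube.provenance).items():
            prov.attrs[key] = (
                value if isinstance(value, (int, float, str, bool))
                else json.dumps(value)
            )


def load_cube(path) -> SpectralTemporalCube:
    """Read a cube from the HDF5 container format."""
    try:
        with h5py.File(path, "r") as f:
            if "counts" not in f:
                raise FormatError(f"{path}: missing 'counts' dataset")
            required = {"period_ns", "n_bins", "channel_centers_nm",
                        "irf_fwhm_ns", "irf_t0_ns"}
            missing = required - set(f.attrs)
            if missing:
                raise FormatError(f"{path}: missing attributes {sorted(missing)}")
            counts = f["counts"][()]
            instrument = InstrumentModel(
                time=TimeAxis(
                    n_bins=int(f.attrs["n_bins"]),
                    period_ns=float(f.attrs["period_ns"]),
                ),
                spectral=SpectralAxis(
                    channel_centers_nm=np.asarray(f.attrs["channel_centers_nm"]),
                    bandwidth_nm=float(f.attrs.get("bandwidth_nm", 12.5)),
                ),
                irf_fwhm_ns=float(f.attrs["irf_fwhm_ns"]),
                irf_t0_ns=float(f.attrs["irf_t0_ns"]),
                wraparound=bool(f.attrs.get("wraparound", True)),
            )
            provenance = (
                dict(f["provenance"].attrs) if "provenance" in f else {}
            )
            return SpectralTemporalCube(
                counts=counts,
                instrument=instrument,
                pixel_size_um=float(f.attrs.get("pixel_size_um", 1.0)),
                provenance=provenance,
            )
    except OSError as exc:
        raise FormatError(f"{path}: not a readable HDF5 container ({exc})") from exc


def save_mask(path, mask: np.ndarray) -> None:
    """Write an integer label image as TIFF."""
    tifffile.imwrite(path, np.asarray(mask, dtype=np.int32))


def load_mask(path) -> np.ndarray:
    """Read an integer label image from TIFF."""
    try:
        mask = tifffile.imread(path)
    except (OSError, ValueError) as exc:
        raise FormatError(f"{path}: not a readable TIFF ({exc})") from exc
    if mask.ndim != 2:
        raise FormatError(f"{path}: label mask must be 2-D, got ndim={mask.ndim}")
    return mask.astype(np.int32)


def save_parameter_maps(path, maps, provenance: dict | None = None) -> None:
    """Write a :class:`~specflim.pipeline.ParameterMaps` bundle to HDF5."""
    with h5py.File(path, "w") as f:
        for name, arr in maps.map_items():
            f.create_dataset(name, data=np.asarray(arr))
        if provenance:
            grp = f.create_group("provenance")
            for key, value in provenance.items():
                grp.attrs[key] = (
                    value if isinstance(value, (int, float, str, bool))
                    else json.dumps(value)
                )


def ensure_new(path: Path, force: bool) -> Path:
    """Refuse to overwrite an existing output unless forced."""
    path = Path(path)
    if path.exists() and not force:
        raise FileExistsError(f"{path} exists; pass --force to overwrite")
    return path
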