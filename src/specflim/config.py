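"""Run configuration: a validated YAML key/value hierarchy.

Unknown keys are rejected so typos fail loudly; the full resolved
configuration (with a content hash and seed) is embedded in every output's
provenance.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml

from .exceptions import ConfigurationError
from .globalfit import ComponentBasis, GlobalFitOptions
from .model import InstrumentModel, SpectralAxis, TimeAxis

__all__ = ["RunConfig"]


def _from_mapping(cls, data: dict, context: str):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigurationError(
            f"unknown keys in {context}: {sorted(unknown)}; known: {sorted(known)}"
        )
    return cls(**data)


@dataclass(frozen=True)
class InstrumentConfig:
    n_bins: int = 256
    period_ns: float = 12.5
    irf_fwhm_ns: float = 0.220
    irf_t0_ns: float | None = None
    wraparound: bool = True
    lambda_min_nm: float = 388.1
    lambda_max_nm: float = 573.6
    n_channels: int = 16
    bandwidth_nm: float = 12.5

    def build(self) -> InstrumentModel:
        return InstrumentModel(
            time=TimeAxis(n_bins=self.n_bins, period_ns=self.period_ns),
            spectral=SpectralAxis(
                channel_centers_nm=np.linspace(
                    self.lambda_min_nm, self.lambda_max_nm, self.n_channels
                ),
                bandwidth_nm=self.bandwidth_nm,
            ),
            irf_fwhm_ns=self.irf_fwhm_ns,
            irf_t0_ns=self.irf_t0_ns,
            wraparound=self.wraparound,
        )


@dataclass(frozen=True)
class BasisConfig:
    spectra_csv: str | None = None  # None -> packaged reference spectra
    tau_free_ns: float = 0.37
    tau_bound_min_ns: float = 0.5
    tau_bound_max_ns: float = 10.0
    tau_flavin_min_ns: float = 0.3
    tau_flavin_max_ns: float = 6.0
    cutoff_nm: float = 490.0

    def build(self, spectral: SpectralAxis) -> ComponentBasis:
        kwargs = dict(
            tau_free_ns=self.tau_free_ns,
            tau_bound_bounds_ns=(self.tau_bound_min_ns, self.tau_bound_max_ns),
            tau_flavin_bounds_ns=(self.tau_flavin_min_ns, self.tau_flavin_max_ns),
            flavin_zero_below_nm=self.cutoff_nm,
        )
        if self.spectra_csv is None:
            return ComponentBasis.default(spectral, **kwargs)
        return ComponentBasis.from_csv(self.spectra_csv, spectral, **kwargs)


@dataclass(frozen=True)
class FitConfig:
    objective: str = "mle"
    bin_parameter: int = 0
    min_photons: float = 2000.0
    multistart: bool = True
    seed: int = 0

    def build(self) -> GlobalFitOptions:
        return GlobalFitOptions(
            objective=self.objective,
            min_photons_global=self.min_photons,
            multistart=self.multistart,
        )


@dataclass(frozen=True)
class ReportConfig:
    reference_group: str = "control"
    depth_bin_um: float = 10.0
    correction: str | None = None


@dataclass(frozen=True)
class RunConfig:
    instrument: InstrumentConfig = field(default_factory=InstrumentConfig)
    basis: BasisConfig = field(default_factory=BasisConfig)
    fit: FitConfig = field(default_factory=FitConfig)
    report: ReportConfig = field(default_factory=ReportConfig)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigurationError(f"{path}: top level must be a mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(
                f"unknown config blocks {sorted(unknown)}; known: {sorted(known)}"
            )
        return cls(
            instrument=_from_mapping(
                InstrumentConfig, raw.get("instrument", {}), "instrument"
            ),
            basis=_from_mapping(BasisConfig, raw.get("basis", {}), "basis"),
            fit=_from_mapping(FitConfig, raw.get("fit", {}), "fit"),
            report=_from_mapping(ReportConfig, raw.get("report", {}), "report"),
        )

    def to_dict(self) -> dict:
        return asdict(self)

    def content_hash(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]

    def provenance(self, **extra) -> dict:
        prov = {"config_hash": self.content_hash(), "config": self.to_dict()}
        prov.update(extra)
        return prov
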