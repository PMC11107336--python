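"""Run configuration, seeding, and serialization glue.

A :class:`RunConfig` bundles every parameter of a simulation run — phantom,
bundle, per-mode acquisition, scan sequence, restoration, and analysis — and
is fully serializable to YAML or JSON. One global seed deterministically
derives independent per-stage substreams via ``SeedSequence([global, stage])``
so stages can be rerun in isolation and still reproduce.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .acquisition import AcquisitionConfig
from .analyze import DetectParams
from .restore import ProcessParams

# fixed stage indices for substream derivation (order is part of the contract)
STAGES = {"phantom": 0, "specular": 1, "noise": 2, "analysis": 3}


def derive_seed(global_seed: int, stage: str) -> int:
    """Per-stage 31-bit seed derived from the global seed."""
    if stage not in STAGES:
        raise KeyError(f"unknown stage {stage!r}; expected one of {sorted(STAGES)}")
    ss = np.random.SeedSequence([int(global_seed), STAGES[stage]])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class PhantomParams:
    field_extent_um: float = 820.0
    pixel_pitch_um: float = 1.0
    density_per_mm2: float = 800.0
    mean_radius_um: float = 4.0
    radius_cv: float = 0.1
    eccentricity_max: float = 0.3
    min_spacing_um: float = 18.0
    nuclear_optical_depth: float = 0.8
    background_optical_depth: float = 0.05
    nuclear_fluor_yield: float = 1.0
    background_fluor_yield: float = 0.02
    diffuse_reflectance: float = 0.6


@dataclass
class BundleParams:
    fov_diameter_um: float = 790.0
    core_pitch_um: float = 4.5
    core_radius_um: float = 1.6
    fill_transmission: float = 1.0
    cladding_level: float = 0.25


@dataclass
class ScanParams:
    band_height_rows: int = 16
    offset_rows: int = 4
    line_width_rows: int = 8


@dataclass
class AnalysisParams:
    n_rois: int = 25  # 5x5 grid of congruent ROIs inside the FOV
    roi_size_um: float = 100.0
    match_tolerance_um: float = 4.0  # = mean nuclear radius


@dataclass
class RunConfig:
    phantom: PhantomParams = field(default_factory=PhantomParams)
    bundle: BundleParams = field(default_factory=BundleParams)
    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    scan: ScanParams = field(default_factory=ScanParams)
    processing: ProcessParams = field(default_factory=ProcessParams)
    detection: DetectParams = field(default_factory=DetectParams)
    analysis: AnalysisParams = field(default_factory=AnalysisParams)
    seed: int = 0
    output_dir: str = "out"
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        """Stable hash of the fully resolved configuration."""
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        def build(klass, key):
            sub = d.get(key, {}) or {}
            names = {f.name for f in dataclasses.fields(klass)}
            unknown = set(sub) - names
            if unknown:
                raise ValueError(f"unknown field(s) in '{key}': {sorted(unknown)}")
            return klass(**sub)

        cfg = cls(
            phantom=build(PhantomParams, "phantom"),
            bundle=build(BundleParams, "bundle"),
            acquisition=build(AcquisitionConfig, "acquisition"),
            scan=build(ScanParams, "scan"),
            processing=build(ProcessParams, "processing"),
            detection=build(DetectParams, "detection"),
            analysis=build(AnalysisParams, "analysis"),
        )
        for key in ("seed", "output_dir", "log_level"):
            if key in d and d[key] is not None:
                setattr(cfg, key, d[key])
        return cfg

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        """Load a YAML (or JSON — valid YAML) configuration file."""
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        return cls.from_dict(data)
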