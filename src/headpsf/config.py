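"""Run configuration: every tunable of the head-model comparison pipeline.

Defaults reproduce the benchmark study conditions: radii proportions
1 : 0.95 : 0.87 : 0.84, conductivities 0.33 / 0.0042 / 1.79 / 0.33 S/m,
62 electrodes, 5000 cortical source points, 26 probe sources, BEM surfaces
at 1500 vertices, FDM grid at 2 mm.  Round-trips losslessly through YAML.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass
class RunConfig:
    # geometry
    outer_radius: float = 92.0
    radii_ratios: tuple = (1.0, 0.95, 0.87, 0.84)
    conductivities: tuple = (0.33, 0.0042, 1.79, 0.33)
    deformation: float = 0.0  # relative amplitude; 0 = exact spheres
    seed: int = 0
    # counts
    n_sensors: int = 62
    n_sources: int = 5000
    n_probes: int = 26
    # solver settings
    bem_vertices: int = 1500
    bem_ipa: bool = True
    fdm_spacing: float = 2.0
    fdm_tol: float = 1e-8
    sphere_n_terms: int = 200
    patch_radius: float = 40.0
    # analysis settings
    smoothing_fwhm: float = 10.0
    source_depth: float = 0.08
    models: tuple = ("SPH", "BEM", "FDM")

    def __post_init__(self) -> None:
        self.radii_ratios = tuple(float(x) for x in self.radii_ratios)
        self.conductivities = tuple(float(x) for x in self.conductivities)
        self.models = tuple(self.models)


def load_config(path: str | Path) -> RunConfig:
    with open(path) as f:
        data = yaml.safe_load(f) or {}
    return RunConfig(**data)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    data = asdict(cfg)
    # YAML-friendly plain lists
    for k, v in data.items():
        if isinstance(v, tuple):
            data[k] = list(v)
    with open(path, "w") as f:
        yaml.safe_dump(data, f, sort_keys=False)
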