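"""Pipeline configuration: one serialisable object, one seed.

YAML is the native format; JSON is accepted transparently. Defaults are
the package's reference values (material: E = 0.7 MPa, nu = 0.45,
rho = 1095 kg/m^3; loading 50 -> 77 mmHg in 10 steps; 2 mm wall in two
layers at ~1 mm element sizing).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


@dataclass
class AnatomyConfig:
    n_cases: int = 12
    neck_radius: float = 11.0
    total_length: float = 120.0
    bulge_center: float = 60.0
    wall_thickness: float = 2.0
    voxel_size: float = 1.0
    noise_sd: float = 0.1
    make_phantoms: bool = False


@dataclass
class ReconstructConfig:
    threshold_lo: float = 0.5
    threshold_hi: float | None = None  # None = no upper bound
    connectivity: int = 26
    field_sigma: float = 1.0
    smooth_iterations: int = 10
    smooth_lambda: float = 0.5
    smooth_mu: float = -0.53


@dataclass
class MeshConfig:
    element_size: float = 1.0
    n_layers: int = 2


@dataclass
class MaterialConfig:
    young_modulus_mpa: float = 0.7
    poisson_ratio: float = 0.45
    density: float = 1095.0


@dataclass
class LoadConfig:
    p_dias_low: float = 80.0
    p_sys_low: float = 130.0
    p_dias_high: float = 123.0
    p_sys_high: float = 230.0
    delta_p_first: float = 50.0
    delta_p_final: float = 77.0
    n_steps: int = 10


@dataclass
class SolverConfig:
    method: str = "direct"  # or "cg"
    tolerance: float = 1e-10


@dataclass
class PipelineConfig:
    anatomy: AnatomyConfig = field(default_factory=AnatomyConfig)
    reconstruct: ReconstructConfig = field(default_factory=ReconstructConfig)
    mesh: MeshConfig = field(default_factory=MeshConfig)
    material: MaterialConfig = field(default_factory=MaterialConfig)
    load: LoadConfig = field(default_factory=LoadConfig)
    solver: SolverConfig = field(default_factory=SolverConfig)
    output_dir: str = "aneufem_out"
    seed: int = 0

    # -- serialisation ----------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        kwargs: dict = {}
        for f in dataclasses.fields(cls):
            if f.name not in d:
                continue
            v = d[f.name]
            if dataclasses.is_dataclass(f.type) or f.name in (
                "anatomy", "reconstruct", "mesh", "material", "load", "solver"
            ):
                sub = {
                    "anatomy": AnatomyConfig,
                    "reconstruct": ReconstructConfig,
                    "mesh": MeshConfig,
                    "material": MaterialConfig,
                    "load": LoadConfig,
                    "solver": SolverConfig,
                }[f.name]
                kwargs[f.name] = sub(**v)
            else:
                kwargs[f.name] = v
        return cls(**kwargs)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        try:
            data = json.loads(text)  # YAML 1.1 would misread e.g. "1e-10"
        except json.JSONDecodeError:
            data = yaml.safe_load(text)
        return cls.from_dict(data)

    def save(self, path: str | Path) -> None:
        p = Path(path)
        if p.suffix == ".json":
            p.write_text(json.dumps(self.to_dict(), indent=1))
        else:
            p.write_text(self.to_yaml())

    # -- bridges to domain objects ----------------------------------------

    def material_model(self):
        from .fem_solver import MaterialModel

        return MaterialModel(
            young_modulus=self.material.young_modulus_mpa * 1e6,
            poisson_ratio=self.material.poisson_ratio,
            density=self.material.density,
        )

    def load_case(self):
        from .fem_solver import LoadCase

        return LoadCase(
            p_dias_low=self.load.p_dias_low,
            p_sys_low=self.load.p_sys_low,
            p_dias_high=self.load.p_dias_high,
            p_sys_high=self.load.p_sys_high,
            delta_p_first=self.load.delta_p_first,
            delta_p_final=self.load.delta_p_final,
            n_steps=self.load.n_steps,
        )
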