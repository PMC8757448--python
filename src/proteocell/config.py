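"""Schema-validated run configuration (YAML or JSON).

Keys carry SI-unit suffixes; unknown keys are rejected so typos fail loudly.
Every CLI run writes the fully resolved configuration next to its outputs.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Literal, Optional

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field

from .cell_model import CellParams, cell_capacity
from .coupling import Scenario, TransferFunction
from .geometry import WellGeometry
from .protein_fit import GridSpec
from .protein_model import GridControls, ProteinParams
from .synthetic import NoiseSpec


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GeometryConfig(_Strict):
    fluid_volume_uL: float = 200.0
    disk_diameter_mm: float = 6.0

    def build(self) -> WellGeometry:
        return WellGeometry(self.fluid_volume_uL, self.disk_diameter_mm)


class ProteinConfig(_Strict):
    k_a_mL_per_ug_h: float = 6.2e-4
    k_d_per_h: float = 0.2
    c_s_max_ug_per_mm2: float = 31.5
    D_mm2_per_h: float = 0.3

    def build(self) -> ProteinParams:
        return ProteinParams(
            self.k_a_mL_per_ug_h, self.k_d_per_h,
            self.c_s_max_ug_per_mm2, self.D_mm2_per_h,
        )


class SolverConfig(_Strict):
    n_cells: int = 200
    dt_h: float = 0.05

    def build(self) -> GridControls:
        return GridControls(n_cells=self.n_cells, dt_h=self.dt_h)


class FitGridConfig(_Strict):
    k_a_min: float = 2.5e-4
    k_a_max: float = 12.5e-4
    k_a_count: int = 20
    k_d_min: float = 0.01
    k_d_max: float = 0.20
    k_d_count: int = 20

    def build(self) -> GridSpec:
        return GridSpec(
            k_a_values=tuple(np.linspace(self.k_a_min, self.k_a_max, self.k_a_count)),
            k_d_values=tuple(np.linspace(self.k_d_min, self.k_d_max, self.k_d_count)),
        )


class CellConfig(_Strict):
    gamma: float = 0.63
    c_0_cells_per_cm2: float = 3500.0
    cell_side_um: float = 25.0
    k_cm2_per_cell_h: Optional[float] = None

    def build(self) -> CellParams:
        return CellParams(
            gamma=self.gamma,
            c_0=self.c_0_cells_per_cm2,
            c_m=cell_capacity(self.cell_side_um),
            k=self.k_cm2_per_cell_h,
        )


class TransferConfig(_Strict):
    a_cm2_per_cell_h: float = 1.32e-5
    b_mm2_per_ug: float = 0.213
    form: Literal["exponential", "hyperbolic"] = "exponential"

    def build(self) -> TransferFunction:
        return TransferFunction(self.a_cm2_per_cell_h, self.b_mm2_per_ug, self.form)


class ScenarioConfig(_Strict):
    pre_incubation_h: float = 0.0
    culture_duration_h: float = 6.0

    def build(self, cfg: "RunConfig") -> Scenario:
        return Scenario(
            pre_incubation_h=self.pre_incubation_h,
            culture_duration_h=self.culture_duration_h,
            protein=cfg.protein.build(),
            geometry=cfg.geometry.build(),
            initial_fluid=cfg.initial_fluid_ug_per_mL,
            cell=cfg.cell.build(),
        )


class NoiseConfig(_Strict):
    kind: Literal[
        "multiplicative-gaussian", "additive-gaussian", "poisson-counts"
    ] = "multiplicative-gaussian"
    magnitude: float = 0.05
    replicates: int = 3

    def build(self, seed: int) -> NoiseSpec:
        return NoiseSpec(
            kind=self.kind, magnitude=self.magnitude,
            replicates=self.replicates, seed=seed,
        )


class ScheduleConfig(_Strict):
    protein_h: List[float] = Field(
        default_factory=lambda: [2.0, 4.0, 6.0, 8.0, 24.0, 48.0, 72.0]
    )
    culture_h: List[float] = Field(default_factory=lambda: [0.5, 1.0, 2.0, 4.0, 6.0])


class RunConfig(_Strict):
    """Top-level configuration of a pipeline run."""

    seed: int = 0
    output_dir: str = "proteocell_out"
    initial_fluid_ug_per_mL: float = 9500.0
    geometry: GeometryConfig = GeometryConfig()
    protein: ProteinConfig = ProteinConfig()
    solver: SolverConfig = SolverConfig()
    fit_grid: FitGridConfig = FitGridConfig()
    cell: CellConfig = CellConfig()
    transfer: TransferConfig = TransferConfig()
    scenarios: List[ScenarioConfig] = Field(
        default_factory=lambda: [
            ScenarioConfig(pre_incubation_h=p) for p in (0.0, 24.0, 48.0)
        ]
    )
    schedules: ScheduleConfig = ScheduleConfig()
    noise: NoiseConfig = NoiseConfig()

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        return cls.model_validate(data or {})

    def dump(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.model_dump(), sort_keys=False)
        )
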