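"""Synthetic measurement series with the statistical structure of the
adsorption/desorption and adhesion experiments.

The generators emulate the study design: triplicate fluid-phase protein
concentrations sampled at 2-72 h during adsorption and desorption of a
~9,500 ug/mL albumin solution, and areal attached-cell counts at 0.5-6 h
for a seeding density of 3,500 cells/cm^2.  Replicate scatter is
multiplicative Gaussian by default (CV 5%, matching the relative error
bars of the assays); additive-Gaussian and Poisson-count modes are
available.  Every series carries its noiseless ground truth so parameter
recovery is self-describing, and all randomness flows from one explicit
seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .cell_model import CellParams, attached_cells_analytic
from .coupling import Scenario, TransferFunction, coupled_attached_cells
from .geometry import WellGeometry, DEFAULT_GEOMETRY
from .protein_fit import DEFAULT_PROTEIN_SCHEDULE
from .protein_model import GridControls, ProteinParams, solve_protein_kinetics
from .series import MeasurementSeries

__all__ = [
    "NoiseSpec",
    "generate_protein_series",
    "generate_cell_counts",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Replicate-noise description.

    kind : "multiplicative-gaussian" (magnitude = CV), "additive-gaussian"
        (magnitude = SD in data units) or "poisson-counts" (magnitude
        ignored; counting noise from the imaged field of view).
    replicates : independent replicates per time point; the series stores
        their mean and sample SD.
    seed : seed for the dedicated random generator.
    fov_area_mm2 : imaged area used to scale densities to integer counts in
        Poisson mode.
    """

    kind: str = "multiplicative-gaussian"
    magnitude: float = 0.05
    replicates: int = 3
    seed: int = 0
    fov_area_mm2: float = 1.4

    def __post_init__(self) -> None:
        if self.kind not in (
            "multiplicative-gaussian", "additive-gaussian", "poisson-counts"
        ):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.magnitude < 0:
            raise ValueError("noise magnitude must be non-negative")
        if self.replicates < 1:
            raise ValueError("at least one replicate is required")

    def apply(self, truth: np.ndarray, rng: np.random.Generator,
              counts: bool = False) -> tuple[np.ndarray, np.ndarray]:
        """Noisy replicate means and SDs for a truth vector."""
        truth = np.asarray(truth, dtype=float)
        n = truth.size
        if self.kind == "multiplicative-gaussian":
            reps = truth[None, :] * (
                1.0 + self.magnitude * rng.standard_normal((self.replicates, n))
            )
        elif self.kind == "additive-gaussian":
            reps = truth[None, :] + self.magnitude * rng.standard_normal(
                (self.replicates, n)
            )
        else:  # poisson-counts: density -> expected count in the FOV -> back
            if not counts:
                raise ValueError("poisson-counts noise applies to cell counts only")
            per_fov = truth[None, :] * self.fov_area_mm2 / 100.0  # cells/cm^2 -> per FOV
            reps = rng.poisson(np.broadcast_to(per_fov, (self.replicates, n)))
            reps = reps * 100.0 / self.fov_area_mm2
        reps = np.clip(reps, 0.0, None)
        sd = reps.std(axis=0, ddof=1) if self.replicates > 1 else np.zeros(n)
        return reps.mean(axis=0), sd

    def manifest(self) -> dict:
        return asdict(self)


def generate_protein_series(
    params: ProteinParams,
    geometry: WellGeometry = DEFAULT_GEOMETRY,
    scenario: str = "adsorption",
    schedule: Sequence[float] = DEFAULT_PROTEIN_SCHEDULE,
    noise: NoiseSpec = NoiseSpec(),
    initial_fluid: float = 9500.0,
    initial_surface: Optional[float] = None,
    grid: GridControls = GridControls(n_cells=60, dt_h=0.1),
) -> MeasurementSeries:
    """Synthetic depth-averaged fluid concentrations for one experiment.

    scenario "adsorption": uniform ``initial_fluid`` over a bare surface.
    scenario "desorption": protein-free medium over a coverage of
    ``initial_surface`` (default: the adsorption end state after 72 h).

    The returned series' ``truth`` attribute holds the noiseless model
    output at the schedule.
    """
    schedule = np.asarray(schedule, dtype=float)
    if scenario == "adsorption":
        init_f, init_s = initial_fluid, 0.0
    elif scenario == "desorption":
        if initial_surface is None:
            ads = solve_protein_kinetics(
                params, geometry, initial_fluid, 0.0,
                t_end=float(schedule[-1]), output_times=[schedule[-1]], grid=grid,
            )
            initial_surface = float(ads.c_surface[-1])
        init_f, init_s = 0.0, float(initial_surface)
    else:
        raise ValueError("scenario must be 'adsorption' or 'desorption'")

    traj = solve_protein_kinetics(
        params, geometry, init_f, init_s,
        t_end=float(schedule[-1]), output_times=schedule, grid=grid,
    )
    truth = np.interp(schedule, traj.times, traj.mean_fluid)
    rng = np.random.default_rng(noise.seed)
    values, sd = noise.apply(truth, rng)
    return MeasurementSeries(
        times=schedule, values=values, sd=sd, label=scenario, truth=truth
    )


def generate_cell_counts(
    params: CellParams,
    k: Optional[float] = None,
    tf: Optional[TransferFunction] = None,
    scenario: Optional[Scenario] = None,
    schedule: Sequence[float] = (0.5, 1.0, 2.0, 4.0, 6.0),
    noise: NoiseSpec = NoiseSpec(),
) -> MeasurementSeries:
    """Synthetic attached-cell counts at the imaging schedule.

    Either a constant adhesion coefficient ``k`` or a transfer function
    plus pre-incubation scenario (protein-coupled rate) must be given.
    """
    schedule = np.asarray(schedule, dtype=float)
    if tf is not None:
        if scenario is None:
            raise ValueError("a Scenario is required with a transfer function")
        traj = coupled_attached_cells(scenario, tf, t_culture=schedule)
        truth = traj.attached
    else:
        rate = k if k is not None else params.k
        if rate is None:
            raise ValueError("a constant rate k or a transfer function is required")
        truth = attached_cells_analytic(schedule, params, K=rate * schedule)
    rng = np.random.default_rng(noise.seed)
    values, sd = noise.apply(truth, rng, counts=True)
    return MeasurementSeries(
        times=schedule, values=values, sd=sd, label="cell_culture", truth=truth
    )


def write_manifest(path: str | Path, noise: NoiseSpec, **params) -> None:
    """Record generator parameters and seed next to a synthetic dataset."""
    payload = {"noise": noise.manifest(), **params}
    Path(path).write_text(json.dumps(payload, indent=2, default=str))
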