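"""Grid-search estimation of the Langmuir rate constants (k_a, k_d).

The adsorption and desorption experiments are fitted jointly: for every
candidate (k_a, k_d) pair the monolayer capacity c_s_max is derived from
the observed steady state, both experiments are simulated forward, and the
relative-RMS errors of the two runs are added.  The pair with the smallest
summed error wins (exhaustive evaluation, deterministic tie-breaking).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .geometry import WellGeometry, DEFAULT_GEOMETRY
from .protein_model import (
    GridControls,
    ProteinParams,
    SteadyState,
    _simulate_batch,
    steady_state_capacity,
    solve_protein_kinetics,
)
from .series import MeasurementSeries

__all__ = [
    "DEFAULT_PROTEIN_SCHEDULE",
    "GridSpec",
    "GridFitResult",
    "LangmuirGridSearch",
    "model_error",
    "grid_fit_protein",
]

#: default comparison/sampling schedule for protein measurements, hours
DEFAULT_PROTEIN_SCHEDULE = (2.0, 4.0, 6.0, 8.0, 24.0, 48.0, 72.0)


def model_error(predicted: Sequence[float], observed: MeasurementSeries,
                mask: Optional[np.ndarray] = None) -> float:
    """Percent error between model prediction and measurement.

    Root-mean-square of the pointwise relative deviations, times 100::

        100 * sqrt( (1/N) * sum_i ((p_i - o_i) / o_i)^2 )

    Zero iff the series agree exactly; invariant under joint positive
    scaling of both series.

    Parameters
    ----------
    predicted : array-like
        Model values aligned one-to-one with ``observed.times``.
    observed : MeasurementSeries
    mask : bool array, optional
        Points to include; observed zeros must be masked out explicitly,
        otherwise the relative error is undefined and an error is raised.
    """
    p = np.asarray(predicted, dtype=float)
    o = observed.values
    if p.shape != o.shape:
        raise ValueError(f"predicted shape {p.shape} != observed shape {o.shape}")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        p, o = p[mask], o[mask]
    if p.size == 0:
        raise ValueError("no points left to compare")
    if np.any(o == 0):
        raise ValueError("observed value is zero at a compared point; mask it explicitly")
    return float(100.0 * np.sqrt(np.mean(((p - o) / o) ** 2)))


@dataclass(frozen=True)
class GridSpec:
    """Candidate grids for the exhaustive (k_a, k_d) search.

    Defaults: 20 equally spaced k_a values over (2.5-12.5)e-4 mL/(ug*h)
    (step ~0.53e-4) and 20 k_d values over 0.01-0.20 1/h (step 0.01),
    i.e. 400 candidate pairs.
    """

    k_a_values: tuple = tuple(np.linspace(2.5e-4, 12.5e-4, 20))
    k_d_values: tuple = tuple(np.round(np.arange(1, 21) * 0.01, 10))

    def __post_init__(self) -> None:
        if len(self.k_a_values) < 1 or len(self.k_d_values) < 1:
            raise ValueError("grids must be non-empty")

    @property
    def n_candidates(self) -> int:
        return len(self.k_a_values) * len(self.k_d_values)


@dataclass
class GridFitResult:
    """Outcome of the exhaustive grid search."""

    k_a: float
    k_d: float
    c_s_max: float
    error_percent: float
    error_surface: pd.DataFrame  # columns k_a, k_d, error_percent
    grid: GridSpec

    def to_json_dict(self) -> dict:
        return {
            "k_a_mL_per_ug_h": self.k_a,
            "k_d_per_h": self.k_d,
            "c_s_max_ug_per_mm2": self.c_s_max,
            "error_percent": self.error_percent,
        }


class LangmuirGridSearch(BaseEstimator):
    """Exhaustive grid-search fit of Langmuir adsorption/desorption constants.

    For each candidate pair the capacity is tied to the observed adsorption
    steady state (c^f = last adsorption value, c_s^f = the areal density of
    the total depletion), an adsorption run from the uniform initial
    concentration and a desorption run from the adsorbed state into
    protein-free medium are simulated, and the two relative-RMS errors are
    summed.  Ties are broken toward smaller k_d, then smaller k_a.

    Parameters
    ----------
    grid : GridSpec
        Candidate (k_a, k_d) values.
    geometry : WellGeometry
    D : float
        Fluid diffusion coefficient, mm^2/h.
    initial_fluid : float
        Fluid concentration at the start of the adsorption experiment,
        ug/mL.
    grid_controls : GridControls
        PDE discretisation used for the forward runs inside the search.

    Attributes
    ----------
    k_a_, k_d_ : float
        Best-fitting rate constants.
    c_s_max_ : float
        Capacity derived from the steady state at the best point.
    error_percent_ : float
        Summed adsorption+desorption error at the best point.
    error_surface_ : pandas.DataFrame
        Exhaustive error surface (k_a, k_d, error_percent); failed
        simulations are recorded with error = +inf, never dropped.
    result_ : GridFitResult
    """

    def __init__(
        self,
        grid: GridSpec = GridSpec(),
        geometry: WellGeometry = DEFAULT_GEOMETRY,
        D: float = 0.3,
        initial_fluid: float = 9500.0,
        grid_controls: GridControls = GridControls(n_cells=60, dt_h=0.1),
    ):
        self.grid = grid
        self.geometry = geometry
        self.D = D
        self.initial_fluid = initial_fluid
        self.grid_controls = grid_controls

    # -- internal -----------------------------------------------------------

    def _endpoints(self, adsorption: MeasurementSeries) -> SteadyState:
        c_f = float(adsorption.values[-1])
        c_s_f = self.geometry.fluid_to_surface(self.initial_fluid - c_f)
        if c_s_f <= 0:
            raise ValueError(
                "adsorption series shows no depletion; steady-state coverage "
                "would be non-positive"
            )
        return SteadyState(c_final=c_f, c_s_final=c_s_f)

    def fit(self, adsorption: MeasurementSeries, desorption: MeasurementSeries):
        """Run the exhaustive search against the two measurement series."""
        if adsorption.n_points < 1 or desorption.n_points < 1:
            raise ValueError("both series must be non-empty")
        steady = self._endpoints(adsorption)

        ka_grid, kd_grid = np.meshgrid(
            np.asarray(self.grid.k_a_values, float),
            np.asarray(self.grid.k_d_values, float),
            indexing="ij",
        )
        ka = ka_grid.ravel()
        kd = kd_grid.ravel()
        csm = steady.c_s_final * (1.0 + kd / (ka * steady.c_final))

        errors = np.full(ka.size, np.inf)
        ok = np.ones(ka.size, dtype=bool)
        try:
            ads_mean, _, _ = _simulate_batch(
                ka, kd, csm, self.D, self.geometry,
                self.initial_fluid, 0.0, adsorption.times, self.grid_controls,
            )
            des_mean, _, _ = _simulate_batch(
                ka, kd, csm, self.D, self.geometry,
                0.0, steady.c_s_final, desorption.times, self.grid_controls,
            )
        except Exception:
            # batch path failed as a whole: fall back to per-candidate runs so
            # a single pathological pair cannot sink the search
            ads_mean = np.empty((ka.size, adsorption.n_points))
            des_mean = np.empty((ka.size, desorption.n_points))
            for i in range(ka.size):
                try:
                    a, _, _ = _simulate_batch(
                        ka[i], kd[i], csm[i], self.D, self.geometry,
                        self.initial_fluid, 0.0, adsorption.times,
                        self.grid_controls,
                    )
                    d, _, _ = _simulate_batch(
                        ka[i], kd[i], csm[i], self.D, self.geometry,
                        0.0, steady.c_s_final, desorption.times,
                        self.grid_controls,
                    )
                    ads_mean[i], des_mean[i] = a[0], d[0]
                except Exception:
                    ok[i] = False

        for i in np.nonzero(ok)[0]:
            errors[i] = model_error(ads_mean[i], adsorption) + model_error(
                des_mean[i], desorption
            )

        # deterministic winner: smallest error, ties to smaller k_d then k_a
        order = np.lexsort((ka, kd, errors))
        best = order[0]
        if not np.isfinite(errors[best]):
            raise RuntimeError("every grid point failed to simulate")

        surface = pd.DataFrame(
            {"k_a": ka, "k_d": kd, "error_percent": errors}
        )
        self.k_a_ = float(ka[best])
        self.k_d_ = float(kd[best])
        self.c_s_max_ = float(csm[best])
        self.error_percent_ = float(errors[best])
        self.error_surface_ = surface
        self.steady_state_ = steady
        self.result_ = GridFitResult(
            k_a=self.k_a_,
            k_d=self.k_d_,
            c_s_max=self.c_s_max_,
            error_percent=self.error_percent_,
            error_surface=surface,
            grid=self.grid,
        )
        return self

    def predict(self, times: Sequence[float], scenario: str = "adsorption") -> np.ndarray:
        """Depth-averaged fluid concentration at ``times`` for the fitted
        parameters, for either experiment ('adsorption' or 'desorption')."""
        if not hasattr(self, "k_a_"):
            raise RuntimeError("estimator is not fitted")
        params = ProteinParams(self.k_a_, self.k_d_, self.c_s_max_, self.D)
        times = np.asarray(times, dtype=float)
        if scenario == "adsorption":
            init_fluid, init_surf = self.initial_fluid, 0.0
        elif scenario == "desorption":
            init_fluid, init_surf = 0.0, self.steady_state_.c_s_final
        else:
            raise ValueError("scenario must be 'adsorption' or 'desorption'")
        traj = solve_protein_kinetics(
            params, self.geometry, init_fluid, init_surf,
            t_end=float(times[-1]), output_times=times, grid=self.grid_controls,
        )
        return np.interp(times, traj.times, traj.mean_fluid)


def grid_fit_protein(
    adsorption: MeasurementSeries,
    desorption: MeasurementSeries,
    geometry: WellGeometry = DEFAULT_GEOMETRY,
    D: float = 0.3,
    grid_spec: GridSpec = GridSpec(),
    initial_fluid: float = 9500.0,
    grid_controls: GridControls = GridControls(n_cells=60, dt_h=0.1),
) -> GridFitResult:
    """Functional wrapper over :class:`LangmuirGridSearch`."""
    est = LangmuirGridSearch(
        grid=grid_spec, geometry=geometry, D=D,
        initial_fluid=initial_fluid, grid_controls=grid_controls,
    )
    est.fit(adsorption, desorption)
    return est.result_
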