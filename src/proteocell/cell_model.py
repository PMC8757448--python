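"""Two-compartment osteoblast attachment kinetics.

Seeded cells either sit in a "free" layer above the substrate or are
attached to it.  With gamma the fraction of seeded cells that reach the
surface in a viable state, c_0 the seeded density and c_m the monolayer
capacity of the surface, the closed system

    dc_free/dt = -dc_a/dt
    dc_a/dt    = k(t) * c_free * (c_m - c_a)
    c_free(0)  = gamma * c_0,   c_a(0) = 0

has the logistic-type closed form (K(t) = integral of k up to t)

    c_a(K) = A * M * (exp((M - A) K) - 1) / (M * exp((M - A) K) - A)

with A = gamma*c_0 and M = c_m, so all viable cells end up attached
(c_a -> A) whenever A < M.  Attached cells never detach and do not
proliferate on the time scale modelled (minutes to hours): both effects
are absent structurally, not merely parameterised to zero.

The adhesion coefficient k may be a constant (fitted per experiment) or a
function of time via the protein coupling (see :mod:`proteocell.coupling`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import minimize_scalar
from sklearn.base import BaseEstimator

from .protein_fit import model_error
from .series import MeasurementSeries

__all__ = [
    "CellParams",
    "CellTrajectory",
    "DEFAULT_CULTURE_SCHEDULE",
    "cell_capacity",
    "attached_cells_analytic",
    "attached_cells_numeric",
    "estimate_gamma",
    "fit_k_constant",
    "AdhesionRateFit",
    "SaturationWarning",
]

#: imaging schedule of the adhesion experiments, hours after seeding
DEFAULT_CULTURE_SCHEDULE = (0.5, 1.0, 2.0, 4.0, 6.0)


class SaturationWarning(UserWarning):
    """Fitted data carry no information about the adhesion rate."""


def cell_capacity(cell_side_um: float = 25.0) -> float:
    """Monolayer capacity (cells/cm^2) for cells spreading to squares of a
    given side length (um).  25 um -> 1.6e5 cells/cm^2."""
    if cell_side_um <= 0:
        raise ValueError("cell_side_um must be positive")
    side_cm = cell_side_um * 1e-4
    return 1.0 / side_cm**2


@dataclass(frozen=True)
class CellParams:
    """Parameters of the attachment model.

    gamma : viable (adhesion-competent) fraction of seeded cells, in (0, 1];
        estimated values above 1 are kept with a warning.
    c_0 : seeded density, cells/cm^2.
    c_m : monolayer capacity of the surface, cells/cm^2.
    k : constant adhesion coefficient, cm^2 cells^-1 h^-1 (optional; the
        coupled pipeline supplies a time-dependent rate instead).
    """

    gamma: float = 0.63
    c_0: float = 3500.0
    c_m: float = cell_capacity(25.0)
    k: Optional[float] = None

    def __post_init__(self) -> None:
        if not (self.gamma > 0):
            raise ValueError("gamma must be positive")
        if self.gamma > 1:
            warnings.warn(
                f"gamma = {self.gamma:.3f} > 1: more viable cells than seeded",
                UserWarning,
                stacklevel=2,
            )
        if self.c_0 <= 0 or self.c_m <= 0:
            raise ValueError("densities must be positive")
        if self.k is not None and self.k < 0:
            raise ValueError("adhesion coefficient must be non-negative")

    @property
    def viable(self) -> float:
        """Viable seeded density gamma * c_0, cells/cm^2."""
        return self.gamma * self.c_0


@dataclass
class CellTrajectory:
    """Free and attached cell densities over time (closed system:
    free + attached = gamma * c_0 at all times)."""

    times: np.ndarray  # h
    attached: np.ndarray  # cells/cm^2
    free: np.ndarray  # cells/cm^2


def attached_cells_analytic(t, params: CellParams,
                            K: Optional[np.ndarray] = None) -> np.ndarray:
    """Closed-form attached density c_a at times ``t``.

    Parameters
    ----------
    t : float or array
        Culture times, h.
    params : CellParams
        ``params.k`` is used as the constant rate when ``K`` is omitted.
    K : float or array, optional
        Cumulative adhesion exposure integral of k over [0, t]
        (cm^2 cells^-1 h^-1 * h); overrides the constant-rate product k*t.
        Must be non-negative and aligned with ``t``.

    Notes
    -----
    Evaluated in overflow-safe form; the degenerate case gamma*c_0 = c_m
    uses the exact limit M - M / (1 + M K).
    """
    t = np.asarray(t, dtype=float)
    if K is None:
        if params.k is None:
            raise ValueError("either a constant params.k or an exposure K is required")
        K = params.k * t
    K = np.asarray(K, dtype=float)
    if np.any(K < -1e-15):
        raise ValueError("cumulative exposure K must be non-negative")
    K = np.clip(K, 0.0, None)
    A = params.viable
    M = params.c_m
    if A > M * (1 + 1e-12):
        raise ValueError(
            f"viable density gamma*c_0 = {A:.3g} exceeds surface capacity "
            f"c_m = {M:.3g}; model assumptions violated"
        )
    if np.isclose(A, M, rtol=1e-12):
        return M - M / (1.0 + M * K)
    # c_a = A M (e^{(M-A)K} - 1) / (M e^{(M-A)K} - A), written with decaying
    # exponentials so large exposures cannot overflow
    e = np.exp(-(M - A) * K)
    return A * (1.0 - e) / (1.0 - (A / M) * e)


def attached_cells_numeric(
    params: CellParams,
    k: Callable[[float], float] | float | None = None,
    t_grid: Sequence[float] = DEFAULT_CULTURE_SCHEDULE,
    rtol: float = 1e-10,
    atol: float = 1e-8,
) -> CellTrajectory:
    """Direct adaptive ODE integration of the two-compartment system.

    Independent oracle for :func:`attached_cells_analytic`; conservation
    free + attached = gamma*c_0 is enforced to 1e-9 relative.
    """
    if k is None:
        if params.k is None:
            raise ValueError("an adhesion rate (constant or callable) is required")
        k = params.k
    rate = k if callable(k) else (lambda t, _k=float(k): _k)
    t_grid = np.asarray(t_grid, dtype=float)
    A = params.viable
    if A > params.c_m * (1 + 1e-12):
        raise ValueError("viable density exceeds surface capacity")

    def rhs(t, y):
        free, att = y
        d = rate(t) * free * (params.c_m - att)
        return [-d, d]

    t0 = min(0.0, t_grid[0])
    sol = solve_ivp(
        rhs, (t0, t_grid[-1]), [A, 0.0], t_eval=t_grid,
        method="LSODA", rtol=rtol, atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"cell ODE solver failed: {sol.message}")
    free, att = sol.y
    drift = np.max(np.abs(free + att - A)) / A
    if drift > 1e-9:
        raise RuntimeError(f"cell-number conservation violated: relative drift {drift:.3e}")
    return CellTrajectory(times=t_grid, attached=att, free=free)


def estimate_gamma(counts: MeasurementSeries, c_0: float) -> float:
    """Survival fraction: mean of the last two counts over the seeded density.

    The late counts (4 and 6 h in the reference schedule) sit on the
    attachment plateau, where c_a ~ gamma * c_0.
    """
    if counts.n_points < 2:
        raise ValueError("need at least two count measurements to estimate gamma")
    if c_0 <= 0:
        raise ValueError("seeded density must be positive")
    gamma = float(np.mean(counts.values[-2:]) / c_0)
    if gamma > 1:
        warnings.warn(
            f"estimated gamma = {gamma:.3f} > 1 (counts exceed seeding)",
            UserWarning,
            stacklevel=2,
        )
    return gamma


class AdhesionRateFit(BaseEstimator):
    """Fit a constant adhesion coefficient to attached-cell counts.

    One-dimensional minimisation of the relative-RMS count error over k on
    a log-spaced scan refined by bounded scalar minimisation, plus the
    uncertainty interval {k : error(k) <= 1.5 * error(k*)} reported as the
    connected bounds around the optimum.

    Parameters
    ----------
    c_0 : seeded density, cells/cm^2.
    c_m : surface capacity, cells/cm^2.
    gamma : survival fraction; estimated from the counts when None.
    k_bounds : scan range for k, cm^2 cells^-1 h^-1.
    n_scan : points in the log-spaced scan.
    error_factor : relative error increase defining the interval (1.5 =
        "no more than 50% worse than the optimum").

    Attributes
    ----------
    gamma_, k_, error_percent_, k_interval_ : fitted quantities.
    saturated_ : True when the counts sit on the plateau and carry no
        information about k (the scan's upper bound is then reported).
    """

    def __init__(
        self,
        c_0: float = 3500.0,
        c_m: float = cell_capacity(25.0),
        gamma: Optional[float] = None,
        k_bounds: tuple = (1e-7, 1e-2),
        n_scan: int = 200,
        error_factor: float = 1.5,
    ):
        self.c_0 = c_0
        self.c_m = c_m
        self.gamma = gamma
        self.k_bounds = k_bounds
        self.n_scan = n_scan
        self.error_factor = error_factor

    def _error(self, k: float, counts: MeasurementSeries, params: CellParams) -> float:
        pred = attached_cells_analytic(counts.times, replace(params, k=float(k)))
        return model_error(pred, counts)

    def fit(self, counts: MeasurementSeries):
        if counts.n_points < 1:
            raise ValueError("counts must be non-empty")
        if np.all(counts.values == 0):
            raise ValueError("all-zero counts: error landscape is flat in k")
        gamma = self.gamma if self.gamma is not None else estimate_gamma(counts, self.c_0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)  # gamma>1 already warned
            params = CellParams(gamma=gamma, c_0=self.c_0, c_m=self.c_m)

        lo, hi = self.k_bounds
        ks = np.logspace(np.log10(lo), np.log10(hi), self.n_scan)
        errs = np.array([self._error(k, counts, params) for k in ks])
        i = int(np.argmin(errs))

        self.saturated_ = False
        # the plateau prediction (k -> inf) matching the data as well as any
        # finite k means the counts carry no rate information
        if errs[-1] <= errs[i] * (1 + 1e-9) + 1e-12:
            # error still decreasing at the top of the scan: counts are at the
            # plateau for every large k and cannot identify the rate
            warnings.warn(
                "counts are saturated; adhesion rate unidentifiable, "
                "reporting the scan's upper bound",
                SaturationWarning,
                stacklevel=2,
            )
            self.saturated_ = True
            k_best, e_best = float(ks[-1]), float(errs[-1])
        else:
            lo_b = ks[max(i - 1, 0)]
            hi_b = ks[min(i + 1, self.n_scan - 1)]
            res = minimize_scalar(
                self._error, bounds=(lo_b, hi_b), args=(counts, params),
                method="bounded", options={"xatol": lo_b * 1e-6},
            )
            k_best, e_best = float(res.x), float(res.fun)

        self.gamma_ = gamma
        self.k_ = k_best
        self.error_percent_ = e_best
        self.k_interval_ = self._interval(k_best, e_best, counts, params)
        self.params_ = replace(params, k=k_best)
        return self

    def _interval(self, k_best, e_best, counts, params) -> tuple:
        """Connected {k : error <= factor * error(k*)} bounds via bisection."""
        target = self.error_factor * max(e_best, 1e-12)
        lo, hi = self.k_bounds

        def above(k):
            return self._error(k, counts, params) - target

        k_lo = lo
        if above(lo) > 0:
            a, b = lo, k_best
            for _ in range(80):
                m = np.sqrt(a * b)
                if above(m) > 0:
                    a = m
                else:
                    b = m
            k_lo = b
        k_hi = hi
        if above(hi) > 0:
            a, b = k_best, hi
            for _ in range(80):
                m = np.sqrt(a * b)
                if above(m) > 0:
                    b = m
                else:
                    a = m
            k_hi = a
        return (float(k_lo), float(k_hi))

    def predict(self, times: Sequence[float]) -> np.ndarray:
        """Attached-cell density at ``times`` for the fitted constant rate."""
        if not hasattr(self, "k_"):
            raise RuntimeError("estimator is not fitted")
        return attached_cells_analytic(np.asarray(times, float), self.params_)


def fit_k_constant(
    counts: MeasurementSeries,
    c_0: float = 3500.0,
    c_m: float = cell_capacity(25.0),
    gamma: Optional[float] = None,
    **kwargs,
) -> tuple[float, float, tuple]:
    """Functional wrapper over :class:`AdhesionRateFit`.

    Returns (k, error_percent, (k_lo, k_hi)).
    """
    est = AdhesionRateFit(c_0=c_0, c_m=c_m, gamma=gamma, **kwargs).fit(counts)
    return est.k_, est.error_percent_, est.k_interval_
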