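"""Protein adsorption/desorption on a biomaterial disk: 1D diffusion with
Langmuir boundary kinetics.

Model
-----
The fluid column above the disk is quiescent, so fluid-phase protein
transport is pure diffusion along the column height z (z = 0 at the disk
face, z = h at the free surface)::

    dc/dt = D d2c/dz2,          0 < z < h
    dc/dz = 0                   at z = h        (no escape at the top)

The disk itself is treated as an infinitely thin adsorbing plane whose
areal coverage c_s(t) [ug/mm^2] follows Langmuir attach/detach kinetics
driven by the fluid concentration at the wall::

    dc_s/dt = k_a * c(0,t) * (c_s_max - c_s) - k_d * c_s

and the diffusive flux at z = 0 balances dc_s/dt exactly, so total mass
(fluid + surface) is conserved.

Units
-----
Canonical internal units are mm / h / ug.  Fluid concentration is stored in
ug/mL because the adsorption constant k_a is given in mL ug^-1 h^-1, but
wherever a fluid concentration meets an areal flux it is converted to
ug/mm^3 (factor 1e-3).  This double convention is deliberate and asserted
by a dedicated unit test.

Numerics
--------
Finite-volume discretisation on a uniform grid (cell-centred, default 200
cells), which conserves mass exactly in the semi-discrete system, advanced
by backward Euler with Newton iteration.  Ordering the surface coverage as
the first unknown makes the Jacobian tridiagonal, so each Newton step is a
Thomas solve; the solver is vectorised over a batch of parameter sets so
the 400-point grid search integrates all candidates simultaneously.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .geometry import WellGeometry, DEFAULT_GEOMETRY

__all__ = [
    "ProteinParams",
    "ProteinTrajectory",
    "SteadyState",
    "GridControls",
    "SolverError",
    "solve_protein_kinetics",
    "steady_state_capacity",
    "equilibrium_state",
    "fluid_to_surface",
    "surface_to_fluid",
    "average_surface_concentration",
]

#: factor converting ug/mL to ug/mm^3
_ML_TO_MM3 = 1.0e-3


class SolverError(RuntimeError):
    """Raised when the implicit time stepper fails to converge or the
    solution violates physical bounds beyond tolerance."""


@dataclass(frozen=True)
class ProteinParams:
    """Langmuir kinetic constants and fluid diffusivity.

    k_a : adsorption coefficient, mL ug^-1 h^-1
    k_d : desorption coefficient, h^-1
    c_s_max : maximum (monolayer) surface concentration, ug/mm^2
    D : fluid diffusion coefficient, mm^2/h (0.3 for serum albumin at 37 C)
    """

    k_a: float
    k_d: float
    c_s_max: float
    D: float = 0.3

    def __post_init__(self) -> None:
        if self.k_a < 0 or self.k_d < 0:
            raise ValueError("rate constants must be non-negative")
        if self.c_s_max <= 0:
            raise ValueError("c_s_max must be positive")
        if self.D <= 0:
            raise ValueError("diffusion coefficient must be positive")


@dataclass(frozen=True)
class SteadyState:
    """Final (equilibrium) fluid and surface concentrations."""

    c_final: float  # ug/mL
    c_s_final: float  # ug/mm^2

    def __post_init__(self) -> None:
        if self.c_final < 0 or self.c_s_final < 0:
            raise ValueError("steady-state concentrations must be non-negative")


@dataclass(frozen=True)
class GridControls:
    """Discretisation controls for the finite-volume solver."""

    n_cells: int = 200
    dt_h: float = 0.05
    newton_tol: float = 1.0e-10
    max_newton: int = 25

    def __post_init__(self) -> None:
        if self.n_cells < 4:
            raise ValueError("need at least 4 grid cells")
        if self.dt_h <= 0:
            raise ValueError("dt_h must be positive")


@dataclass
class ProteinTrajectory:
    """Depth-resolved fluid field and surface coverage over time.

    c has shape (n_cells, n_times); z_grid holds cell centres.  mass_total
    is the ledger volume*mean_fluid + area*c_s at every output time.
    """

    times: np.ndarray  # h
    z_grid: np.ndarray  # mm, cell centres
    c: np.ndarray  # ug/mL, shape (nz, nt)
    c_surface: np.ndarray  # ug/mm^2
    mean_fluid: np.ndarray  # ug/mL
    mass_total: np.ndarray  # ug
    geometry: WellGeometry
    params: ProteinParams

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_h": self.times,
                "mean_fluid_ug_per_mL": self.mean_fluid,
                "surface_ug_per_mm2": self.c_surface,
                "mass_ug": self.mass_total,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def field_frame(self) -> pd.DataFrame:
        """Full c(z, t) field as a matrix (rows = z, columns = time)."""
        return pd.DataFrame(self.c, index=self.z_grid, columns=self.times)


# ---------------------------------------------------------------------------
# batched tridiagonal solve (Thomas algorithm)

def _thomas(dl: np.ndarray, d: np.ndarray, du: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Solve batched tridiagonal systems.

    All arrays have shape (B, m); dl[:, 0] and du[:, -1] are ignored.
    Small batches go through LAPACK's banded solver (the Python sweep only
    pays off when its per-cell cost is amortised over many systems).
    """
    B, m = d.shape
    if B <= 8:
        from scipy.linalg import solve_banded

        out = np.empty_like(d)
        ab = np.zeros((3, m))
        for k in range(B):
            ab[0, 1:] = du[k, :-1]
            ab[1, :] = d[k]
            ab[2, :-1] = dl[k, 1:]
            out[k] = solve_banded((1, 1), ab, b[k])
        return out
    cp = np.empty_like(d)
    bp = np.empty_like(d)
    cp[:, 0] = du[:, 0] / d[:, 0]
    bp[:, 0] = b[:, 0] / d[:, 0]
    for i in range(1, m):
        denom = d[:, i] - dl[:, i] * cp[:, i - 1]
        cp[:, i] = du[:, i] / denom
        bp[:, i] = (b[:, i] - dl[:, i] * bp[:, i - 1]) / denom
    x = np.empty_like(d)
    x[:, -1] = bp[:, -1]
    for i in range(m - 2, -1, -1):
        x[:, i] = bp[:, i] - cp[:, i] * x[:, i + 1]
    return x


def _rhs(x: np.ndarray, k_a, k_d, csm, D, dz: float) -> np.ndarray:
    """Semi-discrete RHS; state x = [c_s, c_0 .. c_{n-1}] per batch row."""
    s = x[:, 0]
    c = x[:, 1:]
    mu = D / dz**2
    beta = dz * _ML_TO_MM3  # converts ug/mm^2/h into ug/mL/h for one cell
    rate = k_a * c[:, 0] * (csm - s) - k_d * s
    f = np.empty_like(x)
    f[:, 0] = rate
    lap = np.empty_like(c)
    lap[:, 0] = mu * (c[:, 1] - c[:, 0])
    lap[:, 1:-1] = mu * (c[:, 2:] - 2.0 * c[:, 1:-1] + c[:, :-2])
    lap[:, -1] = mu * (c[:, -2] - c[:, -1])
    f[:, 1:] = lap
    f[:, 1] -= rate / beta
    return f


def _jac_diags(x: np.ndarray, k_a, k_d, csm, D, dz: float):
    """Tridiagonal Jacobian diagonals of the RHS (shape (B, m) each)."""
    B, m = x.shape
    s = x[:, 0]
    c0 = x[:, 1]
    mu = D / dz**2
    beta = dz * _ML_TO_MM3
    drate_ds = -(k_a * c0 + k_d)
    drate_dc0 = k_a * (csm - s)

    d = np.empty((B, m))
    dl = np.zeros((B, m))
    du = np.zeros((B, m))
    # surface row
    d[:, 0] = drate_ds
    du[:, 0] = drate_dc0
    # wall cell row
    dl[:, 1] = -drate_ds / beta
    d[:, 1] = -mu - drate_dc0 / beta
    du[:, 1] = mu
    # interior
    d[:, 2:-1] = -2.0 * mu
    dl[:, 2:-1] = mu
    du[:, 2:-1] = mu
    # top cell
    d[:, -1] = -mu
    dl[:, -1] = mu
    return dl, d, du


def _step_be(x: np.ndarray, dt: float, k_a, k_d, csm, D, dz: float,
             tol: float, max_iter: int, t: float) -> np.ndarray:
    """One backward-Euler step with Newton iteration on the full state."""
    xn = x.copy()
    scale = np.maximum(np.max(np.abs(x), axis=1, keepdims=True), 1.0)
    for it in range(max_iter):
        g = xn - x - dt * _rhs(xn, k_a, k_d, csm, D, dz)
        res = np.max(np.abs(g) / scale)
        if res < tol:
            return xn
        dl, d, du = _jac_diags(xn, k_a, k_d, csm, D, dz)
        # Jacobian of g is I - dt * J_f
        dl = -dt * dl
        du = -dt * du
        d = 1.0 - dt * d
        xn = xn - _thomas(dl, d, du, g)
    g = xn - x - dt * _rhs(xn, k_a, k_d, csm, D, dz)
    res = float(np.max(np.abs(g) / scale))
    if res < tol * 100:  # accept near-converged steps (bilinear residual stalls)
        return xn
    raise SolverError(
        f"Newton iteration failed to converge at t={t:.4g} h: "
        f"residual {res:.3e} after {max_iter} iterations"
    )


def _simulate_batch(
    k_a: np.ndarray,
    k_d: np.ndarray,
    c_s_max: np.ndarray,
    D: float,
    geometry: WellGeometry,
    initial_fluid,
    initial_surface,
    output_times: np.ndarray,
    grid: GridControls,
    mix_times: Sequence[float] = (),
):
    """Integrate a batch of parameter sets on a shared grid/schedule.

    Returns (mean_fluid (B, T), c_surface (B, T), c_field (B, nz, T)).
    """
    k_a = np.atleast_1d(np.asarray(k_a, dtype=float))
    k_d = np.atleast_1d(np.asarray(k_d, dtype=float))
    c_s_max = np.atleast_1d(np.asarray(c_s_max, dtype=float))
    B = max(k_a.shape[0], k_d.shape[0], c_s_max.shape[0])
    k_a, k_d, c_s_max = (np.broadcast_to(a, (B,)).copy() for a in (k_a, k_d, c_s_max))

    nz = grid.n_cells
    h = geometry.height_mm
    dz = h / nz

    x = np.empty((B, nz + 1))
    init_s = np.broadcast_to(np.asarray(initial_surface, dtype=float), (B,))
    if np.any(init_s > c_s_max * (1 + 1e-12)):
        raise ValueError("initial_surface exceeds c_s_max")
    x[:, 0] = init_s
    cf = np.asarray(initial_fluid, dtype=float)
    if cf.ndim == 0:
        x[:, 1:] = cf
    elif cf.shape == (nz,):
        x[:, 1:] = cf[None, :]
    else:
        raise ValueError(f"initial_fluid must be scalar or length-{nz} profile")
    if np.any(x < 0):
        raise ValueError("initial concentrations must be non-negative")

    output_times = np.asarray(output_times, dtype=float)
    t_end = output_times[-1]
    # anchor instants (outputs, mix events, endpoints), deduplicated with a
    # tolerance so float near-duplicates cannot create degenerate steps;
    # each anchor interval is subdivided uniformly at (at most) dt_h
    mix_times = np.asarray(mix_times, dtype=float)
    anchors = np.unique(np.concatenate([[0.0, t_end], output_times, mix_times]))
    anchors = anchors[(anchors >= 0.0) & (anchors <= t_end)]
    keep = np.concatenate([[True], np.diff(anchors) > 1e-10])
    anchors = anchors[keep]

    out_mean = np.empty((B, output_times.size))
    out_surf = np.empty((B, output_times.size))
    out_field = np.empty((B, nz, output_times.size))
    recorded = np.zeros(output_times.size, dtype=bool)

    def record(t):
        hits = np.nonzero(np.abs(output_times - t) <= 1e-9)[0]
        for j in hits:
            out_mean[:, j] = x[:, 1:].mean(axis=1)
            out_surf[:, j] = x[:, 0]
            out_field[:, :, j] = x[:, 1:]
            recorded[j] = True

    record(anchors[0])
    for a, b in zip(anchors[:-1], anchors[1:]):
        n_sub = max(1, int(np.ceil((b - a) / grid.dt_h - 1e-12)))
        t_prev = a
        for s_i in range(1, n_sub + 1):
            t_next = a + (b - a) * s_i / n_sub
            x = _step_be(x, t_next - t_prev, k_a, k_d, c_s_max, D, dz,
                         grid.newton_tol, grid.max_newton, t_next)
            t_prev = t_next
        if mix_times.size and np.min(np.abs(mix_times - b)) <= 1e-9:
            x[:, 1:] = x[:, 1:].mean(axis=1, keepdims=True)
        record(b)
    if not recorded.all():
        missing = output_times[~recorded]
        raise SolverError(f"internal error: output times {missing} never reached")

    # physical-bounds audit: tiny negatives from finite Newton tolerance are
    # zeroed; anything material is an error, never clamped silently
    floor = -1e-6 * max(float(np.max(out_field, initial=0.0)), 1.0)
    if np.min(out_field) < floor or np.min(out_surf) < floor:
        raise SolverError(
            f"negative concentration beyond tolerance: min c = {np.min(out_field):.3e}, "
            f"min c_s = {np.min(out_surf):.3e}"
        )
    np.clip(out_field, 0.0, None, out=out_field)
    np.clip(out_surf, 0.0, None, out=out_surf)
    over = (out_surf - c_s_max[:, None]) / c_s_max[:, None]
    if np.max(over) > 1e-6:
        raise SolverError(f"surface coverage exceeds capacity by {np.max(over):.3e} relative")
    out_surf = np.minimum(out_surf, c_s_max[:, None])
    out_mean = out_field.mean(axis=1)
    return out_mean, out_surf, out_field


def solve_protein_kinetics(
    params: ProteinParams,
    geometry: WellGeometry = DEFAULT_GEOMETRY,
    initial_fluid=0.0,
    initial_surface: float = 0.0,
    t_end: float = 80.0,
    output_times: Optional[Sequence[float]] = None,
    grid: GridControls = GridControls(),
    mix_times: Sequence[float] = (),
) -> ProteinTrajectory:
    """Simulate the coupled diffusion-Langmuir system.

    Parameters
    ----------
    initial_fluid : float or array
        Uniform fluid concentration (ug/mL) or a depth profile on the cell
        centres.
    initial_surface : float
        Initial coverage c_s(0), ug/mm^2; must not exceed ``params.c_s_max``.
    t_end, output_times :
        Simulation horizon (h) and reporting instants; defaults to 201
        uniformly spaced outputs over [0, t_end].
    mix_times :
        Optional instants at which the fluid is re-homogenised to its depth
        average (off by default; sampling-induced mixing hook).

    Returns
    -------
    ProteinTrajectory
        With a mass ledger at every output time.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    if output_times is None:
        output_times = np.linspace(0.0, t_end, 201)
    output_times = np.asarray(sorted(set(float(t) for t in output_times)))
    if output_times[0] < 0 or output_times[-1] > t_end * (1 + 1e-12):
        raise ValueError("output_times must lie within [0, t_end]")
    if not np.isclose(output_times[-1], t_end):
        output_times = np.append(output_times, t_end)

    mean_f, surf, fields = _simulate_batch(
        params.k_a, params.k_d, params.c_s_max, params.D,
        geometry, initial_fluid, initial_surface, output_times, grid, mix_times,
    )
    nz = grid.n_cells
    dz = geometry.height_mm / nz
    z = (np.arange(nz) + 0.5) * dz
    mass = geometry.volume_mL * mean_f[0] + geometry.area_mm2 * surf[0]
    return ProteinTrajectory(
        times=output_times,
        z_grid=z,
        c=fields[0].copy(),
        c_surface=surf[0],
        mean_fluid=mean_f[0],
        mass_total=mass,
        geometry=geometry,
        params=params,
    )


def steady_state_capacity(k_a: float, k_d: float, steady: SteadyState) -> float:
    """Monolayer capacity c_s_max implied by an observed equilibrium.

    At steady state the Langmuir attach and detach terms balance,
    ``k_a * c_f * (c_s_max - c_s_f) = k_d * c_s_f``, giving

        c_s_max = c_s_f * (1 + k_d / (k_a * c_f)).
    """
    if k_a * steady.c_final <= 0:
        raise ValueError(
            "capacity undefined: k_a * c_final must be positive "
            f"(k_a={k_a}, c_final={steady.c_final})"
        )
    return steady.c_s_final * (1.0 + k_d / (k_a * steady.c_final))


def equilibrium_state(
    params: ProteinParams,
    geometry: WellGeometry = DEFAULT_GEOMETRY,
    total_mass: float = 0.0,
) -> tuple[float, float]:
    """Closed-form well-mixed equilibrium (c_eq, c_s_eq) for a given total
    protein mass.

    Combines the zero-net-flux Langmuir condition with mass conservation
    V*c + A*c_s = total_mass; the admissible root of the resulting quadratic
    (0 <= c_s_eq <= c_s_max, c_eq >= 0) is returned.  Used as the long-time
    oracle for the PDE solver.
    """
    if total_mass < 0:
        raise ValueError("total_mass must be non-negative")
    if total_mass == 0:
        return 0.0, 0.0
    V = geometry.volume_mL
    A = geometry.area_mm2
    ka, kd, csm = params.k_a, params.k_d, params.c_s_max
    if ka == 0:
        if kd == 0:
            raise ValueError("equilibrium undefined with k_a = k_d = 0")
        return total_mass / V, 0.0
    # ka/V * (M - A*cs) * (csm - cs) = kd * cs
    p2 = ka * A / V
    p1 = -(ka * (total_mass + A * csm) / V + kd)
    p0 = ka * total_mass * csm / V
    disc = p1 * p1 - 4.0 * p2 * p0
    if disc < 0:
        raise ValueError(f"no admissible equilibrium root (discriminant {disc:.3e})")
    # both roots are positive; the smaller one satisfies cs <= min(csm, M/A)
    cs = (-p1 - np.sqrt(disc)) / (2.0 * p2)
    cs = float(min(max(cs, 0.0), csm))
    c = (total_mass - A * cs) / V
    if c < -1e-9 * max(total_mass / V, 1.0):
        raise ValueError(f"no admissible equilibrium root (c_eq={c:.3e} < 0)")
    return max(c, 0.0), cs


def fluid_to_surface(delta_c: float, geometry: WellGeometry = DEFAULT_GEOMETRY) -> float:
    """Areal density (ug/mm^2) holding the mass of a fluid depletion (ug/mL)."""
    return geometry.fluid_to_surface(delta_c)


def surface_to_fluid(delta_cs: float, geometry: WellGeometry = DEFAULT_GEOMETRY) -> float:
    """Fluid concentration (ug/mL) holding the mass of an areal density (ug/mm^2)."""
    return geometry.surface_to_fluid(delta_cs)


def average_surface_concentration(
    traj: ProteinTrajectory, window: tuple[float, float]
) -> float:
    """Time-average of c_s(t) over ``window`` by trapezoidal integration at
    the trajectory's native resolution (window endpoints interpolated)."""
    t0, t1 = float(window[0]), float(window[1])
    if not (traj.times[0] - 1e-9 <= t0 < t1 <= traj.times[-1] + 1e-9):
        raise ValueError(
            f"window [{t0}, {t1}] outside trajectory range "
            f"[{traj.times[0]}, {traj.times[-1]}] or empty"
        )
    inner = traj.times[(traj.times > t0) & (traj.times < t1)]
    ts = np.concatenate([[t0], inner, [t1]])
    cs = np.interp(ts, traj.times, traj.c_surface)
    return float(np.trapezoid(cs, ts) / (t1 - t0))
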