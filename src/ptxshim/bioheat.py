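"""Explicit finite-difference Pennes bioheat solver.

Solves, on the voxel grid and over the head + insulation domain,

    rho_t C_t dT/dt = k_t lap(T) + V_b rho_t C_b (T_b - T)
                      + rho_t SAR + rho_t Q_m

with a 7-point Laplacian, forward-Euler time stepping, and a Robin
(convective) exchange with ambient air on the domain surface.  The
perfusion term uses the tissue density (the perfusion rate V_b is per
kilogram of tissue, so this combination is the one that yields a
volumetric power density); insulation voxels carry their own heat
capacity and conductivity with no perfusion and no sources.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_model import Grid3D, LeadModel, TissueModel
from .sar_metrics import SarField

__all__ = [
    "BoundaryCondition",
    "ThermalField",
    "stable_timestep",
    "pennes_simulate",
    "peak_tip_delta_t",
]

BODY_TEMPERATURE = 37.0  # degC


@dataclass(frozen=True)
class BoundaryCondition:
    """Convective surface exchange: flux = h (T_ambient - T) on exposed faces.

    ``h = 0`` gives an insulated (no-flux) surface.
    """

    ambient: float = 20.0   # degC
    h: float = 10.0         # W/(m^2 K)

    def __post_init__(self) -> None:
        if self.h < 0:
            raise ValueError("surface exchange coefficient must be >= 0")


@dataclass
class ThermalField:
    """Temperature snapshots T(r, t) stored at strictly increasing times."""

    grid: Grid3D
    times: np.ndarray
    snapshots: np.ndarray      # (n_times, nx, ny, nz)
    dt: float
    duration: float
    bc: BoundaryCondition

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.snapshots = np.asarray(self.snapshots, float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("snapshot times must be strictly increasing")
        if self.snapshots.shape != (self.times.size,) + tuple(self.grid.dims):
            raise ValueError("snapshot array shape mismatch")
        if not np.all(np.isfinite(self.snapshots)):
            raise ValueError("non-finite temperatures")


def stable_timestep(
    tissue: TissueModel, grid: Grid3D, cap: float = 60.0, safety: float = 0.5
) -> float:
    """Explicit-scheme stability bound with a safety factor.

    dt = safety * min over the domain of (rho C / (2 k)) / (1/dx^2 + 1/dy^2 + 1/dz^2);
    in the diffusion-free limit (k -> 0) the bound is infinite and the
    configured ``cap`` is returned.
    """
    if any(h <= 0 for h in grid.spacing):
        raise ValueError("degenerate grid spacing")
    domain = tissue.head_mask | tissue.insulation_mask
    k = tissue.k_t[domain]
    rho_c = tissue.rho[domain] * tissue.C_t[domain]
    conducting = k > 0
    if not conducting.any():
        return cap
    inv_h2 = sum(1.0 / h**2 for h in grid.spacing)
    dt = safety * float(np.min(rho_c[conducting] / (2.0 * k[conducting]))) / inv_h2
    return min(dt, cap)


def pennes_simulate(
    tissue: TissueModel,
    sar: SarField,
    duration: float,
    dt: float | None = None,
    bc: BoundaryCondition | None = None,
    initial_T: np.ndarray | float = BODY_TEMPERATURE,
    n_snapshots: int = 25,
) -> ThermalField:
    """Forward-Euler Pennes solution under a steady SAR source.

    The exposure model applies the SAR field constantly for ``duration``
    seconds (a continuous-heating stand-in for a power-intensive
    refocusing-pulse sequence).  Temperatures start at 37 degC by
    default.  An instability (|T| > 200 degC) aborts with the offending
    voxel named.
    """
    grid = tissue.grid
    bc = bc or BoundaryCondition()
    if duration <= 0:
        raise ValueError("duration must be positive")
    dt_max = stable_timestep(tissue, grid)
    if dt is None:
        dt = dt_max
    elif dt > dt_max * (1 + 1e-9):
        raise ValueError(f"dt={dt} exceeds the stability bound {dt_max:.4g}")

    domain = tissue.head_mask | tissue.insulation_mask
    dims = tuple(grid.dims)
    T = np.full(dims, BODY_TEMPERATURE, float)
    if np.ndim(initial_T) == 0:
        T[domain] = float(initial_T)
    else:
        T[domain] = np.asarray(initial_T, float)[domain]

    rho = tissue.rho
    heat_cap = rho * tissue.C_t          # J/(m^3 K)
    k = tissue.k_t
    perf = tissue.V_b * rho * tissue.C_b  # W/(m^3 K)
    source = rho * (sar.sar + tissue.Q_m)  # W/m^3

    n_steps = max(int(np.ceil(duration / dt)), 1)
    dt = duration / n_steps
    store_at = np.unique(
        np.linspace(0, n_steps, min(n_snapshots, n_steps + 1)).astype(int)
    )
    times = [0.0]
    snaps = [T.copy()]

    shifts = [(ax, off) for ax in range(3) for off in (-1, +1)]
    inv_h2 = [1.0 / h**2 for h in grid.spacing]
    inv_h = [1.0 / h for h in grid.spacing]

    for step in range(1, n_steps + 1):
        flux = np.zeros(dims)
        for ax, off in shifts:
            T_nb = np.roll(T, off, axis=ax)
            nb_in = np.roll(domain, off, axis=ax)
            # rolled-around faces are grid-boundary faces, not neighbours
            edge = [slice(None)] * 3
            edge[ax] = 0 if off == 1 else -1
            nb_in = nb_in.copy()
            nb_in[tuple(edge)] = False
            k_face = 0.5 * (k + np.roll(k, off, axis=ax))
            interior = domain & nb_in
            flux[interior] += (
                k_face[interior] * (T_nb[interior] - T[interior]) * inv_h2[ax]
            )
            surface = domain & ~nb_in
            flux[surface] += bc.h * (bc.ambient - T[surface]) * inv_h[ax]
        dTdt = np.zeros(dims)
        dTdt[domain] = (
            flux[domain]
            + perf[domain] * (tissue.T_b - T[domain])
            + source[domain]
        ) / heat_cap[domain]
        T = T + dt * dTdt
        if np.any(np.abs(T[domain]) > 200.0):
            idx = np.unravel_index(
                np.argmax(np.abs(np.where(domain, T, 0.0))), dims
            )
            raise RuntimeError(f"thermal instability at voxel {idx}")
        if step in store_at:
            times.append(step * dt)
            snaps.append(T.copy())

    return ThermalField(
        grid=grid,
        times=np.asarray(times),
        snapshots=np.asarray(snaps),
        dt=dt,
        duration=duration,
        bc=bc,
    )


def peak_tip_delta_t(thermal: ThermalField, lead: LeadModel) -> float:
    """Peak temperature rise at the lead-tip voxel over the stored times (degC)."""
    idx = thermal.grid.index_of(lead.tip)
    trace = thermal.snapshots[(slice(None),) + idx]
    return float(np.max(trace - trace[0]))
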