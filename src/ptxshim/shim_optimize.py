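"""Cost-function RF shimming: quadrature precheck, simplex search, lambda sweep,
and safety-limited solution selection.

The cost for a shim setting w = {A_n, phi_n} is

    J(w) = s_VOI(|B1+|) / mu_VOI(|B1+|)  +  lambda * mu_ROM(|E|^2 / |E_quad|^2)

i.e. B1+ inhomogeneity over the imaging volume plus a weighted mean of
the tip-region E-field power relative to the quadrature reference.
Weights are re-normalized to the target mean B1+ inside every cost
evaluation, so uniformly shrinking the drives cannot game the E term.

The selection procedure sweeps lambda from 0 (homogeneity only) to the
regime where both terms stop changing, discards solutions whose 1 g SAR
at the tip exceeds the safety limit, and among the survivors takes the
lowest-SAR solution within a COV ceiling that starts at 10% and is
relaxed in 5-point steps only if necessary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .core_model import LeadModel, RegionMask, TissueModel
from .sar_metrics import raw_sar, volume_avg_sar
from .shim_core import (
    CoilFieldMaps,
    CombinedField,
    ShimWeights,
    combine_fields,
    normalize_weights,
    quadrature_weights,
)

__all__ = [
    "OptimizationConfig",
    "OptimizationResult",
    "CostEvaluator",
    "cost",
    "quadrature_precheck",
    "optimize_weights",
    "lambda_sweep",
    "select_solution",
]


@dataclass
class OptimizationConfig:
    """Settings of the lambda sweep and the simplex search."""

    lambda_grid: tuple = tuple(np.linspace(0.0, 6.0, 13))
    sar_limit: float = 0.4            # W/kg, ROM 1 g SAR safety ceiling
    cov_threshold_start: float = 0.10
    cov_threshold_step: float = 0.05
    target_mean_b1: float = 1e-6      # tesla
    max_iterations: int | None = 400   # per start; None -> scipy's dimension-scaled default
    fatol: float = 1e-10
    xatol: float = 1e-6
    restarts: int = 3
    restart_scale: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if any(l < 0 for l in self.lambda_grid):
            raise ValueError("lambda values must be >= 0")
        if self.sar_limit <= 0:
            raise ValueError("SAR limit must be positive")
        if not 0 < self.cov_threshold_start <= 1 or not 0 < self.cov_threshold_step <= 1:
            raise ValueError("COV thresholds must lie in (0, 1]")


@dataclass
class OptimizationResult:
    """One (lambda, weights) solution with its quality metrics."""

    weights: ShimWeights | None
    lam: float
    cov: float = np.nan
    rom_term: float = np.nan
    rom_1g_sar: float = np.nan
    whole_head_sar: float = np.nan
    cost: float = np.nan
    iterations: int = 0
    converged: bool = False
    error: str | None = None


def _params_to_weights(x: np.ndarray, n: int) -> ShimWeights:
    """2N-1 real parameters -> weights: |a_n| amplitudes, phi_0 fixed at 0."""
    amps = np.abs(x[:n])
    phases = np.concatenate([[0.0], x[n:]])
    return ShimWeights(amps, phases)


def _weights_to_params(w: ShimWeights) -> np.ndarray:
    phases = np.mod(w.phases - w.phases[0], 2.0 * np.pi)
    return np.concatenate([w.amplitudes, phases[1:]])


class CostEvaluator:
    """Precomputed restricted field bases for fast repeated cost evaluation.

    Holds the per-channel B1+ basis over the VOI, the per-channel E basis
    over the ROM, and the quadrature |E|^2 denominator (floored at a
    machine-epsilon-scaled level; voxels below the floor are excluded
    from the ROM mean).  Optionally holds tissue data so that ROM 1 g SAR
    and whole-head SAR can be evaluated per candidate without touching
    the full grids.
    """

    def __init__(
        self,
        maps: CoilFieldMaps,
        voi: RegionMask,
        rom: RegionMask,
        cfg: OptimizationConfig | None = None,
        tissue: TissueModel | None = None,
    ) -> None:
        self.cfg = cfg or OptimizationConfig()
        self.n_channels = maps.n_channels
        self.B1_voi = maps.B1[:, voi.mask].T                 # (n_voi, N)
        self.E_rom = np.moveaxis(maps.E[:, rom.mask], 0, -1)  # (n_rom, 3, N)

        wq = normalize_weights(
            quadrature_weights(self.n_channels), maps, voi, self.cfg.target_mean_b1
        ).as_complex()
        Eq = np.einsum("vcn,n->vc", self.E_rom, wq)
        self.Equad_sq = np.sum(np.abs(Eq) ** 2, axis=-1)
        floor = np.finfo(float).eps * self.Equad_sq.max()
        self.valid = self.Equad_sq > floor
        if not self.valid.any():
            raise ValueError("quadrature E-field vanishes over the whole ROM")

        self.tissue = tissue
        if tissue is not None:
            rom_sel = rom.mask & tissue.head_mask & ~tissue.insulation_mask
            self.rom_rho = tissue.rho[rom_sel]
            self.rom_sigma = tissue.sigma[rom_sel]
            self.E_rom_tissue = np.moveaxis(maps.E[:, rom_sel], 0, -1)
            head = tissue.head_mask
            self.E_head = np.moveaxis(maps.E[:, head], 0, -1)
            self.head_sigma = tissue.sigma[head]
            self.head_mass = float(tissue.rho[head].sum())

    # -- core terms -------------------------------------------------------

    def _normalized_complex(self, w: np.ndarray) -> tuple[np.ndarray, float]:
        """Scale factor bringing the VOI-mean |B1+| to target, and B1 samples."""
        b1 = self.B1_voi @ w
        mean = float(np.mean(np.abs(b1)))
        if mean <= 0:
            raise ValueError("zero B1+ over the VOI")
        return b1, self.cfg.target_mean_b1 / mean

    def terms(self, weights: ShimWeights) -> tuple[float, float]:
        """(COV term, ROM ratio term) for a shim setting."""
        w = weights.as_complex()
        b1, scale = self._normalized_complex(w)
        mag = np.abs(b1)
        cov = float(mag.std(ddof=0) / mag.mean())
        E = np.einsum("vcn,n->vc", self.E_rom, w * scale)
        ratio = np.sum(np.abs(E) ** 2, axis=-1)[self.valid] / self.Equad_sq[self.valid]
        return cov, float(ratio.mean())

    def cost(self, weights: ShimWeights, lam: float) -> float:
        cov, rom_term = self.terms(weights)
        return cov + lam * rom_term

    def _cost_from_params(self, x: np.ndarray, lam: float) -> float:
        return self.cost(_params_to_weights(x, self.n_channels), lam)

    # -- SAR metrics on the restricted bases ------------------------------

    def normalized(self, weights: ShimWeights) -> ShimWeights:
        w = weights.as_complex()
        _, scale = self._normalized_complex(w)
        return weights.scaled(scale)

    def rom_1g_sar(self, normalized_weights: ShimWeights) -> float:
        if self.tissue is None:
            raise ValueError("evaluator was built without tissue data")
        w = normalized_weights.as_complex()
        E = np.einsum("vcn,n->vc", self.E_rom_tissue, w)
        sar = self.rom_sigma * np.sum(np.abs(E) ** 2, axis=-1) / (2.0 * self.rom_rho)
        return float(np.sum(sar * self.rom_rho) / self.rom_rho.sum())

    def whole_head_sar(self, normalized_weights: ShimWeights) -> float:
        if self.tissue is None:
            raise ValueError("evaluator was built without tissue data")
        w = normalized_weights.as_complex()
        E = np.einsum("vcn,n->vc", self.E_head, w)
        power = self.head_sigma * np.sum(np.abs(E) ** 2, axis=-1) / 2.0
        return float(power.sum() / self.head_mass)


def cost(
    weights: ShimWeights,
    maps: CoilFieldMaps,
    voi: RegionMask,
    rom: RegionMask,
    lam: float,
    quad_field: CombinedField,
    target_mean_b1: float = 1e-6,
) -> float:
    """Standalone cost evaluation from full-grid fields.

    ``quad_field`` must be the normalized quadrature combination; the
    pointwise |E|^2 ratio denominator is floored at a machine-epsilon
    scale of its ROM maximum, with sub-floor voxels excluded.
    """
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    normalized = normalize_weights(weights, maps, voi, target_mean_b1)
    total = combine_fields(normalized, maps)
    mag = np.abs(total.B1[voi.mask])
    mean = mag.mean()
    if mean <= 0:
        raise ValueError("zero B1+ over the VOI")
    cov = float(mag.std(ddof=0) / mean)
    e_sq = np.sum(np.abs(total.E[rom.mask]) ** 2, axis=-1)
    eq_sq = np.sum(np.abs(quad_field.E[rom.mask]) ** 2, axis=-1)
    if eq_sq.size == 0:
        raise ValueError("empty ROM")
    valid = eq_sq > np.finfo(float).eps * eq_sq.max()
    return cov + lam * float(np.mean(e_sq[valid] / eq_sq[valid]))


def quadrature_precheck(
    maps: CoilFieldMaps,
    tissue: TissueModel,
    lead: LeadModel,
    voi: RegionMask,
    limit: float = 0.4,
) -> tuple[str, float]:
    """Decide whether quadrature drive is already safe at the lead tip.

    Returns ``("safe-skip", sar)`` when the normalized quadrature mode's
    ROM 1 g SAR is below ``limit`` (W/kg) — optimization is unnecessary
    and the near-zero quadrature denominator regime is avoided — else
    ``("optimize", sar)``.
    """
    wq = normalize_weights(quadrature_weights(maps.n_channels), maps, voi)
    sar = raw_sar(combine_fields(wq, maps), tissue)
    from .core_model import build_rom_mask

    rom = build_rom_mask(maps.grid, lead, tissue)
    rom_sar = volume_avg_sar(sar, rom, tissue)
    return ("safe-skip" if rom_sar < limit else "optimize", rom_sar)


def optimize_weights(
    maps: CoilFieldMaps,
    voi: RegionMask,
    rom: RegionMask,
    lam: float,
    cfg: OptimizationConfig | None = None,
    tissue: TissueModel | None = None,
    evaluator: CostEvaluator | None = None,
) -> OptimizationResult:
    """Nelder-Mead minimization of the shim cost at one lambda.

    Parameterization uses 2N-1 real variables (N free amplitudes through
    an absolute-value map, N-1 phases with phi_0 pinned to remove the
    global-phase degeneracy), initialized at quadrature with optional
    seeded restarts.  The returned cost never exceeds the quadrature
    starting cost.
    """
    cfg = cfg or OptimizationConfig()
    ev = evaluator or CostEvaluator(maps, voi, rom, cfg, tissue=tissue)
    n = ev.n_channels
    if n < 2:
        raise ValueError("optimization needs at least two channels")
    x_quad = _weights_to_params(quadrature_weights(n))
    rng = np.random.default_rng(cfg.seed + int(round(1000 * lam)))

    starts = [x_quad]
    for _ in range(cfg.restarts):
        pert = np.concatenate(
            [
                rng.uniform(-cfg.restart_scale, cfg.restart_scale, n),
                rng.uniform(-np.pi, np.pi, n - 1) * cfg.restart_scale,
            ]
        )
        starts.append(x_quad + pert)

    best_x, best_f = x_quad, ev._cost_from_params(x_quad, lam)
    iterations = 0
    converged = False
    options = {"fatol": cfg.fatol, "xatol": cfg.xatol}
    if cfg.max_iterations is not None:
        options["maxiter"] = cfg.max_iterations
    for x0 in starts:
        res = minimize(
            ev._cost_from_params,
            x0,
            args=(lam,),
            method="Nelder-Mead",
            options=options,
        )
        if not np.isfinite(res.fun):
            raise ValueError(f"non-finite cost at parameters {res.x}")
        iterations += int(res.nit)
        if res.fun < best_f:
            best_x, best_f = res.x, float(res.fun)
            converged = bool(res.success)
        elif not converged:
            converged = bool(res.success)

    weights = ev.normalized(_params_to_weights(best_x, n))
    cov, rom_term = ev.terms(weights)
    result = OptimizationResult(
        weights=weights,
        lam=float(lam),
        cov=cov,
        rom_term=rom_term,
        cost=cov + lam * rom_term,
        iterations=iterations,
        converged=converged,
    )
    if ev.tissue is not None:
        result.rom_1g_sar = ev.rom_1g_sar(weights)
        result.whole_head_sar = ev.whole_head_sar(weights)
    return result


def lambda_sweep(
    maps: CoilFieldMaps,
    voi: RegionMask,
    rom: RegionMask,
    cfg: OptimizationConfig | None = None,
    tissue: TissueModel | None = None,
) -> list[OptimizationResult]:
    """One optimization per lambda on the configured grid, ordered by lambda.

    A failure at a single lambda is recorded on its result and the sweep
    continues; if every lambda fails the sweep itself raises.
    """
    cfg = cfg or OptimizationConfig()
    if len(cfg.lambda_grid) == 0:
        raise ValueError("lambda grid is empty")
    ev = CostEvaluator(maps, voi, rom, cfg, tissue=tissue)
    results: list[OptimizationResult] = []
    for lam in sorted(cfg.lambda_grid):
        try:
            results.append(
                optimize_weights(maps, voi, rom, lam, cfg, evaluator=ev)
            )
        except Exception as exc:  # recorded per-lambda, sweep continues
            results.append(
                OptimizationResult(weights=None, lam=float(lam), error=str(exc))
            )
    if all(r.error is not None for r in results):
        raise ValueError("every lambda optimization failed")
    return results


def select_solution(
    results: list[OptimizationResult],
    cfg: OptimizationConfig | None = None,
) -> OptimizationResult:
    """Two-stage safety/homogeneity selection over a lambda sweep.

    Solutions whose ROM 1 g SAR exceeds the safety limit are discarded.
    Among survivors, the minimum-SAR solution within the COV ceiling is
    returned; the ceiling starts at 10% and is raised in 5-point steps
    (capped at 100%) until at least one solution qualifies.
    """
    cfg = cfg or OptimizationConfig()
    if not results:
        raise ValueError("no results to select from")
    ok = [
        r
        for r in results
        if r.error is None and np.isfinite(r.rom_1g_sar) and r.rom_1g_sar <= cfg.sar_limit
    ]
    if not ok:
        raise ValueError("no safe solution: every result exceeds the SAR limit")
    threshold = cfg.cov_threshold_start
    while threshold <= 1.0 + 1e-12:
        within = [r for r in ok if r.cov <= threshold]
        if within:
            return min(within, key=lambda r: r.rom_1g_sar)
        threshold += cfg.cov_threshold_step
    raise ValueError("no safe solution: no result within the COV ceiling cap")
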