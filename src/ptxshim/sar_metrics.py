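"""SAR and B1+ quality metrics.

Raw SAR is sigma |E|^2 / (2 rho) per voxel; region averages are
mass-weighted (with the homogeneous head this reduces to the arithmetic
mean).  The 1 g local SAR averages over the whole-voxel cube region
grown around the exposed lead tip.  B1+ inhomogeneity is the coefficient
of variation of |B1+| over the VOI, using the population standard
deviation (the VOI is the entire population of voxels of interest).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_model import Grid3D, LeadModel, RegionMask, TissueModel, build_rom_mask
from .shim_core import CombinedField

__all__ = [
    "SarField",
    "raw_sar",
    "volume_avg_sar",
    "local_1g_sar",
    "whole_head_sar",
    "cov_b1",
]


@dataclass
class SarField:
    """Per-voxel raw SAR (W/kg); zero outside the head."""

    sar: np.ndarray
    grid: Grid3D

    def __post_init__(self) -> None:
        self.sar = np.asarray(self.sar, float)
        if self.sar.shape != tuple(self.grid.dims):
            raise ValueError("SAR shape does not match grid dims")
        if not np.all(np.isfinite(self.sar)) or np.any(self.sar < 0):
            raise ValueError("raw SAR must be finite and non-negative")


def raw_sar(field: CombinedField, tissue: TissueModel) -> SarField:
    """Pointwise SAR(r) = sigma(r) |E(r)|^2 / (2 rho(r)), zero outside the head."""
    head = tissue.head_mask
    if np.any(tissue.rho[head] <= 0):
        raise ValueError("tissue density must be positive inside the head")
    e_sq = np.sum(np.abs(field.E) ** 2, axis=-1)
    sar = np.zeros(tuple(field.grid.dims))
    sar[head] = tissue.sigma[head] * e_sq[head] / (2.0 * tissue.rho[head])
    return SarField(sar=sar, grid=field.grid)


def volume_avg_sar(sar: SarField, region: RegionMask, tissue: TissueModel) -> float:
    """Mass-weighted mean SAR over the tissue voxels of a region (W/kg)."""
    sel = region.mask & tissue.head_mask & ~tissue.insulation_mask
    mass = tissue.rho[sel]
    total_mass = float(mass.sum())
    if total_mass <= 0:
        raise ValueError(f"region {region.role} contains no tissue mass")
    return float(np.sum(sar.sar[sel] * mass) / total_mass)


def local_1g_sar(sar: SarField, tissue: TissueModel, lead: LeadModel) -> float:
    """SAR averaged over the 1 g cube region at the exposed lead tip (W/kg)."""
    rom = build_rom_mask(sar.grid, lead, tissue)
    return volume_avg_sar(sar, rom, tissue)


def whole_head_sar(sar: SarField, tissue: TissueModel) -> float:
    """Mass-averaged SAR over the entire head (W/kg)."""
    head = RegionMask(mask=tissue.head_mask, grid=sar.grid, role="HEAD")
    return volume_avg_sar(sar, head, tissue)


def cov_b1(field: CombinedField, voi: RegionMask) -> float:
    """Coefficient of variation of |B1+| over the VOI (dimensionless).

    COV = s_VOI(|B1+|) / mu_VOI(|B1+|) with the population standard
    deviation; multiply by 100 to report percent.
    """
    mag = np.abs(field.B1[voi.mask])
    mean = float(mag.mean())
    if mean <= 0:
        raise ValueError("zero mean |B1+| over the VOI")
    return float(mag.std(ddof=0) / mean)
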