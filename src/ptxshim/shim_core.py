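"""Channel-weight algebra: quadrature weights, field superposition, B1+ normalization.

With per-channel complex basis maps e_n(r) (E-field, V/m per unit drive)
and b1+_n(r) (transmit field, tesla per unit drive), a static RF shim
setting {A_n, phi_n} produces

    E_tot(r)   = sum_n A_n exp(i phi_n) e_n(r)
    B1+_tot(r) = sum_n A_n exp(i phi_n) b1+_n(r)

Everything downstream (SAR, COV, optimization) is built on this linear
superposition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_model import Grid3D, RegionMask

__all__ = [
    "ShimWeights",
    "CoilFieldMaps",
    "CombinedField",
    "quadrature_weights",
    "combine_fields",
    "normalize_weights",
]


@dataclass
class ShimWeights:
    """Per-channel drive amplitude A_n (>= 0) and phase phi_n (radians)."""

    amplitudes: np.ndarray
    phases: np.ndarray

    def __post_init__(self) -> None:
        self.amplitudes = np.atleast_1d(np.asarray(self.amplitudes, float))
        self.phases = np.atleast_1d(np.asarray(self.phases, float))
        if self.amplitudes.shape != self.phases.shape or self.amplitudes.ndim != 1:
            raise ValueError("amplitudes and phases must be equal-length 1-D arrays")
        if not np.all(np.isfinite(self.amplitudes)) or not np.all(
            np.isfinite(self.phases)
        ):
            raise ValueError("weights must be finite")
        if np.any(self.amplitudes < 0):
            raise ValueError("amplitudes must be non-negative")

    @property
    def n_channels(self) -> int:
        return self.amplitudes.size

    def as_complex(self) -> np.ndarray:
        """Complex drive vector A_n exp(i phi_n)."""
        return self.amplitudes * np.exp(1j * self.phases)

    @classmethod
    def from_complex(cls, w: np.ndarray) -> "ShimWeights":
        w = np.atleast_1d(np.asarray(w, complex))
        return cls(amplitudes=np.abs(w), phases=np.angle(w))

    def scaled(self, factor: float) -> "ShimWeights":
        """Uniform amplitude rescaling; phases unchanged."""
        if factor < 0:
            raise ValueError("scale factor must be >= 0")
        return ShimWeights(self.amplitudes * factor, self.phases.copy())

    def to_dict(self) -> dict:
        return {
            "amplitudes": self.amplitudes.tolist(),
            "phases_rad": self.phases.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ShimWeights":
        return cls(np.asarray(d["amplitudes"]), np.asarray(d["phases_rad"]))


@dataclass
class CoilFieldMaps:
    """Per-channel complex E and B1+ basis maps on a shared grid.

    E has shape (N, nx, ny, nz, 3) in V/m per unit drive; B1 has shape
    (N, nx, ny, nz) in tesla per unit drive.
    """

    grid: Grid3D
    E: np.ndarray
    B1: np.ndarray
    frequency: float = 128e6
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.E = np.asarray(self.E, complex)
        self.B1 = np.asarray(self.B1, complex)
        dims = tuple(self.grid.dims)
        if self.E.ndim != 5 or self.E.shape[1:4] != dims or self.E.shape[4] != 3:
            raise ValueError(f"E must have shape (N, {dims}, 3)")
        if self.B1.shape != (self.E.shape[0],) + dims:
            raise ValueError(f"B1 must have shape (N, {dims})")
        if not np.all(np.isfinite(self.E)) or not np.all(np.isfinite(self.B1)):
            raise ValueError("field maps contain non-finite values")

    @property
    def n_channels(self) -> int:
        return self.E.shape[0]


@dataclass
class CombinedField:
    """Total complex fields produced by one shim setting on one set of maps."""

    grid: Grid3D
    E: np.ndarray
    B1: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.E = np.asarray(self.E, complex)
        self.B1 = np.asarray(self.B1, complex)
        dims = tuple(self.grid.dims)
        if self.E.shape != dims + (3,):
            raise ValueError("combined E has wrong shape")
        if self.B1.shape != dims:
            raise ValueError("combined B1 has wrong shape")
        if not np.all(np.isfinite(self.E)) or not np.all(np.isfinite(self.B1)):
            raise ValueError("combined field contains non-finite values")


def quadrature_weights(n_channels: int) -> ShimWeights:
    """Quadrature drive: A_n = 1, phi_n = 2 pi n / N.

    Emulates circularly polarized excitation; used as the reference mode
    and as the optimizer's starting point.
    """
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    n = np.arange(n_channels)
    return ShimWeights(np.ones(n_channels), 2.0 * np.pi * n / n_channels)


def combine_fields(weights: ShimWeights, maps: CoilFieldMaps) -> CombinedField:
    """Superpose per-channel maps under a shim setting (linear in the drives)."""
    if weights.n_channels != maps.n_channels:
        raise ValueError(
            f"weight count {weights.n_channels} != channel count {maps.n_channels}"
        )
    w = weights.as_complex()
    E_tot = np.tensordot(w, maps.E, axes=(0, 0))
    B1_tot = np.tensordot(w, maps.B1, axes=(0, 0))
    return CombinedField(
        grid=maps.grid,
        E=E_tot,
        B1=B1_tot,
        provenance={"weights": weights.to_dict(), "maps": maps.meta.get("id")},
    )


def normalize_weights(
    weights: ShimWeights,
    maps: CoilFieldMaps,
    voi: RegionMask,
    target_mean_b1: float = 1e-6,
) -> ShimWeights:
    """Scale all amplitudes by one factor so the VOI-mean |B1+| hits the target.

    The common scale makes excitations comparable across coil
    configurations (the shim target is mean |B1+| = 1 uT over the VOI by
    default); phases are untouched.
    """
    if target_mean_b1 <= 0:
        raise ValueError("target mean B1+ must be positive")
    w = weights.as_complex()
    B1_voi = np.tensordot(w, maps.B1[:, voi.mask], axes=(0, 0))
    mean_b1 = float(np.mean(np.abs(B1_voi)))
    if mean_b1 <= 0:
        raise ValueError("zero B1+ over the VOI; cannot normalize")
    return weights.scaled(target_mean_b1 / mean_b1)
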