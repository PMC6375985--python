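"""Grid, tissue, lead and region data model plus field-data conditioning.

All quantities are SI internally (metres, kilograms, seconds, degrees
Celsius for temperature).  World coordinates are attached to voxel
centres; the coil-assembly centre is the world origin, with z along the
bore and the patient facing the -y direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Grid3D",
    "TissueModel",
    "LeadModel",
    "RegionMask",
    "VoiSpec",
    "build_voi_mask",
    "build_rom_mask",
    "hampel_filter",
    "hampel_filter_volume",
    "min_nonadjacent_segment_distance",
]

# Default voxel pitch of the field maps (metres).
DEFAULT_SPACING = (0.0039, 0.0045, 0.0035)


@dataclass(frozen=True)
class Grid3D:
    """Regular 3-D voxel grid.

    Parameters
    ----------
    dims : tuple of int
        Number of voxels along (x, y, z); each must be >= 2.
    spacing : tuple of float
        Voxel pitch (dx, dy, dz) in metres; each must be > 0.
    origin : tuple of float
        World coordinate (metres) of the centre of voxel (0, 0, 0).
    """

    dims: tuple[int, int, int]
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.dims) != 3 or any(int(n) < 2 for n in self.dims):
            raise ValueError("grid needs >= 2 voxels per axis")
        if len(self.spacing) != 3 or any(h <= 0 for h in self.spacing):
            raise ValueError("grid spacing must be positive")
        object.__setattr__(self, "dims", tuple(int(n) for n in self.dims))
        object.__setattr__(self, "spacing", tuple(float(h) for h in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @classmethod
    def centered(
        cls,
        dims: tuple[int, int, int],
        spacing: tuple[float, float, float] = DEFAULT_SPACING,
    ) -> "Grid3D":
        """Grid whose centre coincides with the coil-assembly centre."""
        origin = tuple(-(n - 1) / 2.0 * h for n, h in zip(dims, spacing))
        return cls(dims=dims, spacing=spacing, origin=origin)

    @property
    def voxel_volume(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis voxel-centre world coordinates."""
        return tuple(
            o + h * np.arange(n)
            for n, h, o in zip(self.dims, self.spacing, self.origin)
        )

    def coordinate_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Broadcastable (sparse) meshgrid of voxel-centre coordinates."""
        ax, ay, az = self.axes()
        return np.meshgrid(ax, ay, az, indexing="ij", sparse=True)

    def points(self) -> np.ndarray:
        """Dense (nx*ny*nz, 3) array of voxel-centre coordinates."""
        gx, gy, gz = np.meshgrid(*self.axes(), indexing="ij")
        return np.stack([gx, gy, gz], axis=-1).reshape(-1, 3)

    def contains(self, point: np.ndarray) -> bool:
        """True if ``point`` falls inside the voxel lattice (nearest-voxel sense)."""
        idx = np.round((np.asarray(point, float) - self.origin) / self.spacing)
        return bool(np.all(idx >= 0) and np.all(idx <= np.array(self.dims) - 1))

    def index_of(self, point: np.ndarray) -> tuple[int, int, int]:
        """Index of the voxel whose centre is nearest to ``point``."""
        idx = np.round((np.asarray(point, float) - self.origin) / self.spacing)
        if np.any(idx < 0) or np.any(idx > np.array(self.dims) - 1):
            raise ValueError(f"point {point} lies outside the grid")
        return tuple(int(i) for i in idx)

    def extent(self) -> tuple[tuple[float, float], ...]:
        """Per-axis (min, max) voxel-centre coordinates."""
        return tuple(
            (o, o + h * (n - 1))
            for n, h, o in zip(self.dims, self.spacing, self.origin)
        )


# --------------------------------------------------------------------------
# Tissue model
# --------------------------------------------------------------------------

#: Electromagnetic / thermal defaults of the homogeneous head medium at 128 MHz.
TISSUE_DEFAULTS = dict(
    sigma=0.69,        # S/m
    eps_r=67.0,
    rho=1000.0,        # kg/m^3 (not reported for the head medium; gel-phantom scale)
    C_t=3650.0,        # J/(kg K)
    k_t=0.6,           # W/(m K)
    V_b=0.0085,        # kg_blood / (s kg_tissue)
    Q_m=0.0,           # W/kg
)

#: Lead-insulation thermal properties (perfusion-free, source-free).
INSULATION_DEFAULTS = dict(C=1500.0, k=0.026)

#: Blood constants for the perfusion sink.
BLOOD_DEFAULTS = dict(rho_b=1050.0, C_b=3617.0, T_b=37.0)


@dataclass
class TissueModel:
    """Per-voxel electromagnetic and thermal properties of the model.

    The insulation mask overrides tissue properties wherever it is true:
    sigma = 0, V_b = 0, Q_m = 0, and the insulation heat capacity /
    conductivity replace the tissue values there.
    """

    grid: Grid3D
    head_mask: np.ndarray
    sigma: np.ndarray
    eps_r: np.ndarray
    rho: np.ndarray
    C_t: np.ndarray
    k_t: np.ndarray
    V_b: np.ndarray
    Q_m: np.ndarray
    insulation_mask: np.ndarray
    rho_b: float = BLOOD_DEFAULTS["rho_b"]
    C_b: float = BLOOD_DEFAULTS["C_b"]
    T_b: float = BLOOD_DEFAULTS["T_b"]

    def __post_init__(self) -> None:
        shape = tuple(self.grid.dims)
        for name in ("head_mask", "insulation_mask"):
            arr = np.asarray(getattr(self, name), bool)
            if arr.shape != shape:
                raise ValueError(f"{name} shape {arr.shape} != grid dims {shape}")
            setattr(self, name, arr)
        for name in ("sigma", "eps_r", "rho", "C_t", "k_t", "V_b", "Q_m"):
            arr = np.asarray(getattr(self, name), float)
            if arr.shape != shape:
                raise ValueError(f"{name} shape {arr.shape} != grid dims {shape}")
            if np.any(arr < 0):
                raise ValueError(f"{name} must be non-negative")
            setattr(self, name, arr)
        ins = self.insulation_mask
        if np.any(self.sigma[ins] != 0) or np.any(self.V_b[ins] != 0):
            raise ValueError("sigma and V_b must vanish on insulation voxels")

    @classmethod
    def homogeneous(
        cls,
        grid: Grid3D,
        head_mask: np.ndarray,
        insulation_mask: np.ndarray | None = None,
        **overrides: float,
    ) -> "TissueModel":
        """Uniform head properties with insulation overrides applied."""
        props = dict(TISSUE_DEFAULTS)
        blood = dict(BLOOD_DEFAULTS)
        for key, val in overrides.items():
            if key in props:
                props[key] = val
            elif key in blood:
                blood[key] = val
            else:
                raise TypeError(f"unknown tissue property {key!r}")
        shape = tuple(grid.dims)
        head = np.asarray(head_mask, bool)
        ins = (
            np.zeros(shape, bool)
            if insulation_mask is None
            else np.asarray(insulation_mask, bool)
        )

        def fill(value: float, inside_only: bool = True) -> np.ndarray:
            arr = np.zeros(shape)
            arr[head] = value
            if not inside_only:
                arr[:] = value
            return arr

        sigma = fill(props["sigma"])
        eps_r = fill(props["eps_r"])
        rho = fill(props["rho"])
        C_t = fill(props["C_t"])
        k_t = fill(props["k_t"])
        V_b = fill(props["V_b"])
        Q_m = fill(props["Q_m"])
        # insulation overrides
        sigma[ins] = 0.0
        V_b[ins] = 0.0
        Q_m[ins] = 0.0
        C_t[ins] = INSULATION_DEFAULTS["C"]
        k_t[ins] = INSULATION_DEFAULTS["k"]
        rho[ins] = np.where(rho[ins] > 0, rho[ins], props["rho"])
        return cls(
            grid=grid,
            head_mask=head,
            sigma=sigma,
            eps_r=eps_r,
            rho=rho,
            C_t=C_t,
            k_t=k_t,
            V_b=V_b,
            Q_m=Q_m,
            insulation_mask=ins,
            **blood,
        )

    def head_mass(self) -> float:
        """Total tissue mass (kg), excluding insulation voxels."""
        tissue = self.head_mask & ~self.insulation_mask
        return float(self.rho[tissue].sum() * self.grid.voxel_volume)


# --------------------------------------------------------------------------
# Lead model
# --------------------------------------------------------------------------

#: Geometric constants of the DBS lead (metres).
LEAD_OUTER_DIAMETER = 1.27e-3
LEAD_CORE_DIAMETER = 260e-6
LEAD_CONTACT_WALL = 150e-6
#: Arc length of the distal exposed-electrode span (four contacts).
LEAD_EXPOSED_SPAN = 7.5e-3


def _segment_pair_distances(p1, q1, p2, q2):
    """Vectorized minimum distance between segment batches [p1,q1] and [p2,q2]."""
    d1 = q1 - p1
    d2 = q2 - p2
    r = p1 - p2
    a = np.einsum("ij,ij->i", d1, d1)
    e = np.einsum("ij,ij->i", d2, d2)
    f = np.einsum("ij,ij->i", d2, r)
    c = np.einsum("ij,ij->i", d1, r)
    b = np.einsum("ij,ij->i", d1, d2)
    denom = a * e - b * b
    s = np.where(denom > 1e-30, (b * f - c * e) / np.where(denom > 1e-30, denom, 1.0), 0.0)
    s = np.clip(s, 0.0, 1.0)
    t = np.where(e > 1e-30, (b * s + f) / np.where(e > 1e-30, e, 1.0), 0.0)
    t = np.clip(t, 0.0, 1.0)
    # re-clamp s for clamped t
    s = np.where(a > 1e-30, (b * t - c) / np.where(a > 1e-30, a, 1.0), 0.0)
    s = np.clip(s, 0.0, 1.0)
    closest1 = p1 + s[:, None] * d1
    closest2 = p2 + t[:, None] * d2
    return np.linalg.norm(closest1 - closest2, axis=1)


def min_nonadjacent_segment_distance(vertices: np.ndarray) -> float:
    """Minimum distance between all pairs of non-adjacent polyline segments.

    Segments sharing a vertex are skipped.  Brute force over all pairs;
    intended for trajectory validation, not inner loops.
    """
    verts = np.asarray(vertices, float)
    nseg = len(verts) - 1
    if nseg < 3:
        return np.inf
    i, j = np.triu_indices(nseg, k=2)
    return float(
        _segment_pair_distances(verts[i], verts[i + 1], verts[j], verts[j + 1]).min()
    )


@dataclass
class LeadModel:
    """Implanted lead as an ordered proximal-to-distal 3-D polyline.

    The distal ``exposed_span`` metres of arc length carry the four
    un-insulated electrode contacts; everything proximal is insulated.
    The tip is the last vertex.
    """

    vertices: np.ndarray
    outer_diameter: float = LEAD_OUTER_DIAMETER
    core_diameter: float = LEAD_CORE_DIAMETER
    contact_wall: float = LEAD_CONTACT_WALL
    exposed_span: float = LEAD_EXPOSED_SPAN

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be an (M, 3) array")
        if len(self.vertices) < 2:
            raise ValueError("lead needs at least two vertices")

    @property
    def tip(self) -> np.ndarray:
        return self.vertices[-1]

    def segment_lengths(self) -> np.ndarray:
        return np.linalg.norm(np.diff(self.vertices, axis=0), axis=1)

    def arc_length(self) -> float:
        return float(self.segment_lengths().sum())

    def cumulative_arc_length(self) -> np.ndarray:
        """Arc length from the proximal end to each vertex."""
        return np.concatenate([[0.0], np.cumsum(self.segment_lengths())])

    def point_at_arc_length(self, s: float) -> np.ndarray:
        """Interpolated point at arc length ``s`` from the proximal end."""
        cum = self.cumulative_arc_length()
        s = float(np.clip(s, 0.0, cum[-1]))
        k = int(np.searchsorted(cum, s, side="right") - 1)
        k = min(k, len(self.vertices) - 2)
        seg = cum[k + 1] - cum[k]
        frac = 0.0 if seg == 0 else (s - cum[k]) / seg
        return self.vertices[k] + frac * (self.vertices[k + 1] - self.vertices[k])

    def exposed_midpoint(self) -> np.ndarray:
        """Midpoint (by arc length) of the exposed electrode span."""
        return self.point_at_arc_length(self.arc_length() - self.exposed_span / 2.0)

    def tip_tangent(self) -> np.ndarray:
        """Unit tangent of the final segment (points distally)."""
        d = self.vertices[-1] - self.vertices[-2]
        return d / np.linalg.norm(d)

    def resample(self, step: float) -> np.ndarray:
        """Vertices resampled at uniform arc-length ``step`` (tip included)."""
        total = self.arc_length()
        n = max(int(np.ceil(total / step)), 1)
        s = np.linspace(0.0, total, n + 1)
        return np.array([self.point_at_arc_length(si) for si in s])

    def min_clearance(self) -> float:
        """Minimum distance between non-adjacent segments."""
        return min_nonadjacent_segment_distance(self.vertices)

    def validate(self, length_bounds: tuple[float, float] | None = None) -> None:
        """Check arc-length bounds and the self-clearance requirement."""
        if length_bounds is not None:
            lo, hi = length_bounds
            if not lo <= self.arc_length() <= hi:
                raise ValueError(
                    f"lead length {self.arc_length():.3f} m outside [{lo}, {hi}] m"
                )
        if self.min_clearance() <= self.outer_diameter:
            raise ValueError("non-adjacent lead segments closer than the lead diameter")


# --------------------------------------------------------------------------
# Region masks
# --------------------------------------------------------------------------


@dataclass
class RegionMask:
    """Boolean voxel region on a grid, tagged by its role (VOI / ROM / HEAD)."""

    mask: np.ndarray
    grid: Grid3D
    role: str = "VOI"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, bool)
        if self.mask.shape != tuple(self.grid.dims):
            raise ValueError("mask shape does not match grid dims")
        if not self.mask.any():
            raise ValueError(f"empty {self.role} mask")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class VoiSpec:
    """Elliptical-column volume of interest: semi-axes r_x, r_y, length L along z.

    Defaults place the column over the approximate brain location when the
    head is centred in the coil.
    """

    center: tuple[float, float, float] = (-0.005, 0.010, 0.030)
    r_x: float = 0.060
    r_y: float = 0.075
    length: float = 0.045

    def __post_init__(self) -> None:
        if self.r_x <= 0 or self.r_y <= 0 or self.length <= 0:
            raise ValueError("VOI radii and length must be positive")

    def contains(self, x, y, z):
        cx, cy, cz = self.center
        return (((x - cx) / self.r_x) ** 2 + ((y - cy) / self.r_y) ** 2 <= 1.0) & (
            np.abs(z - cz) <= self.length / 2.0
        )


def build_voi_mask(grid: Grid3D, voi_spec: VoiSpec | None = None) -> RegionMask:
    """Voxelize the elliptical-column VOI by voxel-centre membership."""
    spec = voi_spec or VoiSpec()
    gx, gy, gz = grid.coordinate_arrays()
    mask = spec.contains(gx, gy, gz)
    if not mask.any():
        raise ValueError("empty VOI: the specified column misses the grid")
    return RegionMask(mask=mask, grid=grid, role="VOI")


def build_rom_mask(
    grid: Grid3D,
    lead: LeadModel,
    tissue: TissueModel,
    target_mass: float = 1e-3,
) -> RegionMask:
    """1 g region of minimization around the exposed lead tip.

    An axis-aligned cube of whole voxels centred on the exposed-span
    midpoint is grown one voxel shell at a time until the tissue mass it
    encloses reaches ``target_mass`` (kg).  Insulation voxels carry no
    mass and are excluded from the region.
    """
    head_tissue = tissue.head_mask & ~tissue.insulation_mask
    try:
        tip_idx = grid.index_of(lead.tip)
    except ValueError as exc:
        raise ValueError("lead tip lies outside the grid") from exc
    if not tissue.head_mask[tip_idx]:
        raise ValueError("lead tip lies outside the head mask")
    if tissue.head_mass() < target_mass:
        raise ValueError("whole-head tissue mass is below the averaging mass")

    ci, cj, ck = grid.index_of(lead.exposed_midpoint())
    dims = grid.dims
    dv = grid.voxel_volume
    max_half = max(dims)
    for half in range(max_half + 1):
        sl = tuple(
            slice(max(c - half, 0), min(c + half + 1, n))
            for c, n in zip((ci, cj, ck), dims)
        )
        cube = np.zeros(dims, bool)
        cube[sl] = True
        region = cube & head_tissue
        mass = float(tissue.rho[region].sum() * dv)
        if mass >= target_mass:
            return RegionMask(mask=region, grid=grid, role="ROM")
    raise ValueError("could not enclose the averaging mass within the grid")


# --------------------------------------------------------------------------
# Hampel filtering
# --------------------------------------------------------------------------

_MAD_SCALE = 1.4826  # consistency factor: MAD -> Gaussian sigma


def hampel_filter(values, window: int = 5, k: float = 3.0) -> np.ndarray:
    """Hampel outlier filter for a 1-D sequence.

    Each sample is compared with the median ``m`` of its centred window
    (truncated at the edges).  If it deviates from ``m`` by more than
    ``k`` times the scaled median absolute deviation it is replaced by
    ``m``.  A zero MAD degenerates to "replace anything different from
    the median".
    """
    x = np.asarray(values, float)
    if x.ndim != 1:
        raise ValueError("hampel_filter expects a 1-D sequence")
    if x.size == 0:
        raise ValueError("empty input")
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 3")
    if k < 0:
        raise ValueError("threshold k must be >= 0")
    half = window // 2
    out = x.copy()
    for i in range(x.size):
        win = x[max(0, i - half): i + half + 1]
        m = np.median(win)
        s = _MAD_SCALE * np.median(np.abs(win - m))
        dev = abs(x[i] - m)
        if (s == 0 and x[i] != m) or (s > 0 and dev > k * s):
            out[i] = m
    return out


def hampel_filter_volume(volume: np.ndarray, window: int = 5, k: float = 3.0) -> np.ndarray:
    """Hampel filter a 3-D volume along each grid axis in sequence (x, y, z)."""
    arr = np.asarray(volume, float)
    if arr.ndim != 3:
        raise ValueError("expected a 3-D volume")
    for axis in range(3):
        arr = np.apply_along_axis(hampel_filter, axis, arr, window, k)
    return arr
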