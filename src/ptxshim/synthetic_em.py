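"""Desk-scale electromagnetic surrogate for pTx coil arrays loading a head phantom.

Replaces a full-wave solver with a quasi-static model that keeps the one
property the shimming method relies on: every field is strictly linear
in the per-channel drives.

* Per-channel background fields come from Biot-Savart / vector-potential
  integration over rectangular loop elements wrapped on a cylinder:
  B(r) from the loop current, b1+ = (Bx + i By)/2, and E = -i omega A
  (scaled by a dimensionless calibration factor so that background power
  deposition sits at realistic head-coil levels once B1+ is normalized).
* Implant coupling is a transfer-function-style model: each channel's
  tangential E along the lead is integrated with an exponential weight
  toward the distal end, and the resulting complex coupling coefficient
  drives a localized E hot spot at the exposed tip.  The hot spot is a
  linear functional of the channel drives, so superposition is exact.

Wavelength effects, dielectric loading and conductor interactions are
deliberately out of scope.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .core_model import Grid3D, LeadModel, TissueModel
from .shim_core import CoilFieldMaps

__all__ = [
    "CoilArray",
    "HeadEllipsoid",
    "SyntheticConfig",
    "generate_coil_array",
    "birdcage_array",
    "generate_head_phantom",
    "voxelize_lead_insulation",
    "generate_lead_trajectory",
    "compute_coil_maps",
    "apply_rigid_transform",
    "rotation_matrix",
]

MU0 = 4e-7 * np.pi
_SUPPORTED_CHANNELS = (1, 2, 4, 8, 16)


# --------------------------------------------------------------------------
# Coil array
# --------------------------------------------------------------------------


@dataclass
class CoilArray:
    """N rectangular loop elements wrapped on a cylinder around the bore axis.

    Element n is centred at azimuth 2 pi n / N; each loop spans the full
    cylinder height with an azimuthal arc of ``arc_length`` metres.
    """

    n_channels: int
    radius: float = 0.125
    height: float = 0.15
    arc_length: float | None = None
    segments_per_arc: int = 10
    segments_per_leg: int = 5
    frequency: float = 128e6

    def __post_init__(self) -> None:
        if self.n_channels not in _SUPPORTED_CHANNELS:
            raise ValueError(f"n_channels must be one of {_SUPPORTED_CHANNELS}")
        if self.arc_length is None:
            # abutting elements: arc = circumference / N
            self.arc_length = 2.0 * np.pi * self.radius / self.n_channels
        if self.arc_length * self.n_channels > 2.0 * np.pi * self.radius * (1 + 1e-9):
            raise ValueError("element arcs overlap on the cylinder")

    def element_azimuths(self) -> np.ndarray:
        return 2.0 * np.pi * np.arange(self.n_channels) / self.n_channels

    def element_loop(self, n: int) -> np.ndarray:
        """Closed polyline (M, 3) of element ``n`` on the cylinder surface."""
        theta_c = 2.0 * np.pi * n / self.n_channels
        half = self.arc_length / (2.0 * self.radius)
        t1, t2 = theta_c - half, theta_c + half
        z1, z2 = -self.height / 2.0, self.height / 2.0

        def ring(theta):
            return np.stack(
                [
                    self.radius * np.cos(theta),
                    self.radius * np.sin(theta),
                    np.full_like(theta, np.nan),
                ],
                axis=-1,
            )

        bot = ring(np.linspace(t1, t2, self.segments_per_arc + 1))
        bot[:, 2] = z1
        top = ring(np.linspace(t2, t1, self.segments_per_arc + 1))
        top[:, 2] = z2
        up = np.linspace(bot[-1], top[0], self.segments_per_leg + 1)[1:-1]
        down = np.linspace(top[-1], bot[0], self.segments_per_leg + 1)[1:-1]
        loop = np.concatenate([bot, up, top, down, bot[:1]], axis=0)
        return loop


def generate_coil_array(n_channels: int, **overrides) -> CoilArray:
    """Coil array with elements 2 pi / N radians apart on the cylinder."""
    return CoilArray(n_channels=n_channels, **overrides)


def birdcage_array(**overrides) -> CoilArray:
    """Reference volume-coil emulation: 16 elements on a 28 cm diameter,
    35 cm tall cylinder, always driven with fixed quadrature weights."""
    params = dict(n_channels=16, radius=0.14, height=0.35)
    params.update(overrides)
    return CoilArray(**params)


# --------------------------------------------------------------------------
# Head phantom
# --------------------------------------------------------------------------


@dataclass
class HeadEllipsoid:
    """Homogeneous ellipsoidal head: centre, semi-axes and orientation."""

    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    semi_axes: tuple[float, float, float] = (0.070, 0.080, 0.065)
    orientation: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.semi_axes):
            raise ValueError("ellipsoid semi-axes must be positive")
        self.orientation = np.asarray(self.orientation, float)

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Membership test for an (..., 3) array of points."""
        p = np.asarray(points, float)
        local = (p - np.asarray(self.center)) @ self.orientation
        q = local / np.asarray(self.semi_axes)
        return np.sum(q * q, axis=-1) <= 1.0

    def axis_extents(self) -> np.ndarray:
        """Half-extent of the (rotated) ellipsoid along each world axis."""
        M = self.orientation * np.asarray(self.semi_axes)
        return np.sqrt(np.sum(M * M, axis=1))

    def surface_z(self, x: float, y: float) -> float:
        """Top-surface z at (x, y) for an axis-aligned ellipsoid."""
        cx, cy, cz = self.center
        rx, ry, rz = self.semi_axes
        rad = 1.0 - ((x - cx) / rx) ** 2 - ((y - cy) / ry) ** 2
        if rad <= 0:
            raise ValueError("point lies outside the ellipsoid footprint")
        return cz + rz * np.sqrt(rad)

    def outward_normal(self, point: np.ndarray) -> np.ndarray:
        """Unit outward normal of the ellipsoid surface nearest ``point``."""
        local = (np.asarray(point, float) - np.asarray(self.center)) @ self.orientation
        grad_local = 2.0 * local / np.asarray(self.semi_axes) ** 2
        grad = self.orientation @ grad_local
        return grad / np.linalg.norm(grad)


def _check_head_fits(grid: Grid3D, head: HeadEllipsoid) -> None:
    ext = head.axis_extents()
    for (lo, hi), c, e in zip(grid.extent(), head.center, ext):
        if c - e < lo or c + e > hi:
            raise ValueError("head ellipsoid does not fit inside the grid")


def voxelize_lead_insulation(
    grid: Grid3D, lead: LeadModel, step: float | None = None
) -> np.ndarray:
    """Boolean mask of voxels traversed by the insulated portion of the lead."""
    step = step or min(grid.spacing) / 2.0
    pts = lead.resample(step)
    # drop the distal exposed span
    cum = np.concatenate(
        [[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))]
    )
    insulated = pts[cum <= cum[-1] - lead.exposed_span]
    mask = np.zeros(tuple(grid.dims), bool)
    idx = np.round(
        (insulated - np.asarray(grid.origin)) / np.asarray(grid.spacing)
    ).astype(int)
    ok = np.all(idx >= 0, axis=1) & np.all(idx <= np.array(grid.dims) - 1, axis=1)
    idx = idx[ok]
    mask[idx[:, 0], idx[:, 1], idx[:, 2]] = True
    return mask


def generate_head_phantom(
    grid: Grid3D,
    head: HeadEllipsoid | None = None,
    lead: LeadModel | None = None,
    **tissue_overrides: float,
) -> TissueModel:
    """Voxelize a homogeneous ellipsoidal head (optionally with lead insulation).

    Every in-head voxel receives the uniform 128 MHz tissue properties
    (sigma = 0.69 S/m, eps_r = 67 by default); insulation voxels get the
    insulation overrides.
    """
    head = head or HeadEllipsoid()
    _check_head_fits(grid, head)
    gx, gy, gz = grid.coordinate_arrays()
    pts = np.stack(np.broadcast_arrays(gx, gy, gz), axis=-1)
    mask = head.contains(pts)
    if not mask.any():
        raise ValueError("head ellipsoid contains no voxel centres")
    ins = (
        voxelize_lead_insulation(grid, lead) if lead is not None else None
    )
    return TissueModel.homogeneous(grid, mask, insulation_mask=ins, **tissue_overrides)


# --------------------------------------------------------------------------
# Lead trajectory generator
# --------------------------------------------------------------------------


@dataclass
class TrajectoryParams:
    """Tunable geometry of the synthetic DBS lead trajectory."""

    n_turns: int = 4
    length_range: tuple[float, float] = (0.42, 0.48)
    turn_offset: float = 0.003      # normal spacing between loop passes (m)
    points_per_turn: int = 48
    entry_lateral: float = 0.025    # burr-hole |x| (m)
    target_lateral: float = 0.012   # deep-target |x| (m)
    target_depth: tuple[float, float] = (0.005, 0.020)  # (y, z) of target (m)
    jitter: float = 0.003           # uniform +- positional jitter (m)
    max_repair_attempts: int = 5


def _gerono_loops(
    a: float, n_turns: int, offset: float, points_per_turn: int,
    u: np.ndarray, v: np.ndarray, n_hat: np.ndarray,
) -> np.ndarray:
    """Stacked figure-eight (Gerono lemniscate) turns with a normal drift.

    The drift separates the two centre crossings within each turn by
    offset/2 and chains consecutive turns continuously, guaranteeing
    strand-to-strand clearance of offset/2 by construction.
    """
    t = np.linspace(0.0, 2.0 * np.pi * n_turns, points_per_turn * n_turns + 1)
    planar = a * np.sin(t)[:, None] * u + a * (np.sin(t) * np.cos(t))[:, None] * v
    lift = (t / (2.0 * np.pi))[:, None] * offset * n_hat
    return planar + lift


def generate_lead_trajectory(
    lateralization: str,
    head: HeadEllipsoid | None = None,
    params: TrajectoryParams | None = None,
    seed: int = 0,
) -> LeadModel:
    """Seeded synthetic DBS lead: figure-eight loop bundle at the skull
    vertex plus a straight penetrating segment to a lateralized deep target.

    The polyline runs proximal to distal (the tip is the last vertex),
    has total arc length inside the configured 40-50 cm band, and keeps
    non-adjacent segments farther apart than the lead diameter.
    """
    if lateralization not in ("left", "right"):
        raise ValueError("lateralization must be 'left' or 'right'")
    head = head or HeadEllipsoid()
    p = params or TrajectoryParams()
    rng = np.random.default_rng(seed)
    side = -1.0 if lateralization == "left" else 1.0

    jit = lambda: rng.uniform(-p.jitter, p.jitter, size=3)
    target = np.array(
        [side * p.target_lateral, p.target_depth[0], p.target_depth[1]]
    ) + jit()
    entry_xy = np.array([side * p.entry_lateral, -0.005]) + jit()[:2] * 0.5
    entry = np.array(
        [entry_xy[0], entry_xy[1], head.surface_z(entry_xy[0], entry_xy[1])]
    )

    n_hat = head.outward_normal(entry)
    u = np.cross(n_hat, [0.0, 1.0, 0.0])
    u /= np.linalg.norm(u)
    v = np.cross(n_hat, u)
    # randomize loop-plane orientation
    ang = rng.uniform(0.0, 2.0 * np.pi)
    u, v = np.cos(ang) * u + np.sin(ang) * v, -np.sin(ang) * u + np.cos(ang) * v

    loop_center = entry + 0.004 * n_hat
    stem = 0.004 + np.linalg.norm(target - entry)
    total_target = rng.uniform(*p.length_range)

    offset = p.turn_offset
    for attempt in range(p.max_repair_attempts):
        # solve the lemniscate scale for the length budget (secant, 3 steps)
        a = (total_target - stem) / (6.1 * p.n_turns)
        for _ in range(3):
            loops = _gerono_loops(
                a, p.n_turns, offset, p.points_per_turn, u, v, n_hat
            )
            loop_len = np.linalg.norm(np.diff(loops, axis=0), axis=1).sum()
            a *= (total_target - stem) / loop_len
        loops = _gerono_loops(a, p.n_turns, offset, p.points_per_turn, u, v, n_hat)

        # proximal -> distal: outer end of the bundle, down to the base,
        # through the burr hole, straight to the target
        verts = np.concatenate(
            [loop_center + loops[::-1], [entry], [target]], axis=0
        )
        lead = LeadModel(vertices=verts)
        clearance = lead.min_clearance()
        if clearance > lead.outer_diameter:
            lo, hi = 0.40, 0.50
            if not lo <= lead.arc_length() <= hi:
                raise ValueError(
                    f"generated lead length {lead.arc_length():.3f} m "
                    f"outside [{lo}, {hi}] m"
                )
            return lead
        offset *= 1.4  # local repair: widen the strand spacing and rebuild
    raise ValueError(
        f"could not achieve lead self-clearance after {p.max_repair_attempts} "
        f"attempts (last clearance {clearance:.2e} m)"
    )


# --------------------------------------------------------------------------
# Field synthesis
# --------------------------------------------------------------------------


@dataclass
class SyntheticConfig:
    """Knobs of the surrogate field generator.

    ``background_e_scale`` calibrates the quasi-static E/B ratio to
    head-coil power-deposition levels; ``coupling_gain`` (1/m) converts
    the lead line-integral (volts) into the tip E hot-spot amplitude.
    """

    attenuation_length: float = 0.10   # l_a: coupling memory along the lead (m)
    tip_spread: float = 0.003          # delta: hot-spot decay length (m)
    coupling_gain: float = 485.0       # 1/m
    background_e_scale: float = 0.53   # dimensionless E calibration
    axial_potential: float = 1.6e-7    # T m: array-level end-ring-like E_z potential
    axial_common: float = 0.5          # common-mode fraction of the axial E_z pattern
    frequency: float = 128e6
    lead_step: float = 0.00025         # line-integral resolution (m)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.attenuation_length <= 0 or self.tip_spread <= 0:
            raise ValueError("attenuation and spread lengths must be positive")

    @property
    def omega(self) -> float:
        return 2.0 * np.pi * self.frequency

    def to_json(self) -> str:
        return json.dumps(asdict(self))


def _loop_segments(loop: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Midpoints and dl vectors of a closed polyline's segments."""
    dl = np.diff(loop, axis=0)
    mid = 0.5 * (loop[:-1] + loop[1:])
    return mid, dl


def _biot_savart_and_potential(
    points: np.ndarray, loop: np.ndarray, r_min: float = 5e-3
) -> tuple[np.ndarray, np.ndarray]:
    """Magnetic field B and vector potential A of a unit loop current.

    Plain segment-wise Biot-Savart; distances are clamped at ``r_min``
    to keep the quadrature finite should a point graze a conductor.
    """
    mid, dl = _loop_segments(loop)
    B = np.zeros_like(points)
    A = np.zeros_like(points)
    pref = MU0 / (4.0 * np.pi)
    for m, d in zip(mid, dl):
        r = points - m
        dist = np.maximum(np.linalg.norm(r, axis=-1), r_min)
        B += pref * np.cross(np.broadcast_to(d, r.shape), r) / dist[..., None] ** 3
        A += pref * d / dist[..., None]
    return B, A


def _channel_background(
    points: np.ndarray,
    loop: np.ndarray,
    cfg: SyntheticConfig,
    azimuth: float = 0.0,
    axial_share: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-unit-drive background (E, b1+) at ``points`` for one element.

    E carries two parts: the loop's own vector potential (spatially
    structured, strongest near the conductors) and a spatially uniform
    axial component with channel phase e^{-i azimuth}, emulating the
    end-ring/axial E_z of a volume resonator.  The uniform part survives
    quadrature combination — as the axial E of a real birdcage does —
    and keeps implant coupling a smooth function of patient pose.
    ``axial_share`` apportions the array-level axial potential to one
    element (1/N), so the quadrature-mode axial E is independent of the
    channel count.  The pattern mixes a rotating term e^{-i azimuth}
    with a common-mode term (equal on all channels; it cancels under
    quadrature drive), so suppressing implant coupling does not force
    the transmit field's co-rotating mode to zero.
    """
    B, A = _biot_savart_and_potential(points, loop)
    A_total = A.astype(complex)
    A_total[..., 2] += (
        cfg.axial_potential
        * axial_share
        * (np.exp(-1j * azimuth) + cfg.axial_common)
    )
    E = -1j * cfg.omega * cfg.background_e_scale * A_total
    # Co-rotating transmit component under the e^{+i omega t} phasor
    # convention, so that quadrature drive (phi_n = 2 pi n / N) adds
    # constructively at the bore centre.
    b1p = 0.5 * (B[..., 0] - 1j * B[..., 1])
    return E, b1p


def _coupling_coefficient(
    lead: LeadModel,
    loop: np.ndarray,
    cfg: SyntheticConfig,
    azimuth: float = 0.0,
    axial_share: float = 1.0,
) -> complex:
    """kappa_n = integral E_n(s) . t(s) exp(-(L - s)/l_a) ds along the lead."""
    pts = lead.resample(cfg.lead_step)
    seg = np.diff(pts, axis=0)
    ds = np.linalg.norm(seg, axis=1)
    mid = 0.5 * (pts[:-1] + pts[1:])
    tangent = seg / ds[:, None]
    s_mid = np.concatenate([[0.0], np.cumsum(ds)])[:-1] + ds / 2.0
    L = ds.sum()
    E_mid, _ = _channel_background(mid, loop, cfg, azimuth, axial_share)
    weight = np.exp(-(L - s_mid) / cfg.attenuation_length)
    return complex(np.sum(np.einsum("ij,ij->i", E_mid, tangent) * weight * ds))


def compute_coil_maps(
    array: CoilArray,
    tissue: TissueModel,
    lead: LeadModel,
    grid: Grid3D,
    cfg: SyntheticConfig | None = None,
) -> CoilFieldMaps:
    """Per-channel (E, b1+) maps: smooth background plus implant-tip hot spot.

    Output is per unit drive, so arbitrary shim settings follow by exact
    linear superposition.
    """
    cfg = cfg or SyntheticConfig()
    if tuple(tissue.grid.dims) != tuple(grid.dims):
        raise ValueError("tissue model and grid dims disagree")
    dims = tuple(grid.dims)
    pts = grid.points()
    N = array.n_channels
    E = np.empty((N,) + dims + (3,), complex)
    B1 = np.empty((N,) + dims, complex)

    tip = lead.tip
    t_tip = lead.tip_tangent()
    dist_tip = np.linalg.norm(pts - tip, axis=1)
    tip_profile = np.exp(-dist_tip / cfg.tip_spread)

    azimuths = array.element_azimuths()
    share = 1.0 / N
    for n in range(N):
        loop = array.element_loop(n)
        E_bg, b1p = _channel_background(pts, loop, cfg, azimuths[n], share)
        kappa = _coupling_coefficient(lead, loop, cfg, azimuths[n], share)
        E_n = E_bg + (cfg.coupling_gain * kappa) * tip_profile[:, None] * t_tip
        E[n] = E_n.reshape(dims + (3,))
        B1[n] = b1p.reshape(dims)

    if not (np.all(np.isfinite(E)) and np.all(np.isfinite(B1))):
        raise ValueError("synthetic maps contain non-finite values")
    return CoilFieldMaps(
        grid=grid,
        E=E,
        B1=B1,
        frequency=cfg.frequency,
        meta={
            "generator": json.loads(cfg.to_json()),
            "n_channels": N,
            "coil": {
                "radius": array.radius,
                "height": array.height,
                "arc_length": array.arc_length,
            },
        },
    )


# --------------------------------------------------------------------------
# Rigid transforms
# --------------------------------------------------------------------------


def rotation_matrix(angles_deg) -> np.ndarray:
    """Rotation about world x, then y, then z axes (degrees)."""
    ax, ay, az = np.deg2rad(np.asarray(angles_deg, float))
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


def apply_rigid_transform(
    obj: LeadModel | HeadEllipsoid,
    rotation_deg=(0.0, 0.0, 0.0),
    translation=(0.0, 0.0, 0.0),
    grid: Grid3D | None = None,
):
    """Rotate about the world origin, then translate.

    Lead polylines keep their lengths and inter-vertex distances exactly
    (orthogonal map); a transformed head is checked against the grid when
    one is supplied.
    """
    R = rotation_matrix(rotation_deg)
    t = np.asarray(translation, float)
    if not np.all(np.isfinite(R)) or not np.all(np.isfinite(t)):
        raise ValueError("transform parameters must be finite")
    if isinstance(obj, LeadModel):
        verts = obj.vertices @ R.T + t
        return LeadModel(
            vertices=verts,
            outer_diameter=obj.outer_diameter,
            core_diameter=obj.core_diameter,
            contact_wall=obj.contact_wall,
            exposed_span=obj.exposed_span,
        )
    if isinstance(obj, HeadEllipsoid):
        center = R @ np.asarray(obj.center, float) + t
        moved = HeadEllipsoid(
            center=tuple(center),
            semi_axes=obj.semi_axes,
            orientation=R @ obj.orientation,
        )
        if grid is not None:
            _check_head_fits(grid, moved)
        return moved
    raise TypeError(f"cannot transform object of type {type(obj).__name__}")
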