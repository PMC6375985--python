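"""Surrogate field generator: geometry, determinism, linearity and quadrature oracles."""

import numpy as np
import pytest

from ptxshim.core_model import Grid3D, LeadModel
from ptxshim.shim_core import combine_fields, normalize_weights, quadrature_weights
from ptxshim.sar_metrics import raw_sar
from ptxshim.core_model import build_voi_mask
from ptxshim.synthetic_em import (
    CoilArray,
    HeadEllipsoid,
    SyntheticConfig,
    _channel_background,
    _coupling_coefficient,
    apply_rigid_transform,
    compute_coil_maps,
    generate_coil_array,
    generate_head_phantom,
    generate_lead_trajectory,
    rotation_matrix,
)


class TestCoilArray:
    def test_four_elements_at_cardinal_azimuths(self):
        arr = generate_coil_array(4)
        np.testing.assert_allclose(
            np.degrees(arr.element_azimuths()), [0, 90, 180, 270]
        )

    def test_eight_element_arc_length(self):
        arr = generate_coil_array(8)
        assert arr.arc_length == pytest.approx(0.098, abs=2e-4)

    def test_single_element_at_zero_azimuth(self):
        arr = generate_coil_array(1)
        assert arr.element_azimuths().tolist() == [0.0]

    def test_overlapping_arcs_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            CoilArray(n_channels=4, radius=0.125, arc_length=0.25)

    def test_unsupported_channel_count_rejected(self):
        with pytest.raises(ValueError):
            generate_coil_array(5)

    def test_element_loops_lie_on_cylinder(self):
        arr = generate_coil_array(4)
        loop = arr.element_loop(1)
        radii = np.hypot(loop[:, 0], loop[:, 1])
        # arc points on the cylinder; leg points chord slightly inside
        assert radii.max() == pytest.approx(arr.radius, rel=1e-12)
        assert np.abs(loop[:, 2]).max() == pytest.approx(arr.height / 2)


class TestHeadPhantom:
    def test_in_head_conductivity(self):
        grid = Grid3D.centered((24, 28, 24), (0.008, 0.008, 0.008))
        tissue = generate_head_phantom(grid, HeadEllipsoid(semi_axes=(0.07, 0.08, 0.065)))
        head = tissue.head_mask
        assert head.any()
        np.testing.assert_allclose(tissue.sigma[head], 0.69)
        np.testing.assert_allclose(tissue.eps_r[head], 67.0)
        assert np.all(tissue.sigma[~head] == 0)

    def test_degenerate_ellipsoid_rejected(self):
        with pytest.raises(ValueError):
            HeadEllipsoid(semi_axes=(0.0, 0.08, 0.065))

    def test_head_too_large_for_grid(self):
        grid = Grid3D.centered((10, 10, 10), (0.004, 0.004, 0.004))
        with pytest.raises(ValueError, match="fit"):
            generate_head_phantom(grid, HeadEllipsoid())

    def test_mass_equals_density_times_voxelized_volume(self):
        grid = Grid3D.centered((24, 28, 24), (0.008, 0.008, 0.008))
        head = HeadEllipsoid(semi_axes=(0.06, 0.07, 0.06))
        tissue = generate_head_phantom(grid, head)
        n_in = int(head.contains(grid.points()).sum())
        assert tissue.head_mass() == pytest.approx(
            1000.0 * n_in * grid.voxel_volume, rel=1e-12
        )


def _independent_segment_distance(p, q, r, s):
    """Dense-sampling lower-effort oracle for segment-segment distance."""
    t = np.linspace(0, 1, 60)
    a = p[None] + t[:, None] * (q - p)[None]
    b = r[None] + t[:, None] * (s - r)[None]
    return np.min(np.linalg.norm(a[:, None] - b[None, :], axis=-1))


class TestLeadTrajectory:
    @pytest.mark.parametrize("seed", [0, 3, 9, 42])
    def test_total_length_in_band(self, seed):
        lead = generate_lead_trajectory("left", seed=seed)
        assert 0.40 <= lead.arc_length() <= 0.50

    def test_same_seed_bitwise_identical(self):
        a = generate_lead_trajectory("right", seed=5)
        b = generate_lead_trajectory("right", seed=5)
        np.testing.assert_array_equal(a.vertices, b.vertices)

    def test_different_seeds_differ(self):
        a = generate_lead_trajectory("left", seed=1)
        b = generate_lead_trajectory("left", seed=2)
        assert not np.array_equal(a.vertices, b.vertices)

    def test_nonadjacent_clearance_exceeds_diameter(self):
        lead = generate_lead_trajectory("left", seed=7)
        verts = lead.vertices
        nseg = len(verts) - 1
        best = np.inf
        for i in range(nseg):
            for j in range(i + 2, nseg):
                best = min(
                    best,
                    _independent_segment_distance(
                        verts[i], verts[i + 1], verts[j], verts[j + 1]
                    ),
                )
        assert best > lead.outer_diameter

    def test_lateralization_flips_tip_side(self):
        left = generate_lead_trajectory("left", seed=3)
        right = generate_lead_trajectory("right", seed=3)
        assert left.tip[0] < 0 < right.tip[0]

    def test_unknown_lateralization_rejected(self):
        with pytest.raises(ValueError):
            generate_lead_trajectory("bilateral", seed=0)


@pytest.fixture(scope="module")
def small_scene():
    grid = Grid3D.centered((12, 12, 12), (0.008, 0.008, 0.008))
    head = HeadEllipsoid(semi_axes=(0.04, 0.04, 0.04))
    tissue = generate_head_phantom(grid, head)
    verts = np.stack(
        [np.zeros(30), np.linspace(-0.15, 0.0, 30), np.linspace(0.12, 0.01, 30)],
        axis=1,
    )
    lead = LeadModel(vertices=verts)
    return grid, tissue, lead


class TestCoilMaps:
    def test_deterministic_given_config(self, small_scene):
        grid, tissue, lead = small_scene
        arr = generate_coil_array(4)
        cfg = SyntheticConfig(seed=3)
        a = compute_coil_maps(arr, tissue, lead, grid, cfg)
        b = compute_coil_maps(arr, tissue, lead, grid, cfg)
        np.testing.assert_array_equal(a.E, b.E)
        np.testing.assert_array_equal(a.B1, b.B1)

    def test_zero_gain_reduces_to_background(self, small_scene):
        grid, tissue, lead = small_scene
        arr = generate_coil_array(2)
        cfg = SyntheticConfig(coupling_gain=0.0)
        maps = compute_coil_maps(arr, tissue, lead, grid, cfg)
        pts = grid.points()
        azimuths = arr.element_azimuths()
        for n in range(2):
            E_bg, b1 = _channel_background(
                pts, arr.element_loop(n), cfg, azimuths[n], 1.0 / 2
            )
            np.testing.assert_allclose(maps.E[n].reshape(-1, 3), E_bg, rtol=1e-12)
            np.testing.assert_allclose(maps.B1[n].reshape(-1), b1, rtol=1e-12)

    def test_fields_linear_in_drive(self, small_scene):
        grid, tissue, lead = small_scene
        maps = compute_coil_maps(
            generate_coil_array(2), tissue, lead, grid, SyntheticConfig()
        )
        from ptxshim.shim_core import ShimWeights

        f1 = combine_fields(ShimWeights([1, 0], [0, 0]), maps)
        f2 = combine_fields(ShimWeights([2, 0], [0, 0]), maps)
        np.testing.assert_allclose(f2.E, 2 * f1.E, rtol=1e-12)
        np.testing.assert_allclose(f2.B1, 2 * f1.B1, rtol=1e-12)

    def test_coupling_coefficient_matches_fine_quadrature(self, small_scene):
        _, _, lead = small_scene
        arr = generate_coil_array(4)
        coarse = SyntheticConfig()
        fine = SyntheticConfig(lead_step=SyntheticConfig().lead_step / 10)
        for n in range(4):
            az = arr.element_azimuths()[n]
            k1 = _coupling_coefficient(lead, arr.element_loop(n), coarse, az, 0.25)
            k2 = _coupling_coefficient(lead, arr.element_loop(n), fine, az, 0.25)
            assert abs(k1 - k2) / abs(k2) < 1e-6

    def test_quadrature_tip_hot_spot_dominates_background(
        self, cohort_config, default_patient
    ):
        # the generator must give the optimizer something to suppress
        p = default_patient
        maps = compute_coil_maps(
            generate_coil_array(4), p.tissue, p.lead, p.grid, cohort_config.synthetic
        )
        voi = build_voi_mask(p.grid, cohort_config.voi)
        wq = normalize_weights(quadrature_weights(4), maps, voi)
        sar = raw_sar(combine_fields(wq, maps), p.tissue)
        tip_sar = sar.sar[p.grid.index_of(p.lead.tip)]
        background = np.percentile(sar.sar[p.tissue.head_mask], 95)
        assert tip_sar > background


class TestRigidTransform:
    def test_identity_leaves_geometry(self):
        lead = generate_lead_trajectory("left", seed=1)
        moved = apply_rigid_transform(lead)
        np.testing.assert_allclose(moved.vertices, lead.vertices, atol=1e-15)

    def test_rotation_preserves_arc_length_and_vertex_distances(self):
        lead = generate_lead_trajectory("left", seed=2)
        moved = apply_rigid_transform(lead, rotation_deg=(10, -7, 23), translation=(0.01, 0, -0.02))
        assert moved.arc_length() == pytest.approx(lead.arc_length(), rel=1e-9)
        np.testing.assert_allclose(
            moved.segment_lengths(), lead.segment_lengths(), rtol=1e-9
        )

    def test_composition_matches_matrix_product(self):
        lead = generate_lead_trajectory("right", seed=4)
        r1, t1 = (5.0, -3.0, 8.0), np.array([0.01, 0.02, -0.01])
        r2, t2 = (-2.0, 7.0, 1.0), np.array([-0.005, 0.0, 0.015])
        step = apply_rigid_transform(
            apply_rigid_transform(lead, r1, t1), r2, t2
        )
        R1, R2 = rotation_matrix(r1), rotation_matrix(r2)
        oracle = lead.vertices @ (R2 @ R1).T + (R2 @ t1 + t2)
        np.testing.assert_allclose(step.vertices, oracle, atol=1e-12)

    def test_head_leaving_grid_raises(self):
        grid = Grid3D.centered((24, 28, 24), (0.008, 0.008, 0.008))
        head = HeadEllipsoid(semi_axes=(0.06, 0.07, 0.06))
        with pytest.raises(ValueError, match="fit"):
            apply_rigid_transform(head, translation=(0.08, 0, 0), grid=grid)

    def test_ellipsoid_membership_preserved_under_transform(self):
        head = HeadEllipsoid(semi_axes=(0.05, 0.06, 0.05))
        rng = np.random.default_rng(6)
        pts = rng.uniform(-0.07, 0.07, (200, 3))
        inside = head.contains(pts)
        R = rotation_matrix((9, -4, 12))
        t = np.array([0.01, -0.02, 0.005])
        moved = apply_rigid_transform(head, (9, -4, 12), t)
        np.testing.assert_array_equal(moved.contains(pts @ R.T + t), inside)


def test_superposition_fidelity_against_simultaneous_drive(small_scene):
    """Combining per-channel maps equals computing with all drives applied at once."""
    grid, tissue, lead = small_scene
    arr = generate_coil_array(4)
    cfg = SyntheticConfig()
    maps = compute_coil_maps(arr, tissue, lead, grid, cfg)
    rng = np.random.default_rng(14)
    w = rng.normal(size=4) + 1j * rng.normal(size=4)
    from ptxshim.shim_core import ShimWeights

    combined = combine_fields(ShimWeights.from_complex(w), maps)
    # simultaneous drive: sum channel contributions inside the generator's
    # own primitives (background + coupling hot spot per channel)
    pts = grid.points()
    E_sim = np.zeros((len(pts), 3), complex)
    tip = lead.tip
    t_tip = lead.tip_tangent()
    profile = np.exp(-np.linalg.norm(pts - tip, axis=1) / cfg.tip_spread)
    azimuths = arr.element_azimuths()
    for n in range(4):
        E_bg, _ = _channel_background(pts, arr.element_loop(n), cfg, azimuths[n], 0.25)
        kappa = _coupling_coefficient(lead, arr.element_loop(n), cfg, azimuths[n], 0.25)
        E_sim += w[n] * (E_bg + cfg.coupling_gain * kappa * profile[:, None] * t_tip)
    np.testing.assert_allclose(
        combined.E.reshape(-1, 3), E_sim, rtol=1e-10, atol=1e-12
    )
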