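import numpy as np
import pytest

from pocketdyn.flexibility_metrics import (
    B_FROM_MSF,
    GAS_CONSTANT,
    DihedralEntropyProfile,
    backbone_dihedrals,
    calpha_bfactors,
    dihedral_angles,
    dihedral_entropy,
    kabsch_superpose,
    periodic_kde,
    rmsd_matrix,
)
from pocketdyn.synthetic_data import (
    VonMisesSpec,
    build_backbone,
    gen_torsion_ensemble,
    mixture_density,
    sample_vonmises_mixture,
    vonmises_entropy,
)
from pocketdyn.trajectory_io import AtomSelection, select

from conftest import make_ca_ensemble
from oracles import quaternion_min_rmsd


def rotation_z(deg):
    t = np.radians(deg)
    return np.array([[np.cos(t), -np.sin(t), 0], [np.sin(t), np.cos(t), 0], [0, 0, 1]])


class TestKabschSuperpose:
    def test_pure_rotation_removed(self, rng):
        frame = rng.normal(size=(6, 3))
        rotated = frame @ rotation_z(90).T
        ens = make_ca_ensemble(np.stack([frame, rotated]))
        res = kabsch_superpose(ens, AtomSelection(np.arange(6)), reference=0)
        assert res.per_frame_rmsd[0] == pytest.approx(0.0, abs=1e-10)
        assert res.per_frame_rmsd[1] == pytest.approx(0.0, abs=1e-8)

    def test_identical_frames_zero_rmsd(self, rng):
        frame = rng.normal(size=(5, 3))
        ens = make_ca_ensemble(np.broadcast_to(frame, (4, 5, 3)).copy())
        res = kabsch_superpose(ens, AtomSelection(np.arange(5)))
        assert np.allclose(res.per_frame_rmsd, 0.0, atol=1e-10)

    def test_displaced_atom_matches_quaternion_oracle(self, rng):
        base = rng.normal(size=(4, 3)) * 3.0
        moved = base.copy()
        moved[2] += [1.0, -0.5, 0.7]
        ens = make_ca_ensemble(np.stack([base, moved]))
        res = kabsch_superpose(ens, AtomSelection(np.arange(4)), reference=0)
        oracle = quaternion_min_rmsd(moved, base)
        assert res.per_frame_rmsd[1] == pytest.approx(oracle, abs=1e-4)

    def test_no_mirror_image(self):
        # a chiral 4-point set and its mirror: optimal proper rotation cannot
        # reach RMSD 0, a reflection could
        chiral = np.array([[0, 0, 0], [1.5, 0, 0], [0, 2.0, 0], [0, 0, 2.5]], dtype=float)
        mirror = chiral * np.array([1, 1, -1])
        ens = make_ca_ensemble(np.stack([chiral, mirror]))
        res = kabsch_superpose(ens, AtomSelection(np.arange(4)), reference=0)
        assert res.per_frame_rmsd[1] > 0.5

    def test_collinear_selection_rejected(self):
        line = np.stack([np.arange(4.0), np.zeros(4), np.zeros(4)], axis=1)
        ens = make_ca_ensemble(line[None])
        with pytest.raises(ValueError, match="collinear|degenerate"):
            kabsch_superpose(ens, AtomSelection(np.arange(4)))


class TestCalphaBfactors:
    def test_static_ensemble_zero(self, rng):
        frame = rng.normal(size=(4, 3))
        ens = make_ca_ensemble(np.broadcast_to(frame, (10, 4, 3)).copy())
        profile = calpha_bfactors(ens)
        assert all(v == 0.0 for v in profile.value_by_residue.values())

    def test_two_point_alternation(self):
        # CA hopping between two points 2 Å apart: MSF = 1 Å², B = 8π²/3
        coords = np.zeros((10, 1, 3))
        coords[1::2, 0, 0] = 2.0
        profile = calpha_bfactors(make_ca_ensemble(coords))
        res = next(iter(profile.value_by_residue))
        assert profile.msf_by_residue[res] == pytest.approx(1.0, abs=1e-12)
        assert profile.value_by_residue[res] == pytest.approx(B_FROM_MSF, abs=1e-9)

    def test_isotropic_gaussian_closed_form(self, rng):
        sigma = 0.5
        coords = rng.normal(0.0, sigma, size=(10_000, 1, 3))
        profile = calpha_bfactors(make_ca_ensemble(coords))
        res = next(iter(profile.value_by_residue))
        assert profile.value_by_residue[res] == pytest.approx(
            B_FROM_MSF * 3 * sigma**2, rel=0.05)

    def test_b_msf_identity(self, rng):
        coords = rng.normal(size=(50, 3, 3))
        profile = calpha_bfactors(make_ca_ensemble(coords))
        for res, b in profile.value_by_residue.items():
            assert b == pytest.approx(B_FROM_MSF * profile.msf_by_residue[res], rel=1e-12)


class TestBackboneDihedrals:
    def test_coplanar_anti_maps_to_minus_180(self):
        p = [np.array([[-1.0, 1.0, 0.0]]), np.array([[0.0, 0.0, 0.0]]),
             np.array([[1.0, 0.0, 0.0]]), np.array([[2.0, -1.0, 0.0]])]
        assert dihedral_angles(*p)[0] == pytest.approx(-180.0, abs=1e-9)

    def test_syn_periplanar_is_zero(self):
        p = [np.array([[-1.0, 1.0, 0.0]]), np.array([[0.0, 0.0, 0.0]]),
             np.array([[1.0, 0.0, 0.0]]), np.array([[2.0, 1.0, 0.0]])]
        assert dihedral_angles(*p)[0] == pytest.approx(0.0, abs=1e-9)

    def test_helix_round_trip(self):
        # chain built with fixed phi = -57, psi = -47: recomputed exactly
        from pocketdyn.synthetic_data import _backbone_topology
        from pocketdyn.trajectory_io import FrameEnsemble

        coords = build_backbone(np.full((2, 6), -57.0), np.full((2, 6), -47.0))
        ens = FrameEnsemble(_backbone_topology(6, "T"), coords)
        series = backbone_dihedrals(ens)
        assert len(series) == 10  # 5 phi + 5 psi
        for s in series:
            expected = -57.0 if s.angle_kind == "phi" else -47.0
            assert np.allclose(s.values, expected, atol=1e-6)

    def test_terminal_series_absent(self):
        gen = gen_torsion_ensemble([[VonMisesSpec(-60, 8)]] * 4,
                                   [[VonMisesSpec(-40, 8)]] * 4, 5, seed=1)
        series = backbone_dihedrals(gen.ensemble)
        kinds = {(s.residue.number, s.angle_kind) for s in series}
        assert (1, "phi") not in kinds and (4, "psi") not in kinds
        assert (2, "phi") in kinds and (3, "psi") in kinds

    def test_chain_break_suppresses_torsions(self):
        gen = gen_torsion_ensemble([[VonMisesSpec(-60, 8)]] * 4,
                                   [[VonMisesSpec(-40, 8)]] * 4, 2, seed=1)
        coords = gen.ensemble.coordinates.copy()
        coords[:, 6:] += 50.0  # separate residues 3-4 from 1-2
        ens = gen.ensemble.__class__(gen.ensemble.topology, coords)
        kinds = {(s.residue.number, s.angle_kind) for s in backbone_dihedrals(ens)}
        assert (3, "phi") not in kinds and (2, "psi") not in kinds


class TestPeriodicKde:
    def test_uniform_samples_flat_density(self, rng):
        grid, dens = periodic_kde(rng.uniform(-180, 180, 50_000))
        assert dens == pytest.approx(np.full_like(dens, 1 / 360.0), rel=0.15)
        dx = grid[1] - grid[0]
        assert dens.sum() * dx == pytest.approx(1.0, abs=1e-6)

    def test_boundary_cluster_single_mode(self, rng):
        samples = np.concatenate([
            rng.normal(179.9, 0.3, 25_000), rng.normal(-179.9, 0.3, 25_000)])
        samples = (samples + 180) % 360 - 180
        grid, dens = periodic_kde(samples, grid_points=720)
        # density at the boundary exceeds density 5 degrees away on each side
        at_edge = dens[np.argmin(np.abs(grid - (-180)))]
        inner = dens[np.abs(np.abs(grid) - 175) < 0.5].max()
        assert at_edge > 10 * inner
        # the mode sits at the wrap point itself: no edge-artifact dip there
        assert at_edge == pytest.approx(dens.max(), rel=0.02)

    def test_von_mises_l1_distance(self, rng):
        spec = [VonMisesSpec(30.0, 4.0)]
        samples = sample_vonmises_mixture(spec, 50_000, rng)
        grid, dens = periodic_kde(samples, grid_points=720)
        truth = mixture_density(grid, spec)
        dx = grid[1] - grid[0]
        assert np.abs(dens - truth).sum() * dx < 0.02

    def test_degenerate_samples_fall_back_with_warning(self):
        with pytest.warns(UserWarning, match="1 degree"):
            grid, dens = periodic_kde(np.zeros(100))
        dx = grid[1] - grid[0]
        assert dens.sum() * dx == pytest.approx(1.0, abs=1e-6)

    def test_requested_grid_size_respected(self, rng):
        grid, dens = periodic_kde(rng.uniform(-180, 180, 500), grid_points=360)
        assert len(grid) == len(dens) == 360


class TestDihedralEntropy:
    def test_shift_invariance(self, rng):
        samples = sample_vonmises_mixture([VonMisesSpec(0.0, 3.0)], 20_000, rng)
        base = dihedral_entropy(samples)
        for offset in (47.0, 170.0, 300.0):
            shifted = (samples + offset + 180) % 360 - 180
            assert dihedral_entropy(shifted) == pytest.approx(base, abs=0.1)

    def test_uniform_box_width_scaling(self, rng):
        # S tracks R ln w for uniform boxes; strictly increasing in w
        estimates = []
        for width in (1.0, 10.0, 60.0, 360.0):
            samples = rng.uniform(-width / 2, width / 2, 50_000)
            s = dihedral_entropy(samples)
            assert s == pytest.approx(GAS_CONSTANT * np.log(width), abs=1.0)
            estimates.append(s)
        assert np.all(np.diff(estimates) > 0)

    def test_grid_refinement_stable(self, rng):
        samples = sample_vonmises_mixture([VonMisesSpec(-60.0, 6.0)], 20_000, rng)
        s1 = dihedral_entropy(samples, grid_points=720)
        s2 = dihedral_entropy(samples, grid_points=1440)
        assert abs(s1 - s2) < 0.05

    def test_explicit_bandwidth_accepted(self, rng):
        samples = rng.uniform(-180, 180, 5000)
        s = dihedral_entropy(samples, bandwidth=5.0)
        assert s == pytest.approx(GAS_CONSTANT * np.log(360), abs=1.0)

    def test_profile_respects_uniform_ceiling(self, rng):
        kappas = [0.0, 0.5, 8.0]
        gen = gen_torsion_ensemble(
            [None] + [[VonMisesSpec(-60.0, k)] for k in kappas] + [None],
            [None] + [[VonMisesSpec(-40.0, k)] for k in kappas] + [None],
            2000, seed=3)
        from pocketdyn.flexibility_metrics import dihedral_entropy_profile

        profile = dihedral_entropy_profile(gen.ensemble)
        ceiling = GAS_CONSTANT * np.log(360.0)
        for s in list(profile.s_phi.values()) + list(profile.s_psi.values()):
            assert np.isfinite(s) and s <= ceiling + 0.1


class TestRmsdMatrix:
    def test_identical_frames_zero_matrix(self, rng):
        frame = rng.normal(size=(5, 3))
        ens = make_ca_ensemble(np.broadcast_to(frame, (4, 5, 3)).copy())
        mat = rmsd_matrix(ens, AtomSelection(np.arange(5)))
        assert np.allclose(mat.values, 0.0, atol=1e-7)

    def test_rigid_rotated_copies_zero_offdiagonal(self, rng):
        frame = rng.normal(size=(6, 3))
        ens = make_ca_ensemble(np.stack([frame, frame @ rotation_z(35).T + 2.0]))
        mat = rmsd_matrix(ens, AtomSelection(np.arange(6)))
        assert mat.values[0, 1] == pytest.approx(0.0, abs=1e-7)

    def test_matches_pairwise_quaternion_oracle(self, rng):
        coords = rng.normal(size=(5, 4, 3)) * 2.0
        ens = make_ca_ensemble(coords)
        mat = rmsd_matrix(ens, AtomSelection(np.arange(4)))
        for i in range(5):
            assert mat.values[i, i] == 0.0
            for j in range(i + 1, 5):
                oracle = quaternion_min_rmsd(coords[j], coords[i])
                assert mat.values[i, j] == pytest.approx(oracle, abs=1e-4)
                assert mat.values[i, j] == pytest.approx(mat.values[j, i], abs=1e-12)

    def test_stride(self, rng):
        ens = make_ca_ensemble(rng.normal(size=(10, 4, 3)))
        mat = rmsd_matrix(ens, AtomSelection(np.arange(4)), stride=3)
        assert mat.values.shape == (4, 4)

    def test_subset_support_mixture_blocks(self, rng):
        # conformational-selection analogue: a narrow ensemble supported on a
        # subset of a wide ensemble's states gives cross-RMSD no larger than
        # the wide ensemble's internal spread
        state_a = rng.normal(size=(6, 3)) * 3.0
        state_b = state_a + rng.normal(size=(6, 3)) * 2.0
        wide = [state_a + rng.normal(scale=0.05, size=(6, 3)) for _ in range(5)]
        wide += [state_b + rng.normal(scale=0.05, size=(6, 3)) for _ in range(5)]
        narrow = [state_a + rng.normal(scale=0.05, size=(6, 3)) for _ in range(5)]
        ens = make_ca_ensemble(np.stack(wide + narrow))
        mat = rmsd_matrix(ens, AtomSelection(np.arange(6)))
        within_wide = mat.values[:10, :10].max()
        cross = mat.values[10:, :10].max()
        # equal up to the within-state thermal noise (sigma = 0.05 per atom)
        assert cross <= within_wide + 3 * 0.05
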