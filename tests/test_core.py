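"""Affine fit, projection operator and chi: identities and invariances."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import nonaffine as na
from nonaffine.core import NeighborhoodDisplacement
from nonaffine import synthetic as syn

from conftest import random_neighborhood


class TestDisplacements:
    def test_reference_frame_gives_zero(self, helix, helix_nb):
        disp = na.displacements(helix, helix.positions, helix_nb)
        np.testing.assert_array_equal(disp.delta, 0.0)

    def test_global_translation_cancels(self, helix, helix_nb):
        frame = helix.positions + np.array([3.0, -2.0, 7.0])
        disp = na.displacements(helix, frame, helix_nb)
        np.testing.assert_allclose(disp.delta, 0.0, atol=1e-12)

    def test_hand_computed_two_neighbor_case(self):
        # u_center = 0, u_1 = (1,0,0), u_2 = (0,2,0) -> delta = (1,0,0,0,2,0)
        pos = np.array([[0.0, 0, 0], [2.0, 0, 0], [0, 2.0, 0], [5.0, 5, 5]])
        ref = syn._finalize_reference(pos, "hand")
        from nonaffine.neighborhoods import build_r_matrix

        nb = na.Neighborhood(
            center_index=0,
            member_indices=np.array([1, 2]),
            radius=3.0,
            R_matrix=build_r_matrix(pos[[1, 2]] - pos[0]),
        )
        frame = pos.copy()
        frame[1] += [1.0, 0, 0]
        frame[2] += [0, 2.0, 0]
        disp = na.displacements(ref, frame, nb)
        np.testing.assert_array_equal(disp.delta, [1, 0, 0, 0, 2, 0])


class TestProjectionOperator:
    def test_idempotent_symmetric(self, helix_proj):
        P = helix_proj.P
        assert np.abs(P @ P - P).max() < 1e-10
        assert np.abs(P - P.T).max() < 1e-12

    def test_trace_counts_nonaffine_dimensions(self, helix_nb, helix_proj):
        assert np.trace(helix_proj.P) == pytest.approx(helix_nb.dof - 9, abs=1e-8)

    def test_annihilates_affine_space(self, helix_nb, helix_proj):
        rng = np.random.default_rng(1)
        for _ in range(5):
            D0 = rng.normal(size=9)
            affine = helix_nb.R_matrix @ D0
            assert np.abs(helix_proj.P @ affine).max() < 1e-10 * np.abs(affine).max()


class TestChiEquivalence:
    def test_projection_equals_direct_minimisation(self):
        """The projection route and the explicit least-squares route agree
        to relative 1e-8 over randomized neighborhoods and displacements."""
        worst = 0.0
        for seed in range(100):
            ref, nb, rng = random_neighborhood(seed)
            proj = na.build_projection(nb)
            delta = rng.normal(0, 1.0, nb.dof)
            disp = NeighborhoodDisplacement(delta=delta)
            chi_p = na.chi_projected(disp, proj)
            fit = na.chi_direct(disp, nb)
            worst = max(worst, abs(chi_p - fit.residual) / fit.residual)
        assert worst < 1e-8

    def test_pure_affine_displacement_gives_zero_chi(self, helix_nb, helix_proj):
        rng = np.random.default_rng(2)
        D0 = rng.normal(size=9)
        delta = helix_nb.R_matrix @ D0
        disp = NeighborhoodDisplacement(delta=delta)
        assert na.chi_projected(disp, helix_proj) < 1e-10 * (delta @ delta)

    def test_zero_displacement_gives_zero_chi(self, helix_nb, helix_proj):
        disp = NeighborhoodDisplacement(delta=np.zeros(helix_nb.dof))
        assert na.chi_projected(disp, helix_proj) == 0.0

    def test_dimension_mismatch_raises(self, helix_proj):
        with pytest.raises(ValueError):
            na.chi_projected(NeighborhoodDisplacement(delta=np.ones(5)), helix_proj)


class TestChiDirect:
    def test_recovers_exact_affine_map(self, helix, helix_nb):
        rng = np.random.default_rng(3)
        D0 = np.eye(3) + 0.05 * rng.normal(size=(3, 3))
        delta = helix_nb.R_matrix @ D0.reshape(9)
        fit = na.chi_direct(NeighborhoodDisplacement(delta=delta), helix_nb)
        np.testing.assert_allclose(fit.D, D0, atol=1e-8)
        assert fit.residual < 1e-10

    def test_global_rotation_recovered_as_affine(self, helix, helix_nb):
        rot = Rotation.from_euler("xyz", [11.0, -7.0, 23.0], degrees=True).as_matrix()
        center = helix.positions[helix_nb.center_index]
        frame = center + (helix.positions - center) @ rot.T
        disp = na.displacements(helix, frame, helix_nb)
        fit = na.chi_direct(disp, helix_nb)
        # best-fit D is (rotation - identity) in the Delta convention
        np.testing.assert_allclose(fit.D + np.eye(3), rot, atol=1e-8)
        assert fit.residual < 1e-10 * (disp.delta @ disp.delta)

    def test_grid_search_never_beats_normal_equations(self, helix_nb):
        """Coarse grid scan of D around the optimum lower-bounds nothing:
        every scanned D gives a residual >= the normal-equation residual."""
        rng = np.random.default_rng(4)
        D0 = 0.1 * rng.normal(size=(3, 3))
        delta = helix_nb.R_matrix @ D0.reshape(9)
        delta[4] += 0.5  # single-component non-affine perturbation
        disp = NeighborhoodDisplacement(delta=delta)
        fit = na.chi_direct(disp, helix_nb)
        R = helix_nb.R_matrix
        for _ in range(200):
            D_try = fit.D + rng.normal(0, 0.02, size=(3, 3))
            r = delta - R @ D_try.reshape(9)
            assert r @ r >= fit.residual - 1e-12

    def test_perturbation_residual_equals_projected_norm(self, helix_nb, helix_proj):
        rng = np.random.default_rng(5)
        D0 = 0.1 * rng.normal(size=(3, 3))
        eps = np.zeros(helix_nb.dof)
        eps[7] = 0.3
        delta = helix_nb.R_matrix @ D0.reshape(9) + eps
        fit = na.chi_direct(NeighborhoodDisplacement(delta=delta), helix_nb)
        expected = float(eps @ helix_proj.P @ eps)
        assert fit.residual == pytest.approx(expected, rel=1e-8)


class TestInvariances:
    def test_rigid_motion_invariance(self, helix, helix_nb, helix_proj):
        rng = np.random.default_rng(6)
        frame = helix.positions + rng.normal(0, 0.5, helix.positions.shape)
        chi0 = na.chi_projected(na.displacements(helix, frame, helix_nb), helix_proj)
        rot = Rotation.from_euler("zyx", [40.0, 15.0, -60.0], degrees=True).as_matrix()
        moved = frame @ rot.T + np.array([10.0, 20.0, 30.0])
        chi1 = na.chi_projected(na.displacements(helix, moved, helix_nb), helix_proj)
        assert chi1 == pytest.approx(chi0, rel=1e-8)

    def test_subspace_additivity(self, helix_nb, helix_proj):
        """For Delta = affine + perpendicular component, chi = |perp|^2."""
        rng = np.random.default_rng(7)
        affine = helix_nb.R_matrix @ rng.normal(size=9)
        z = rng.normal(size=helix_nb.dof)
        perp = helix_proj.P @ z  # R^T perp = 0 by construction
        disp = NeighborhoodDisplacement(delta=affine + perp)
        assert na.chi_projected(disp, helix_proj) == pytest.approx(
            float(perp @ perp), rel=1e-8
        )

    def test_member_permutation_invariance(self, helix, helix_nb):
        rng = np.random.default_rng(8)
        frame = helix.positions + rng.normal(0, 0.5, helix.positions.shape)
        disp = na.displacements(helix, frame, helix_nb)
        chi0 = na.chi_direct(disp, helix_nb).residual
        perm = rng.permutation(helix_nb.n_members)
        nb_perm = na.Neighborhood(
            center_index=helix_nb.center_index,
            member_indices=helix_nb.member_indices[perm],
            radius=helix_nb.radius,
            R_matrix=helix_nb.R_matrix.reshape(-1, 3, 9)[perm].reshape(-1, 9),
        )
        disp_perm = na.displacements(helix, frame, nb_perm)
        chi1 = na.chi_direct(disp_perm, nb_perm).residual
        assert chi1 == pytest.approx(chi0, rel=1e-8)


class TestChiSeries:
    def test_matches_per_frame_projection(self, helix, helix_nb, helix_proj):
        ens = syn.isotropic_ensemble(helix, 0.4, 10, seed=9)
        series = na.chi_series(helix, ens, helix_nb)
        for t in range(ens.n_frames):
            disp = na.displacements(helix, ens.frames[t], helix_nb)
            assert series[t] == pytest.approx(
                na.chi_projected(disp, helix_proj), rel=1e-10
            )

    def test_per_atom_normalization(self, helix, helix_nb):
        ens = syn.isotropic_ensemble(helix, 0.4, 5, seed=10)
        raw = na.chi_series(helix, ens, helix_nb)
        per_atom = na.chi_series(helix, ens, helix_nb, per_atom=True)
        np.testing.assert_allclose(per_atom, raw / helix_nb.n_members)
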