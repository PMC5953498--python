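"""DT-J-substitution, two-current direct method, baselines and diagnostics."""

import numpy as np
import pytest

import dtjsub as dj
from dtjsub import recon
from dtjsub.forward import CurrentDensityField
from dtjsub.recon import _velocity


@pytest.fixture(scope="module")
def singleton_weights(rect_grid):
    return dj.make_weights(np.ones(rect_grid.shape), rect_grid, h=0.1,
                           neighborhood=1)


class TestWeightKernel:
    def test_constant_magnitude_gives_uniform_weights(self, rect_grid):
        w = dj.make_weights(np.ones(rect_grid.shape), rect_grid, h=0.5,
                            neighborhood=5)
        interior = np.zeros(rect_grid.shape, bool)
        interior[2:-2, 2:-2] = True
        assert np.allclose(w.weights[:, interior], 1.0 / 25)

    def test_h_zero_ignores_magnitude(self, rect_grid):
        rng = np.random.default_rng(0)
        S = rng.uniform(0.5, 2.0, rect_grid.shape)
        w = dj.make_weights(S, rect_grid, h=0.0, neighborhood=3)
        interior = np.zeros(rect_grid.shape, bool)
        interior[1:-1, 1:-1] = True
        assert np.allclose(w.weights[:, interior], 1.0 / 9)

    def test_weights_normalized_including_boundary(self, rect_grid):
        rng = np.random.default_rng(1)
        S = rng.uniform(0.5, 2.0, rect_grid.shape)
        w = dj.make_weights(S, rect_grid, h=2.0, neighborhood=5)
        total = w.weights.sum(axis=0)
        assert np.allclose(total[rect_grid.domain_mask], 1.0)
        assert np.all(w.weights >= 0)

    def test_large_h_concentrates_on_matching_magnitude(self, rect_grid):
        S = np.zeros(rect_grid.shape)
        S[10, 10] = 0.0
        S[10, 11] = 0.0          # the only matching neighbor
        S[9:12, 9:12] += 5.0
        S[10, 10] = 0.0
        S[10, 11] = 0.0
        w = dj.make_weights(S, rect_grid, h=50.0, neighborhood=3)
        k_self = w.offsets.index((0, 0))
        k_match = w.offsets.index((0, 1))
        assert w.weights[k_self, 10, 10] + w.weights[k_match, 10, 10] > 0.99

    def test_invalid_arguments(self, rect_grid):
        with pytest.raises(ValueError):
            dj.make_weights(np.ones(rect_grid.shape), rect_grid, h=-1.0)
        with pytest.raises(ValueError):
            dj.make_weights(np.ones(rect_grid.shape), rect_grid,
                            neighborhood=4)


class TestDtjUpdate:
    def test_true_potential_is_exact_fixed_point(self, forward_truth,
                                                 rect_grid,
                                                 singleton_weights):
        """With the true u and the consistent current, a singleton update
        reproduces eta exactly."""
        out = dj.dtj_update(forward_truth["J"], forward_truth["D"],
                            forward_truth["u"], singleton_weights)
        m = rect_grid.domain_mask & out.valid
        err = np.abs(out.eta[m] - forward_truth["eta"].eta[m])
        assert err.max() < 1e-10 * forward_truth["eta"].eta[m].max()

    def test_low_sensitivity_voxels_masked_and_filled(self, forward_truth,
                                                      rect_grid,
                                                      singleton_weights):
        J = forward_truth["J"]
        # zero the current in a block: denominators still fine, numerator 0;
        # instead zero the potential gradient region via a doctored u
        u = dj.PotentialField(grid=rect_grid, u=forward_truth["u"].u.copy())
        u.u[20:26, 20:26] = u.u[20:26, 20:26].mean()
        out = dj.dtj_update(J, forward_truth["D"], u, singleton_weights)
        assert not out.valid[22, 22]
        assert np.isfinite(out.eta).all()
        assert np.all(out.eta[rect_grid.domain_mask] > 0)

    def test_clipping_respects_anchor(self, forward_truth, rect_grid,
                                      singleton_weights):
        out = dj.dtj_update(forward_truth["J"], forward_truth["D"],
                            forward_truth["u"], singleton_weights,
                            anchor=0.5, clip_range=(0.9, 1.1))
        m = rect_grid.domain_mask
        assert out.eta[m].min() >= 0.45 - 1e-12
        assert out.eta[m].max() <= 0.55 + 1e-12


class TestDtjIterate:
    def test_starting_from_truth_converges_immediately(self, forward_truth,
                                                       rect_grid,
                                                       opposite_electrodes,
                                                       singleton_weights):
        state = dj.dtj_iterate(forward_truth["J"], forward_truth["D"],
                               opposite_electrodes, rect_grid,
                               eta0=forward_truth["eta"].eta.copy(),
                               weights=singleton_weights, n_max=10, tol=1e-3)
        assert state.converged
        assert state.n_iterations == 1
        assert state.history[0]["rel_change"] < 1e-3

    def test_scale_propagation_is_exact(self, default_result, rect_grid,
                                        singleton_weights):
        """Scaling eta0 by c scales every iterate by exactly c — the global
        scale of a single-current reconstruction is set by its anchor."""
        r = default_result
        el = r["electrodes"]
        m = rect_grid.domain_mask
        base = dj.dtj_iterate(r["Jp"], r["D_true"], el, rect_grid, eta0=0.5,
                              weights=singleton_weights, n_max=3,
                              keep_iterates=True)
        for c in (0.1, 10.0):
            sc = dj.dtj_iterate(r["Jp"], r["D_true"], el, rect_grid,
                                eta0=0.5 * c, weights=singleton_weights,
                                n_max=3, keep_iterates=True)
            for k in range(3):
                dev = np.abs(sc.eta_iterates[k][m]
                             / (c * base.eta_iterates[k][m]) - 1.0)
                assert dev.max() < 1e-10

    def test_phantom_recovery_within_five_iterations(self, default_result):
        assert default_result["metrics"]["eta_rel_rmse_sens"] < 0.05

    def test_history_records_residuals(self, default_result):
        h = default_result["state"].history
        assert len(h) == default_result["state"].n_iterations
        assert all(np.isfinite(e["data_residual"]) for e in h)

    def test_noise_degrades_recovery_monotonically(self, rect_grid,
                                                   default_result,
                                                   singleton_weights):
        """eta error grows with the Bz channel noise over a 10x sweep."""
        from dtjsub.forward import FluxDensityField
        r = default_result
        el = r["electrodes"]
        m = rect_grid.domain_mask
        truth = r["eta_true"].eta
        rng = np.random.default_rng(42)
        errs = []
        for sd in (2e-11, 2e-10):
            rmses = []
            for rep in range(4):
                noisy = FluxDensityField(
                    grid=r["Bz_true"].grid,
                    Bz=r["Bz_true"].Bz
                    + sd * rng.standard_normal(r["Bz_true"].Bz.shape))
                Jp = dj.recover_projected_current(noisy, rect_grid, el,
                                                  sigma0=0.3833,
                                                  smooth_sd=1.0)
                st = dj.dtj_iterate(Jp, r["D_true"], el, rect_grid, eta0=0.5,
                                    weights=singleton_weights, n_max=3)
                e = (st.eta.eta[m] - truth[m]) / truth[m]
                rmses.append(np.sqrt((e ** 2).mean()))
            errs.append(np.mean(rmses))
        assert errs[1] > errs[0]

    def test_convergence_identity_on_iterates(self, forward_truth, rect_grid,
                                              opposite_electrodes,
                                              singleton_weights):
        """Both sides of the energy identity agree within 2% on every iterate
        of the noise-free run."""
        state = dj.dtj_iterate(forward_truth["J"], forward_truth["D"],
                               opposite_electrodes, rect_grid, eta0=0.5,
                               weights=singleton_weights, n_max=5, tol=0.0,
                               keep_iterates=True)
        prev = state.eta0
        for k in range(state.n_iterations):
            res = dj.convergence_identity(
                forward_truth["J"], prev, state.u_iterates[k],
                forward_truth["eta"].eta, forward_truth["u"],
                forward_truth["D"], rect_grid)
            assert res["rel_mismatch"] < 0.02
            prev = state.eta_iterates[k]


class TestInterfaceDistinguishability:
    def test_normal_current_continuous_but_dinvj_jumps(self, rect_grid,
                                                       opposite_electrodes):
        """Across a sharp eta interface the normal component of J is
        continuous while that of D^-1 J jumps — the contrast the update
        exploits."""
        D, eta = dj.make_phantom(
            rect_grid, {"pattern": "concentric",
                        "eigenvalues": (1.7e-3, 0.3e-3, 0.3e-3)},
            {"background": 0.5,
             "inclusions": [{"center": (40, 40), "radius": 8, "eta": 0.25}]},
            seed=0)
        C = dj.ConductivityTensorField.from_eta_and_diffusion(eta, D)
        u = dj.solve_potential(C, opposite_electrodes, rect_grid)
        J = dj.compute_current_density(C, u, rect_grid,
                                       electrodes=opposite_electrodes)
        # x-interface crossing at fixed row through the inclusion center:
        # faces at i = 32, 40 are inside/outside; use face fluxes (normal J)
        j_row = 40
        fx = J.face_flux_x[:, j_row] / (rect_grid.spacing[1] * 1e-3)
        # D^-1 J normal component on cells on both sides of the left edge
        from dtjsub.recon import _dinv_j
        fxc, _ = _dinv_j(D, J)
        i_edge = 32          # inclusion spans i in [32, 48] at j = 40
        inside, outside = fxc[i_edge + 1, j_row], fxc[i_edge - 2, j_row]
        jump_dinv = abs(inside - outside) / max(abs(outside), 1e-30)
        jn_in = fx[i_edge + 1]
        jn_out = fx[i_edge - 1]
        jump_j = abs(jn_in - jn_out) / max(abs(jn_out), 1e-30)
        assert jump_dinv > 5 * jump_j
        # the jump is carried by the tangential gradient through the fiber
        # cross-terms; with the normal-normal coefficient continuous it is
        # well below the factor-2 eta contrast but clearly nonzero
        assert jump_dinv > 0.05


class TestIsotropicBaseline:
    def test_isotropic_phantom_recovery(self, rect_grid,
                                        opposite_electrodes):
        """Scalar J-substitution on an isotropic conductor whose variation is
        transverse to the current: a few percent RMSE within 5 iterations.

        (Variation along the current direction is invisible to a single
        injection — the normal current is continuous across such profiles —
        so this is the identifiable configuration.)"""
        n = 64
        _, jj = np.meshgrid(np.arange(n) + 0.5, np.arange(n) + 0.5,
                            indexing="ij")
        sigma = 0.3 * (1.0 + 0.2 * np.sin(2 * np.pi * jj / n))
        C = dj.ConductivityTensorField.isotropic(rect_grid, sigma)
        u = dj.solve_potential(C, opposite_electrodes, rect_grid)
        J = dj.compute_current_density(C, u, rect_grid,
                                       electrodes=opposite_electrodes)
        state = dj.isotropic_j_substitution(J, opposite_electrodes, rect_grid,
                                            sigma0=0.3, n_max=5)
        m = rect_grid.domain_mask
        err = (state.eta.eta[m] - sigma[m]) / sigma[m]
        assert np.sqrt((err ** 2).mean()) < 0.05

    def test_isotropic_fixed_point_at_true_potential(self, rect_grid,
                                                     opposite_electrodes,
                                                     singleton_weights):
        """sigma_true is an exact fixed point of the scalar update."""
        sigma = np.full(rect_grid.shape, 0.3)
        C = dj.ConductivityTensorField.isotropic(rect_grid, sigma)
        u = dj.solve_potential(C, opposite_electrodes, rect_grid)
        J = dj.compute_current_density(C, u, rect_grid,
                                       electrodes=opposite_electrodes)
        state = dj.isotropic_j_substitution(J, opposite_electrodes, rect_grid,
                                            sigma0=0.3, n_max=2)
        assert state.history[0]["rel_change"] < 1e-10

    def test_residual_exceeds_dtj_on_anisotropic_phantom(self,
                                                         default_result):
        r = default_result
        assert (r["metrics"]["iso_final_residual"]
                > r["metrics"]["dtj_final_residual"])


class TestTwoCurrentDirect:
    def test_constant_eta_recovered_constant(self, rect_grid):
        D, eta = dj.make_phantom(
            rect_grid, {"pattern": "parallel", "angle_deg": 30.0},
            {"background": 0.7}, seed=0)
        C = dj.ConductivityTensorField.from_eta_and_diffusion(eta, D)
        Js = []
        for spec in ([{"kind": "edge", "edge": "left", "polarity": +1},
                      {"kind": "edge", "edge": "right", "polarity": -1}],
                     [{"kind": "edge", "edge": "top", "polarity": +1},
                      {"kind": "edge", "edge": "bottom", "polarity": -1}]):
            el = dj.make_electrodes(rect_grid, spec, current_mA=2.0)
            u = dj.solve_potential(C, el, rect_grid)
            Js.append(dj.compute_current_density(C, u, rect_grid,
                                                 electrodes=el))
        out = dj.two_current_direct(Js[0], Js[1], D, rect_grid, anchor=0.7)
        m = rect_grid.domain_mask
        assert np.ptp(out.eta[m]) / 0.7 < 0.01

    def test_smooth_exponential_recovery(self, exp_phantom, rect_grid):
        D, eta, (J1, J2) = exp_phantom
        m = rect_grid.domain_mask
        anchor = float(np.exp(np.mean(np.log(eta.eta[m]))))
        out = dj.two_current_direct(J1, J2, D, rect_grid, anchor=anchor)
        ln_err = np.log(out.eta[m]) - np.log(eta.eta[m])
        assert np.sqrt((ln_err ** 2).mean()) < 0.05 * np.ptp(np.log(eta.eta[m]))

    def test_identical_currents_raise_rank_deficiency(self, exp_phantom,
                                                      rect_grid):
        D, _, (J1, _) = exp_phantom
        with pytest.raises(ValueError, match="rank-deficient"):
            dj.two_current_direct(J1, J1, D, rect_grid)


class TestDiagnostics:
    def test_angle_zero_for_matching_isotropic_fields(self, rect_grid,
                                                      opposite_electrodes):
        C = dj.ConductivityTensorField.isotropic(rect_grid, 0.3)
        u = dj.solve_potential(C, opposite_electrodes, rect_grid)
        comp = np.zeros(rect_grid.shape + (6,))
        comp[..., [0, 2, 5]] = 1.0e-3
        D_iso = dj.DiffusionTensorField(grid=rect_grid, components=comp)
        am = dj.angle_map(D_iso, u, u)
        assert np.abs(am.alpha[am.valid]).max() < 1e-6

    def test_angle_ninety_for_orthogonal_fields(self, rect_grid):
        X, Y = rect_grid.voxel_centers()
        ux = dj.PotentialField(grid=rect_grid, u=X * 1e-3)
        uy = dj.PotentialField(grid=rect_grid, u=Y * 1e-3)
        comp = np.zeros(rect_grid.shape + (6,))
        comp[..., [0, 2, 5]] = 1.0e-3
        D_iso = dj.DiffusionTensorField(grid=rect_grid, components=comp)
        am = dj.angle_map(D_iso, ux, uy)
        inner = am.valid & np.roll(am.valid, 1, 0)
        assert np.allclose(am.alpha[inner], 90.0, atol=1e-6)

    def test_angle_matches_direct_vector_arithmetic(self, forward_truth,
                                                    default_result,
                                                    rect_grid):
        am = dj.angle_map(forward_truth["D"], default_result["state"].u,
                          forward_truth["u"])
        gxn, gyn = default_result["state"].u.gradient()
        vx, vy = _velocity(forward_truth["D"], gxn, gyn)
        gx, gy = forward_truth["u"].gradient()
        cosa = ((vx * gx + vy * gy)
                / (np.hypot(vx, vy) * np.hypot(gx, gy) + 1e-300))
        expect = np.degrees(np.arccos(np.clip(cosa, -1, 1)))
        assert np.allclose(am.alpha[am.valid], expect[am.valid], atol=1e-9)
        assert am.alpha.min() >= 0.0 and am.alpha.max() <= 180.0

    def test_recovery_error_anticorrelates_with_sensitivity(self,
                                                            default_result,
                                                            rect_grid):
        """Voxels in the top error decile have lower update sensitivity than
        the domain median."""
        r = default_result
        m = rect_grid.domain_mask
        err = np.abs(r["eta"].eta - r["eta_true"].eta) / r["eta_true"].eta
        thresh = np.percentile(err[m], 90)
        worst = m & (err >= thresh)
        sens = r["sensitivity"]
        assert np.median(sens[worst]) < np.median(sens[m])


class TestOutputs:
    def test_mean_conductivity_of_diagonal_tensor(self, rect_grid):
        comp = np.zeros(rect_grid.shape + (6,))
        comp[..., 0], comp[..., 2], comp[..., 5] = 1.0, 2.0, 3.0
        C = dj.ConductivityTensorField(grid=rect_grid, components=comp)
        assert np.allclose(dj.mean_conductivity(C), 2.0)

    def test_mean_conductivity_matches_reported_roi_arithmetic(self):
        # diagonal entries as printed for a CSF region: 1.62, 1.52, 1.64
        assert (1.62 + 1.52 + 1.64) / 3 == pytest.approx(1.5933, abs=1e-4)
        g = dj.make_grid((3, 3), 1.0, "full")
        comp = np.zeros((3, 3, 6))
        comp[..., 0], comp[..., 2], comp[..., 5] = 1.62, 1.52, 1.64
        C = dj.ConductivityTensorField(grid=g, components=comp)
        assert np.allclose(dj.mean_conductivity(C), (1.62 + 1.52 + 1.64) / 3)

    def test_zero_eta_gives_zero_conductivity(self, anis_phantom, rect_grid):
        D, _ = anis_phantom
        # eta must be positive on its validity mask; use the assembly
        # arithmetic directly on a zero field via an empty validity mask
        eta = dj.ScaleParameterField(grid=rect_grid,
                                     eta=np.zeros(rect_grid.shape),
                                     valid=np.zeros(rect_grid.shape, bool))
        C, mean_c = dj.assemble_outputs(eta, D)
        assert np.all(C.components == 0.0)
        assert np.all(mean_c == 0.0)

    def test_conductivity_shares_eigenvectors_with_diffusion(self,
                                                             forward_truth):
        C = forward_truth["C"]
        D = forward_truth["D"]
        vC, _ = dj.eigendecompose(C.as_matrices()[10, 20])
        vD, _ = dj.eigendecompose(D.as_matrices()[10, 20])
        assert np.allclose(np.abs(vC.T @ vD), np.eye(3), atol=1e-8)
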