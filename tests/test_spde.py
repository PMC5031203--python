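import numpy as np
import pytest
from scipy import sparse
from scipy.sparse.linalg import splu
from scipy.special import kv

from voitools.mc import evpi_mc
from voitools.psa import PsaInputError
from voitools.spde import (FemMatrices, MaternParams, Mesh2D, SpdeHyper,
                           build_mesh, default_hyper_bounds, fem_matrices,
                           lgm_fit, matern_covariance, projector,
                           spde_evppi, spde_precision,
                           structured_rectangle_mesh)


def _single_triangle():
    verts = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
    tris = np.array([[0, 1, 2]])
    idx = np.array([0, 1, 2])
    return Mesh2D(verts, tris, idx, idx)


class TestBuildMesh:
    def test_unit_square_corners_inside(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
        mesh = build_mesh(pts)
        tri = mesh.delaunay()
        assert np.all(tri.find_simplex(pts) >= 0)
        # strictly inside the inner ring: positive distance to it
        ring = mesh.vertices[mesh.inner_boundary]
        d = np.min(np.linalg.norm(pts[:, None] - ring[None], axis=2), axis=1)
        assert np.all(d > 0)

    def test_default_vertex_count_rule(self, rng):
        pts = rng.normal(size=(1000, 2))
        mesh = build_mesh(pts)
        assert mesh.V >= 1000

    def test_refinement_monotonicity(self, rng):
        pts = rng.normal(size=(200, 2))
        coarse = build_mesh(pts, max_edge_inner=0.4)
        fine = build_mesh(pts, max_edge_inner=0.2)
        assert fine.V > coarse.V

    def test_collinear_inputs_jittered(self):
        pts = np.column_stack([np.linspace(0, 1, 30), np.zeros(30)])
        mesh = build_mesh(pts)   # jitter resolves exact collinearity
        assert mesh.V >= 30


class TestFem:
    def test_single_triangle_hand_values(self):
        fem = fem_matrices(_single_triangle())
        np.testing.assert_allclose(fem.C.diagonal(), [1 / 6, 1 / 6, 1 / 6],
                                   atol=1e-12)
        expected_G = 0.5 * np.array([[2.0, -1.0, -1.0],
                                     [-1.0, 1.0, 0.0],
                                     [-1.0, 0.0, 1.0]])
        np.testing.assert_allclose(fem.G.toarray(), expected_G, atol=1e-12)

    def test_stiffness_row_sums_zero(self, rng):
        mesh = build_mesh(rng.normal(size=(80, 2)))
        fem = fem_matrices(mesh)
        np.testing.assert_allclose(np.asarray(fem.G.sum(axis=1)).ravel(),
                                   0.0, atol=1e-10)


class TestSpdePrecision:
    def _setup(self):
        mesh = structured_rectangle_mesh(0, 1, 0, 1, 0.08)
        return mesh, fem_matrices(mesh)

    def test_symmetric_positive_definite(self):
        mesh, fem = self._setup()
        Q = spde_precision(SpdeHyper(kappa=5.0, tau=0.1, nugget=0.0), fem)
        assert (abs(Q - Q.T)).max() < 1e-12
        lu = splu(Q.tocsc())
        assert np.all(lu.U.diagonal() != 0)

    def test_tau_scaling_exact(self):
        mesh, fem = self._setup()
        Q1 = spde_precision(SpdeHyper(kappa=5.0, tau=0.1, nugget=0.0), fem)
        Q2 = spde_precision(SpdeHyper(kappa=5.0, tau=0.2, nugget=0.0), fem)
        assert abs(Q2 - 4.0 * Q1).max() < 1e-10

    def test_marginal_variance_identity(self):
        # interior variance must match sigma^2 = 1/(4 pi kappa^2 tau^2)
        mesh = structured_rectangle_mesh(0, 1, 0, 1, 0.03)
        fem = fem_matrices(mesh)
        kappa = 10.0
        tau = 1.0 / np.sqrt(4 * np.pi * kappa ** 2)   # target variance 1
        hyper = SpdeHyper(kappa=kappa, tau=tau, nugget=0.0)
        Q = spde_precision(hyper, fem)
        lu = splu(Q.tocsc())
        v = mesh.vertices
        interior = np.flatnonzero((v[:, 0] > 0.35) & (v[:, 0] < 0.65)
                                  & (v[:, 1] > 0.35) & (v[:, 1] < 0.65))
        sel = interior[::9][:20]
        E = np.zeros((mesh.V, len(sel)))
        E[sel, np.arange(len(sel))] = 1.0
        cols = lu.solve(E)
        var = cols[sel, np.arange(len(sel))]
        target = hyper.marginal_variance()
        assert np.all(np.abs(var - target) / target < 0.10)


class TestProjector:
    def test_vertex_and_centroid_weights(self):
        mesh = _single_triangle()
        A = projector(mesh, [[0.0, 0.0], [1 / 3, 1 / 3]])
        row0 = A[0].toarray().ravel()
        assert row0[0] == pytest.approx(1.0) and row0[1:].max() < 1e-12
        np.testing.assert_allclose(A[1].toarray().ravel(), [1 / 3] * 3,
                                   atol=1e-12)

    def test_rows_sum_to_one(self, rng):
        pts = rng.normal(size=(120, 2))
        mesh = build_mesh(pts)
        A = projector(mesh, pts)
        np.testing.assert_allclose(np.asarray(A.sum(axis=1)).ravel(), 1.0,
                                   atol=1e-12)

    def test_point_outside_mesh(self):
        mesh = _single_triangle()
        with pytest.raises(PsaInputError):
            projector(mesh, [[5.0, 5.0]])


class TestMaternCovariance:
    def test_zero_distance_limit(self):
        p = MaternParams(sigma=2.0, kappa=3.0, nu=1.0)
        assert matern_covariance(0.0, p) == pytest.approx(4.0)

    def test_exponential_special_case(self):
        p = MaternParams(sigma=1.0, kappa=2.0, nu=0.5)
        d = np.array([0.1, 0.5, 1.3])
        np.testing.assert_allclose(matern_covariance(d, p), np.exp(-2.0 * d),
                                   rtol=1e-10)

    def test_nu_one_bessel_value(self):
        p = MaternParams(sigma=1.0, kappa=1.0, nu=1.0)
        assert matern_covariance(1.0, p) == pytest.approx(float(kv(1, 1.0)),
                                                          rel=1e-10)
        assert matern_covariance(1.0, p) == pytest.approx(0.6019, abs=2e-4)


class TestLgmFit:
    def _mesh_setup(self, rng, n=120, spacing=0.15):
        pts = rng.uniform(0.0, 1.0, size=(n, 2))
        mesh = build_mesh(pts, max_edge_inner=spacing)
        fem = fem_matrices(mesh)
        A = projector(mesh, pts)
        H = np.column_stack([np.ones(n), pts])
        return pts, mesh, fem, A, H

    def test_pure_trend_matches_gls(self, rng):
        pts, mesh, fem, A, H = self._mesh_setup(rng)
        beta = np.array([1.0, 2.0, -3.0])
        y = H @ beta + 0.5 * rng.normal(size=len(pts))
        model = lgm_fit(y, A, fem, H, default_hyper_bounds(mesh, y),
                        mesh=mesh)
        ols = H @ np.linalg.lstsq(H, y, rcond=None)[0]
        # no spatial signal: fitted values should essentially be the trend
        assert np.abs(model.fitted - ols).max() < 0.25 * y.std()

    def test_log_marginal_matches_dense_oracle(self, rng):
        from voitools.spde import _BETA_PREC, _lgm_log_marginal
        mesh = structured_rectangle_mesh(0, 1, 0, 1, 0.26)
        fem = fem_matrices(mesh)
        pts = rng.uniform(0.1, 0.9, size=(25, 2))
        A = projector(mesh, pts)
        H = np.column_stack([np.ones(25), pts])
        y = rng.normal(size=25)
        theta = np.log([4.0, 0.05, 0.3])
        ll, _, Q = _lgm_log_marginal(theta, y, A, fem, H, 2)
        cov = (A.toarray() @ np.linalg.solve(Q.toarray(), A.toarray().T)
               + H @ H.T / _BETA_PREC + np.exp(theta[2]) * np.eye(25))
        sign, logdet = np.linalg.slogdet(2 * np.pi * cov)
        dense = -0.5 * (logdet + y @ np.linalg.solve(cov, y))
        assert ll == pytest.approx(dense, abs=1e-6)

    def test_hyperparameter_recovery(self):
        # simulate from the model; the mode of log kappa should be close
        kappa_true, sigma_field, sigma_eps = 6.0, 1.0, 0.2
        tau_true = 1.0 / (sigma_field * kappa_true * np.sqrt(4 * np.pi))
        hits = 0
        reps = 8
        for r in range(reps):
            rng = np.random.default_rng(1000 + r)
            pts = rng.uniform(0.0, 1.0, size=(500, 2))
            mesh = build_mesh(pts, max_edge_inner=0.09)
            fem = fem_matrices(mesh)
            Q = spde_precision(SpdeHyper(kappa=kappa_true, tau=tau_true,
                                         nugget=0.0), fem)
            lu = splu(Q.tocsc())
            # sample omega ~ N(0, Q^-1) via the permuted Cholesky factor
            z = rng.standard_normal(mesh.V)
            omega = _sample_gmrf(Q, z)
            A = projector(mesh, pts)
            y = np.asarray(A @ omega).ravel() + sigma_eps * rng.normal(size=500)
            H = np.ones((500, 1))
            model = lgm_fit(y, A, fem, H, default_hyper_bounds(mesh, y),
                            mesh=mesh)
            if abs(np.log(model.hyper.kappa) - np.log(kappa_true)) < 0.5:
                hits += 1
        assert hits >= int(0.8 * reps)


def _sample_gmrf(Q, z):
    """Draw from N(0, Q^-1) by solving the dense Cholesky system (test
    helper; meshes here are small)."""
    L = np.linalg.cholesky(Q.toarray())
    return np.linalg.solve(L.T, z)


class TestSpdeEvppi:
    def test_noise_only_signal_near_zero(self, rng):
        from voitools.psa import (NetBenefitTable, ParameterDraws, PsaDataset)
        S = 500
        draws = ParameterDraws(["a", "b", "c"], rng.normal(size=(S, 3)))
        inb = rng.normal(size=S)
        nb = NetBenefitTable(np.column_stack([np.zeros(S), inb]), k=0.0)
        est, _ = spde_evppi(PsaDataset(draws, nb), ["a", "b", "c"])
        assert est.value < 4 * np.std(inb) / np.sqrt(S)

    def test_mesh_refinement_cauchy(self, savi_dataset):
        focal = ["x1", "x2"]
        vals = []
        for edge in (0.45, 0.3, 0.2):
            est, _ = spde_evppi(savi_dataset, focal, max_edge_inner=edge)
            vals.append(est.value)
        d1 = abs(vals[1] - vals[0])
        d2 = abs(vals[2] - vals[1])
        assert d2 < max(d1, 0.02 * vals[-1]) + 0.01 * vals[-1]

    def test_single_parameter_focal(self, savi_dataset):
        est, models = spde_evppi(savi_dataset, ["x1"])
        assert est.value >= 0.0
        assert models[0].diagnostics["pfc_d"] is None
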