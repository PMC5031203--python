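import numpy as np
import pytest
from scipy import stats

from voitools.mc import NestedMcPlan, evpi_mc, evppi_nested_mc
from voitools.models import (GaussianLinearModel, GaussianLinearSpec,
                             InfluenzaModel, InfluenzaSpec, PfcTestbedSpec,
                             default_influenza_spec, sample_gaussian_linear,
                             sample_influenza, sample_pfc_testbed,
                             savi_like_spec)


def _degenerate(value):
    # point mass via a zero-width uniform
    return stats.uniform(loc=value, scale=0.0)


class TestInfluenza:
    def test_identical_arms_zero_evpi(self):
        base = default_influenza_spec()
        spec = InfluenzaSpec(pi=base.pi, lam=base.lam, gamma=base.gamma,
                             xi=_degenerate(0.0), rho=_degenerate(1.0))
        ds = sample_influenza(spec, S=500, seed=0)
        np.testing.assert_allclose(ds.nb.values[:, 0], ds.nb.values[:, 1])
        assert evpi_mc(ds.nb).value == pytest.approx(0.0, abs=1e-9)

    def test_zero_infection_risk(self):
        base = default_influenza_spec()
        spec = InfluenzaSpec(pi=_degenerate(0.0), lam=base.lam,
                             gamma=base.gamma, xi=base.xi, rho=base.rho)
        ds = sample_influenza(spec, S=200, seed=1)
        np.testing.assert_allclose(ds.nb.values[:, 0], 0.0)
        xi = ds.draws.values[:, ds.draws.names.index("xi")]
        np.testing.assert_allclose(ds.nb.values[:, 1], -xi)

    def test_seeded_reproducibility(self):
        a = sample_influenza(S=100, seed=7)
        b = sample_influenza(S=100, seed=7)
        np.testing.assert_array_equal(a.draws.values, b.draws.values)
        np.testing.assert_array_equal(a.nb.values, b.nb.values)

    def test_conditional_expectation_full_focal_is_identity(self):
        model = InfluenzaModel()
        ds = sample_influenza(model.spec, S=100, seed=2)
        g = model.conditional_expectation(ds.draws.values, ds.draws.names,
                                          model.spec.k)
        np.testing.assert_allclose(g, ds.nb.values, rtol=1e-12)

    def test_conditional_expectation_empty_focal_prior_means(self):
        model = InfluenzaModel()
        g = model.conditional_expectation(np.zeros((5, 0)), [], model.spec.k)
        assert np.ptp(g[:, 0]) == 0 and np.ptp(g[:, 1]) == 0
        m = model.spec.means()
        expect0 = (model.spec.k * (-m["pi"] * m["lam"])
                   - m["pi"] * m["gamma"] * m["lam"])
        assert g[0, 0] == pytest.approx(expect0)

    def test_conditional_expectation_vs_nested_mc(self):
        # sum-product oracle against brute-force inner Monte Carlo
        model = InfluenzaModel()
        focal = ["pi", "lam", "rho"]
        rng = np.random.default_rng(3)
        phi = model.sample_focal(focal, 5, rng)
        g = model.conditional_expectation(phi, focal, model.spec.k)
        for s in range(5):
            psi = model.sample_nuisance(["gamma", "xi"], phi[s], 200_000,
                                        np.random.default_rng(100 + s))
            draws = {"pi": np.full(200_000, phi[s, 0]),
                     "lam": np.full(200_000, phi[s, 1]),
                     "rho": np.full(200_000, phi[s, 2]),
                     "gamma": psi[:, 0], "xi": psi[:, 1]}
            nb = model.net_benefits(draws, model.spec.k)
            se = nb.std(axis=0) / np.sqrt(200_000)
            assert np.all(np.abs(nb.mean(axis=0) - g[s]) < 3 * se + 1e-9)

    def test_law_of_total_expectation(self):
        model = InfluenzaModel()
        ds = sample_influenza(model.spec, S=50_000, seed=4)
        phi = ds.draws.values[:, [0, 1, 4]]
        g = model.conditional_expectation(phi, ["pi", "lam", "rho"],
                                          model.spec.k)
        se = ds.nb.values.std(axis=0) / np.sqrt(ds.S)
        assert np.all(np.abs(g.mean(axis=0) - ds.nb.values.mean(axis=0))
                      < 4 * se)


class TestGaussianLinear:
    def test_identical_arms_zero_evpi(self):
        spec = GaussianLinearSpec(names=["a", "b"], mean=[0.0, 1.0],
                                  cov=np.eye(2), a=[[1.0, 2.0], [1.0, 2.0]],
                                  b=[3.0, 3.0])
        ds = sample_gaussian_linear(spec, S=300, seed=0)
        assert evpi_mc(ds.nb).value == pytest.approx(0.0, abs=1e-9)

    def test_moments_converge(self):
        spec = savi_like_spec()
        ds = sample_gaussian_linear(spec, S=100_000, seed=1)
        sd = np.sqrt(np.diag(spec.cov))
        se_mean = sd / np.sqrt(ds.S)
        assert np.all(np.abs(ds.draws.values.mean(axis=0) - spec.mean)
                      < 4 * se_mean)
        emp_cov = np.cov(ds.draws.values.T)
        assert np.abs(emp_cov - spec.cov).max() < 0.1

    def test_full_focal_identity(self):
        spec = savi_like_spec()
        model = GaussianLinearModel(spec)
        ds = sample_gaussian_linear(spec, S=100, seed=2)
        g = model.conditional_expectation(ds.draws.values, spec.names)
        np.testing.assert_allclose(g, ds.nb.values, rtol=1e-9)

    def test_independent_blocks_marginal_mean(self):
        cov = np.diag([1.0, 2.0, 3.0])
        spec = GaussianLinearSpec(names=["a", "b", "c"], mean=[1.0, -1.0, 0.5],
                                  cov=cov, a=[[1.0, 1.0, 1.0], [0.0, 2.0, 0.0]],
                                  b=[0.0, 0.0])
        model = GaussianLinearModel(spec)
        g = model.conditional_expectation(np.array([[5.0]]), ["a"])
        # arm 1 depends only on b, independent of a: equals prior mean
        assert g[0, 1] == pytest.approx(2.0 * -1.0)
        assert g[0, 0] == pytest.approx(5.0 + (-1.0) + 0.5)

    def test_conditional_expectation_vs_nested_mc(self):
        rng = np.random.default_rng(5)
        A = rng.normal(size=(5, 5))
        spec = GaussianLinearSpec(
            names=list("abcde"), mean=rng.normal(size=5),
            cov=A @ A.T + np.eye(5), a=rng.normal(size=(2, 5)),
            b=rng.normal(size=2))
        model = GaussianLinearModel(spec)
        focal = ["a", "c"]
        plan = NestedMcPlan(S_phi=3000, S_psi=3000, seed=6)
        nested = evppi_nested_mc(model, focal, plan, k=0.0)
        # same outer draws cannot be replayed; compare against a long run of
        # the exact conditional expectation instead
        from voitools.mc import evppi_single_loop
        oracle = evppi_single_loop(model, focal, S_phi=1_000_000, seed=7,
                                   k=0.0)
        assert nested.value == pytest.approx(oracle.value, rel=0.1)

    def test_bilinear_conditional_expectation_exact(self):
        # quadratic net benefit: conditional second moments must enter
        rng = np.random.default_rng(8)
        cov = np.array([[1.0, 0.6], [0.6, 2.0]])
        B = np.zeros((2, 2, 2))
        B[1] = np.array([[0.0, 0.5], [0.5, 0.3]])
        spec = GaussianLinearSpec(names=["a", "b"], mean=[0.2, -0.1],
                                  cov=cov, a=[[1.0, 0.0], [0.5, 1.0]],
                                  b=[0.0, 0.0], bilinear=B)
        model = GaussianLinearModel(spec)
        phi = np.array([[1.3]])
        g = model.conditional_expectation(phi, ["a"])
        n = 2_000_000
        psi = model.sample_nuisance(["b"], phi[0], n, rng)
        draws = {"a": np.full(n, 1.3), "b": psi[:, 0]}
        nb = model.net_benefits(draws)
        se = nb.std(axis=0) / np.sqrt(n)
        assert np.all(np.abs(nb.mean(axis=0) - g[0]) < 4 * se + 1e-8)


class TestPfcTestbed:
    def test_zero_upsilon_independent_of_response(self):
        spec = PfcTestbedSpec(P=4, d=1, Upsilon=np.zeros((4, 1)) + 1e-12,
                              sigma=1.0)
        Phi, y, _ = sample_pfc_testbed(spec, 2000, seed=0)
        corr = [abs(np.corrcoef(Phi[:, j], y)[0, 1]) for j in range(4)]
        assert max(corr) < 0.08

    def test_noiseless_line(self):
        U = np.array([[3.0], [4.0]]) / 5.0
        spec = PfcTestbedSpec(P=2, d=1, Upsilon=U, h=1, sigma=0.0)
        Phi, y, _ = sample_pfc_testbed(spec, 100, seed=1)
        # points lie exactly on the line through the origin spanned by U
        resid = Phi - np.outer(Phi @ U[:, 0], U[:, 0])
        np.testing.assert_allclose(resid, 0.0, atol=1e-10)

    def test_reproducible(self):
        spec = PfcTestbedSpec(P=3, d=1, Upsilon=np.eye(3)[:, :1])
        a = sample_pfc_testbed(spec, 50, seed=2)
        b = sample_pfc_testbed(spec, 50, seed=2)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])
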