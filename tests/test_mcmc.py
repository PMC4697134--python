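"""Sampler correctness against closed-form and quadrature oracles."""

import numpy as np
import pytest

from nutsurv._polyagamma import pg_draw, pg_mean, seed_pg
from nutsurv.mcmc import PosteriorResult, SamplerConfig, diagnostics, fit, scalar_diagnostics
from nutsurv.model import ModelSpec, build_design
from nutsurv.synthetic import default_config, generate_survey

from conftest import make_bare_design


class TestPolyaGamma:
    @pytest.mark.parametrize("z", [0.0, 0.8, 2.5])
    def test_moments(self, z):
        """Sample mean of PG(1, z) matches tanh(z/2)/(2z) within 5 SE."""
        seed_pg(101)
        zs = np.full(50000, z)
        out = np.empty_like(zs)
        pg_draw(zs, out)
        se = out.std() / np.sqrt(len(out))
        assert abs(out.mean() - pg_mean(z)) < 5 * se

    def test_positive(self):
        seed_pg(7)
        zs = np.linspace(-8, 8, 1000)
        out = np.empty_like(zs)
        pg_draw(zs, out)
        assert (out > 0).all()

    def test_symmetric_in_z(self):
        """PG(1, z) and PG(1, -z) are the same distribution."""
        seed_pg(5)
        out_pos = np.empty(30000)
        pg_draw(np.full(30000, 1.3), out_pos)
        out_neg = np.empty(30000)
        pg_draw(np.full(30000, -1.3), out_neg)
        assert abs(out_pos.mean() - out_neg.mean()) < 5 * out_pos.std() / np.sqrt(30000)


class TestConjugateGaussian:
    def test_matches_closed_form(self):
        """With a Gaussian likelihood the posterior of beta is conjugate:
        N((lam X'X + P0)^-1 lam X'y, (lam X'X + P0)^-1)."""
        rng = np.random.default_rng(21)
        n, lam = 120, 4.0
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        beta_true = np.array([0.5, -1.2])
        y = X @ beta_true + rng.normal(0, 1 / np.sqrt(lam), size=n)
        design = make_bare_design(np.zeros(n), X, ["intercept", "x"])
        design.y = y  # continuous outcome for the Gaussian-likelihood mode
        cfg = SamplerConfig(n_chains=4, n_iter=1500, n_warmup=250, seed=3,
                            likelihood="gaussian", noise_precision=lam)
        res = fit(design, config=cfg)

        P0 = np.eye(2) / design.spec.beta_prior_var
        P = lam * X.T @ X + P0
        mean = np.linalg.solve(P, lam * X.T @ y)
        cov = np.linalg.inv(P)
        draws = res.beta.reshape(-1, 2)
        for j in range(2):
            mcse = draws[:, j].std() / np.sqrt(min(res.n_draws, 2000))
            assert abs(draws[:, j].mean() - mean[j]) < 3 * max(mcse, 1e-4)
            assert draws[:, j].var() == pytest.approx(cov[j, j], rel=0.15)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(22)
        n = 40
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = (rng.random(n) < 0.4).astype(float)
        design = make_bare_design(y, X, ["intercept", "x"])
        cfg = SamplerConfig(n_chains=2, n_iter=300, n_warmup=100, seed=99)
        r1 = fit(design, config=cfg)
        r2 = fit(design, config=cfg)
        np.testing.assert_array_equal(r1.beta, r2.beta)


def quadrature_posterior_mean(y, x, prior_var=100.0):
    """Trapezoid-quadrature oracle for the 1-parameter logistic posterior."""
    grid = np.linspace(-8, 8, 4001)
    eta = np.outer(grid, x)
    ll = (y * eta - np.logaddexp(0.0, eta)).sum(axis=1) - grid**2 / (2 * prior_var)
    w = np.exp(ll - ll.max())
    return float(np.trapezoid(grid * w, grid) / np.trapezoid(w, grid))


class TestLogisticOracle:
    def test_one_parameter_posterior_matches_quadrature(self):
        """Posterior mean of a 1-parameter logistic model on 50 fixed records
        agrees with numerical quadrature within 3 MC standard errors."""
        rng = np.random.default_rng(23)
        n = 50
        x = rng.normal(size=n)
        y = (rng.random(n) < 1 / (1 + np.exp(-0.9 * x))).astype(float)
        design = make_bare_design(y, x[:, None], ["x"])
        res = fit(design, config=SamplerConfig(n_chains=4, n_iter=2000, n_warmup=500, seed=17))
        draws = res.beta[:, :, 0]
        _, ess = scalar_diagnostics(draws)
        mcse = draws.std() / np.sqrt(ess)
        oracle = quadrature_posterior_mean(y, x)
        assert abs(draws.mean() - oracle) < 3 * mcse

    def test_metropolis_fallback_agrees(self):
        """The non-augmented Metropolis path targets the same posterior."""
        rng = np.random.default_rng(24)
        n = 60
        x = rng.normal(size=n)
        y = (rng.random(n) < 1 / (1 + np.exp(-0.5 * x))).astype(float)
        design = make_bare_design(y, x[:, None], ["x"])
        res = fit(design, config=SamplerConfig(
            n_chains=4, n_iter=4000, n_warmup=1500, seed=18, augmentation="metropolis"))
        oracle = quadrature_posterior_mean(y, x)
        draws = res.beta[:, :, 0]
        _, ess = scalar_diagnostics(draws)
        mcse = draws.std() / np.sqrt(max(ess, 10))
        assert abs(draws.mean() - oracle) < 4 * mcse


@pytest.fixture(scope="module")
def survey_fit(small_survey):
    cfg = SamplerConfig(n_chains=2, n_iter=500, n_warmup=250, seed=30)
    return fit(small_survey, ModelSpec(indicator="wasting"), cfg)


class TestHierarchicalFit:
    def test_sum_to_zero_in_every_draw(self, survey_fit):
        """The ICAR field and temporal walk satisfy their constraints in
        every stored draw."""
        design = survey_fit.design
        ind = design.comp_indicator
        u = survey_fit.u  # (chains, draws, n_clusters)
        sums = np.einsum("cdk,mk->cdm", u, ind)
        assert np.abs(sums).max() < 1e-8
        assert np.abs(survey_fit.t.sum(axis=2)).max() < 1e-8

    def test_draw_counts_consistent(self, survey_fit):
        cfg = survey_fit.config
        expected = (cfg.n_iter - cfg.n_warmup) // cfg.thin
        assert survey_fit.beta.shape[:2] == (cfg.n_chains, expected)

    def test_taus_positive(self, survey_fit):
        for arr in survey_fit.tau.values():
            assert (arr > 0).all()

    def test_posterior_contraction_with_more_clusters(self):
        """Doubling the number of clusters shrinks average fixed-effect CrI width."""
        widths = {}
        for n_c in (40, 80):
            cfg = default_config(n_clusters=n_c, households_per_cluster=8,
                                 n_districts=8, seed=61)
            ds = generate_survey(cfg)
            res = fit(ds, ModelSpec(indicator="wasting"),
                      SamplerConfig(n_chains=2, n_iter=500, n_warmup=250, seed=6))
            tab = res.effects()
            widths[n_c] = float(np.mean(np.log(tab["cri_high"]) - np.log(tab["cri_low"])))
        assert widths[80] < widths[40]


class TestDiagnostics:
    def test_iid_chains_rhat_near_one(self):
        rng = np.random.default_rng(40)
        rhat, _ = scalar_diagnostics(rng.standard_normal((4, 2000)))
        assert 0.99 <= rhat <= 1.02

    def test_shifted_chain_flagged(self):
        rng = np.random.default_rng(41)
        draws = rng.standard_normal((4, 1000))
        draws[0] += 10.0
        rhat, _ = scalar_diagnostics(draws)
        assert rhat > 1.5

    def test_ar1_effective_sample_size(self):
        """AR(1) with phi=0.9 has ess/n = (1-phi)/(1+phi) ~ 0.053."""
        rng = np.random.default_rng(42)
        phi, n = 0.9, 10000
        chains = []
        for _ in range(4):
            e = rng.standard_normal(n)
            x = np.empty(n)
            x[0] = e[0] / np.sqrt(1 - phi**2)
            for i in range(1, n):
                x[i] = phi * x[i - 1] + e[i]
            chains.append(x)
        _, ess = scalar_diagnostics(np.array(chains))
        expected = 4 * n * (1 - phi) / (1 + phi)
        assert ess == pytest.approx(expected, rel=0.5)

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            scalar_diagnostics(np.zeros((1, 500)))

    def test_nonconvergence_flagged_not_silent(self, survey_fit):
        """A result with clearly unmixed chains reports converged=False."""
        bad = PosteriorResult(
            beta=np.concatenate(
                [survey_fit.beta[:1], survey_fit.beta[1:] + 5.0], axis=0
            ),
            colnames=survey_fit.colnames,
            u=survey_fit.u, v=survey_fit.v, w=survey_fit.w, t=survey_fit.t,
            f=survey_fit.f, tau=survey_fit.tau,
            config=survey_fit.config, design=survey_fit.design,
        )
        assert not bad.converged
        table = diagnostics(bad)
        assert (table["rhat"] > 1.1).any()

    def test_result_save(self, survey_fit, tmp_path):
        survey_fit.save(tmp_path)
        assert (tmp_path / "draws.csv").exists()
        import json

        manifest = json.loads((tmp_path / "manifest.json").read_text())
        assert manifest["indicator"] == "wasting"
        assert "max_rhat" in manifest


class TestSamplerConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"n_iter": 100, "n_warmup": 100},
        {"thin": 0},
        {"augmentation": "hmc"},
    ])
    def test_invalid(self, kwargs):
        with pytest.raises(ValueError):
            SamplerConfig(**kwargs)
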