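"""Model definition: design compilation, linear predictor, log posterior."""

import numpy as np
import pytest

from nutsurv.model import (
    ModelSpec,
    ParameterState,
    build_design,
    effects_table,
    linear_predictor,
    log_posterior,
    summarize_effect,
)


@pytest.fixture(scope="module")
def design(small_survey):
    return build_design(small_survey, ModelSpec(indicator="wasting"))


def random_state(design, rng, tau=4.0):
    """A valid random ParameterState (constraints imposed)."""
    state = ParameterState.zeros(design, tau=tau)
    state.beta = rng.normal(0, 0.3, size=design.X.shape[1])
    u = rng.normal(0, 0.5, size=design.n_clusters)
    ind = design.comp_indicator
    state.u = u - (ind.T * ((ind @ u) / ind.sum(axis=1))).sum(axis=1)
    state.v = rng.normal(0, 0.5, size=design.n_clusters)
    state.w = rng.normal(0, 0.5, size=design.n_districts)
    t = rng.normal(0, 0.5, size=design.n_rounds)
    state.t = t - t.mean()
    return state


class TestBuildDesign:
    def test_shapes_and_names(self, design, small_survey):
        n = len(small_survey.records)
        assert design.X.shape == (n, 1 + len(design.spec.fixed_covariates))
        assert design.colnames[0] == "intercept"
        assert "evi" in design.colnames and "season_gu" in design.colnames
        assert design.n_clusters == small_survey.n_clusters
        assert design.cluster_codes.max() == design.n_clusters - 1
        assert design.n_rounds == 8

    def test_intercept_column_is_ones(self, design):
        assert np.all(design.X[:, 0] == 1.0)

    def test_outcome_matches_records(self, design, small_survey):
        assert design.y.sum() == small_survey.records["wasted"].sum()

    def test_nonlinear_and_linear_conflict(self):
        with pytest.raises(ValueError):
            ModelSpec(fixed_covariates=("evi",), nonlinear_covariates=({"name": "evi"},))

    def test_unknown_indicator(self):
        with pytest.raises(ValueError):
            ModelSpec(indicator="underweight")


class TestLinearPredictor:
    def test_zero_state_gives_zero(self, design):
        state = ParameterState.zeros(design)
        eta = linear_predictor(state, design)
        assert np.all(eta == 0.0)

    def test_single_evi_coefficient_contrast(self, design):
        """beta_EVI = ln(0.62) implies an eta contrast of about -0.478
        between full and zero vegetation cover."""
        state = ParameterState.zeros(design)
        j = design.colnames.index("evi")
        state.beta[j] = np.log(0.62)
        eta = linear_predictor(state, design)
        evi = design.X[:, j]
        slope = (eta / np.where(evi == 0, np.nan, evi))[evi > 0.5].mean()
        assert slope == pytest.approx(-0.478, abs=1e-3)

    def test_matches_dot_product_oracle(self, design):
        """Record-level eta equals an independently assembled dot product."""
        rng = np.random.default_rng(8)
        state = random_state(design, rng)
        for i in rng.integers(0, design.n, size=12):
            i = int(i)
            oracle = float(np.dot(design.X[i], state.beta))
            oracle += state.u[design.cluster_codes[i]]
            oracle += state.v[design.cluster_codes[i]]
            oracle += state.w[design.district_codes[i]]
            oracle += state.t[design.round_codes[i]]
            assert linear_predictor(state, design, i) == pytest.approx(oracle, abs=1e-12)

    def test_vectorised_matches_per_record(self, design):
        rng = np.random.default_rng(9)
        state = random_state(design, rng)
        eta = linear_predictor(state, design)
        for i in (0, 5, design.n - 1):
            assert eta[i] == pytest.approx(linear_predictor(state, design, i), abs=1e-12)


def brute_force_log_posterior(state, design):
    """Independent term-by-term oracle for the log posterior."""
    spec = design.spec
    total = 0.0
    for i in range(design.n):
        eta = float(np.dot(design.X[i], state.beta))
        eta += state.u[design.cluster_codes[i]] + state.v[design.cluster_codes[i]]
        eta += state.w[design.district_codes[i]] + state.t[design.round_codes[i]]
        total += design.y[i] * eta - np.log1p(np.exp(eta))
    total += -0.5 / spec.beta_prior_var * sum(b * b for b in state.beta)
    a, r = spec.hyper_shape, spec.hyper_rate
    idx = {v: i for i, v in enumerate(design.graph.nodes)}
    edge_sum = sum(
        (state.u[idx[p]] - state.u[idx[q]]) ** 2 for p, q in design.graph.edges
    )
    rank_u = design.n_clusters - design.graph.n_components
    tau = state.tau["spatial"]
    total += 0.5 * rank_u * np.log(tau) - 0.5 * tau * edge_sum + (a - 1) * np.log(tau) - r * tau
    tau = state.tau["cluster"]
    total += (0.5 * design.n_clusters * np.log(tau) - 0.5 * tau * sum(x * x for x in state.v)
              + (a - 1) * np.log(tau) - r * tau)
    tau = state.tau["district"]
    total += (0.5 * design.n_districts * np.log(tau) - 0.5 * tau * sum(x * x for x in state.w)
              + (a - 1) * np.log(tau) - r * tau)
    tau = state.tau["temporal"]
    rw_sum = sum((state.t[k + 1] - state.t[k]) ** 2 for k in range(design.n_rounds - 1))
    total += (0.5 * (design.n_rounds - 1) * np.log(tau) - 0.5 * tau * rw_sum
              + (a - 1) * np.log(tau) - r * tau)
    return total


class TestLogPosterior:
    def test_matches_brute_force_oracle(self, small_survey):
        # ~10 records spanning several clusters (adjacency needs >= 2 sites)
        from nutsurv.summaries import _bare_dataset

        keep = set(small_survey.clusters["cluster_id"].iloc[:4])
        cfg_small = (
            small_survey.records[small_survey.records["cluster_id"].isin(keep)]
            .groupby("cluster_id", group_keys=False)
            .head(3)
            .head(10)
        )
        clusters = small_survey.clusters[small_survey.clusters["cluster_id"].isin(keep)]
        ds = _bare_dataset(cfg_small.reset_index(drop=True), clusters.reset_index(drop=True),
                           small_survey)
        design = build_design(ds, ModelSpec(indicator="wasting"))
        rng = np.random.default_rng(10)
        state = random_state(design, rng)
        state.tau.update({"spatial": 3.0, "cluster": 1.5, "district": 0.7, "temporal": 2.2})
        assert log_posterior(state, design) == pytest.approx(
            brute_force_log_posterior(state, design), abs=1e-10
        )

    def test_single_record_likelihood_contribution(self, design):
        """y=1 at eta=0 contributes ln(1/2)."""
        state = ParameterState.zeros(design)
        base = log_posterior(state, design)
        expected = design.y @ np.zeros(design.n) - design.n * np.log(2.0)
        # all-zero state: likelihood is n * ln(1/2); priors at tau=1 contribute 2(a-1)... = 0 - rate terms
        prior = -4 * design.spec.hyper_rate  # four gamma densities at tau=1, shape 1
        assert base == pytest.approx(expected + prior, abs=1e-10)

    def test_outcome_flip_decomposition(self, design):
        """Flipping record i's outcome changes the value by the difference
        of that record's two Bernoulli terms only."""
        rng = np.random.default_rng(11)
        state = random_state(design, rng)
        lp = log_posterior(state, design)
        i = 17
        eta_i = linear_predictor(state, design, i)
        flipped = design.y.copy()
        flipped[i] = 1 - flipped[i]
        design_flipped = type(design)(**{**design.__dict__, "y": flipped})
        lp2 = log_posterior(state, design_flipped)
        delta = (flipped[i] - design.y[i]) * eta_i
        assert lp2 - lp == pytest.approx(delta, abs=1e-8)

    def test_icar_term_translation_invariant(self, design):
        """Adding a constant per component leaves the pairwise-difference
        penalty unchanged (before the constraint is imposed)."""
        rng = np.random.default_rng(12)
        u = rng.normal(size=design.n_clusters)
        shift = design.comp_indicator.T @ rng.normal(size=design.graph.n_components)
        q1 = u @ (design.Q @ u)
        u2 = u + shift
        q2 = u2 @ (design.Q @ u2)
        assert q1 == pytest.approx(q2, rel=1e-12)

    def test_rw2_penalty_zero_for_linear_effect(self, small_survey):
        """Second differences of a linear-in-bin-index effect vanish."""
        spec = ModelSpec(
            indicator="wasting",
            fixed_covariates=tuple(c for c in ModelSpec().fixed_covariates if c != "evi"),
            nonlinear_covariates=({"name": "evi", "n_bins": 10, "rw2": True},),
        )
        design = build_design(small_survey, spec)
        R = design.nl_R["evi"].toarray()
        f = np.arange(10) - 4.5  # linear, sum-to-zero
        assert f @ R @ f == pytest.approx(0.0, abs=1e-12)

    def test_nonfinite_state_rejected(self, design):
        state = ParameterState.zeros(design)
        state.beta[0] = np.inf
        with pytest.raises(ValueError):
            log_posterior(state, design)


class TestEffectSummaries:
    def test_degenerate_draws(self):
        est = summarize_effect(np.zeros(500), name="null")
        assert est.or_point == pytest.approx(1.0)
        assert est.percent_change == pytest.approx(0.0)

    def test_paper_style_reduction(self):
        """Draws fixed at ln(0.62) summarise to a 38% reduction."""
        est = summarize_effect(np.full(500, np.log(0.62)))
        assert est.or_point == pytest.approx(0.62)
        assert est.percent_change == pytest.approx(-38.0)

    def test_lognormal_quantiles(self):
        """Standard-normal draws give a CrI near [e^-1.96, e^1.96]."""
        rng = np.random.default_rng(13)
        est = summarize_effect(rng.standard_normal(10000))
        assert est.cri_low == pytest.approx(np.exp(-1.96), rel=0.05)
        assert est.cri_high == pytest.approx(np.exp(1.96), rel=0.05)
        assert est.cri_low < est.or_point < est.cri_high

    def test_empty_draws_rejected(self):
        with pytest.raises(ValueError):
            summarize_effect([])

    def test_effects_table_excludes_intercept(self):
        draws = np.random.default_rng(14).normal(size=(200, 3))
        tab = effects_table(draws, ["intercept", "evi", "fever"])
        assert list(tab["covariate"]) == ["evi", "fever"]
        assert (tab["or"] > 0).all()
        assert (tab["cri_low"] < tab["cri_high"]).all()


def test_model_spec_json_round_trip(tmp_path):
    spec = ModelSpec(indicator="stunting", fixed_covariates=("female", "evi"))
    spec.to_json(tmp_path / "spec.json")
    spec2 = ModelSpec.from_json(tmp_path / "spec.json")
    assert spec2 == spec
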