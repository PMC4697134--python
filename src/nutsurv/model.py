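"""Hierarchical spatial-temporal Bernoulli regression model.

For child ``i`` in cluster ``c(i)``, district ``d(i)`` and survey round
``r(i)``, the malnutrition indicator ``y_i`` is Bernoulli with

    logit P(y_i = 1) = eta_i
    eta_i = beta' x_i + u_{c(i)} + v_{c(i)} + w_{d(i)} + t_{r(i)} + sum_j f_j(x_ij)

where ``x_i`` collects the fixed effects (including the intercept and the
two-level season factor, Gu vs the Deyr reference), ``u`` is the spatially
structured intrinsic-CAR field and ``v`` the unstructured exchangeable
effect of the convolution (BYM) prior on clusters, ``w`` are exchangeable
district effects, ``t`` is a first-order random walk over survey rounds and
the optional ``f_j`` are nonlinear effects modelled as second-order random
walks over covariate bins (off by default; per-unit odds ratios assume
linear fixed effects).

Priors: fixed effects are independent N(0, 100); every random-effect
precision has a diffuse gamma(1, 0.0005) hyperprior.  ``u`` is constrained
to sum to zero within each graph component, ``t`` and each ``f_j`` to sum
to zero overall.

:func:`log_posterior` is the density (up to a constant) that the MCMC
engine targets; it retains the tau-dependent normalising terms
``(rank/2) log tau`` needed for precision inference.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .spatial import build_adjacency, icar_precision

__all__ = [
    "ModelSpec",
    "ModelData",
    "ParameterState",
    "EffectEstimate",
    "build_design",
    "linear_predictor",
    "log_posterior",
    "summarize_effect",
    "effects_table",
    "OUTCOME_COLUMNS",
    "DEFAULT_FIXED_COVARIATES",
]

OUTCOME_COLUMNS = {"wasting": "wasted", "stunting": "stunted", "low_muac": "low_muac"}

#: Table-2-style covariate set: child morbidity/vaccination, age bands
#: (reference 6-11 months), sex (reference male), household composition,
#: food access, maternal MUAC, environmental surfaces, season (reference
#: Deyr).
DEFAULT_FIXED_COVARIATES = (
    "female",
    "age_12_23",
    "age_24_59",
    "fever",
    "diarrhoea",
    "ari",
    "measles",
    "polio",
    "vita",
    "access_protein",
    "access_carb",
    "access_fruitveg",
    "household_size",
    "n_under5",
    "head_female",
    "mother_muac_mm",
    "evi",
    "rainfall",
    "temperature",
    "season_gu",
)

DEFAULT_RANDOM_TERMS = ("spatial_icar", "cluster_iid", "district_iid", "temporal_rw1")

#: canonical covariate -> source column in the merged records/clusters table
_SOURCE_COLUMNS = {
    "fever": "fever_2wk",
    "diarrhoea": "diarrhoea_2wk",
    "ari": "ari_2wk",
    "measles": "measles_vax",
    "polio": "polio_vax",
    "vita": "vitA_6mo",
    "access_protein": "access_protein",
    "access_carb": "access_carb",
    "access_fruitveg": "access_fruitveg",
    "household_size": "household_size",
    "n_under5": "n_under5",
    "mother_muac_mm": "mother_muac_mm",
    "evi": "evi",
    "rainfall": "rainfall",
    "temperature": "temperature",
}


@dataclass
class ModelSpec:
    """Definition of one indicator's regression model."""

    indicator: str = "wasting"
    fixed_covariates: tuple = DEFAULT_FIXED_COVARIATES
    nonlinear_covariates: tuple = ()  # e.g. ({"name": "evi", "n_bins": 10, "rw2": True},)
    random_terms: tuple = DEFAULT_RANDOM_TERMS
    hyper_shape: float = 1.0
    hyper_rate: float = 5e-4
    beta_prior_var: float = 100.0
    adjacency_method: str = "knn"
    adjacency_k: int = 5

    def __post_init__(self):
        if self.indicator not in OUTCOME_COLUMNS:
            raise ValueError(f"unknown indicator {self.indicator!r}")
        nl_names = {d["name"] for d in self.nonlinear_covariates}
        overlap = nl_names & set(self.fixed_covariates)
        if overlap:
            raise ValueError(f"covariates both linear and nonlinear: {sorted(overlap)}")
        unknown = set(self.random_terms) - set(DEFAULT_RANDOM_TERMS)
        if unknown:
            raise ValueError(f"unknown random terms: {sorted(unknown)}")

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, default=list))

    @classmethod
    def from_json(cls, path) -> "ModelSpec":
        d = json.loads(Path(path).read_text())
        for key in ("fixed_covariates", "random_terms"):
            if key in d:
                d[key] = tuple(d[key])
        if "nonlinear_covariates" in d:
            d["nonlinear_covariates"] = tuple(d["nonlinear_covariates"])
        return cls(**d)


def _derive_columns(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    out["female"] = (out["sex"] == "female").astype(float)
    if "head_sex" in out.columns:
        out["head_female"] = (out["head_sex"] == "female").astype(float)
    band = pd.cut(out["age_months"], bins=[5, 11, 23, 59], labels=["6-11", "12-23", "24-59"])
    out["age_12_23"] = (band == "12-23").astype(float)
    out["age_24_59"] = (band == "24-59").astype(float)
    if "season" in out.columns:
        out["season_gu"] = (out["season"] == "Gu").astype(float)
    return out


def _rw_structure(n: int, order: int) -> sp.csr_matrix:
    """Structure matrix D'D of a random walk of the given order."""
    D = np.eye(n)
    for _ in range(order):
        D = np.diff(D, axis=0)
    return sp.csr_matrix(D.T @ D)


@dataclass
class ModelData:
    """Dataset compiled against a :class:`ModelSpec` (design matrices, index maps)."""

    spec: ModelSpec
    y: np.ndarray
    X: np.ndarray
    colnames: list
    cluster_ids: list
    cluster_codes: np.ndarray
    district_ids: list
    district_codes: np.ndarray
    round_values: list
    round_codes: np.ndarray
    graph: object = None
    Q: sp.csr_matrix = None
    comp_indicator: np.ndarray = None
    R_rw1: sp.csr_matrix = None
    nl_codes: dict = field(default_factory=dict)
    nl_sizes: dict = field(default_factory=dict)
    nl_R: dict = field(default_factory=dict)
    n_dropped_missing: int = 0
    n_dropped_unlocated: int = 0

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_ids)

    @property
    def n_districts(self) -> int:
        return len(self.district_ids)

    @property
    def n_rounds(self) -> int:
        return len(self.round_values)


def build_design(dataset, spec: ModelSpec) -> ModelData:
    """Compile a survey dataset into the matrices the model needs.

    Complete-case: records with missing values in any used column are
    dropped (counted, never silent), as are records in clusters without
    valid coordinates when the spatial term is active.
    """
    df = dataset.records.merge(
        dataset.clusters, on="cluster_id", how="left", validate="many_to_one"
    )
    df = _derive_columns(df)
    ycol = OUTCOME_COLUMNS[spec.indicator]

    used_cols = [ycol, "cluster_id", "district_id", "round"]
    for cov in spec.fixed_covariates:
        used_cols.append(_SOURCE_COLUMNS.get(cov, cov))
    for nl in spec.nonlinear_covariates:
        used_cols.append(_SOURCE_COLUMNS.get(nl["name"], nl["name"]))
    used_cols = list(dict.fromkeys(used_cols))

    n0 = len(df)
    located = df["lon"].notna() & df["lat"].notna()
    use_spatial = "spatial_icar" in spec.random_terms
    if use_spatial:
        df = df[located]
    n_unloc = n0 - len(df)
    df = df.dropna(subset=[c for c in used_cols if c in df.columns])
    n_missing = n0 - n_unloc - len(df)
    if len(df) == 0:
        raise ValueError("no records left after exclusions")

    y = df[ycol].to_numpy(dtype=float)
    cols = [np.ones(len(df))]
    names = ["intercept"]
    for cov in spec.fixed_covariates:
        src = _SOURCE_COLUMNS.get(cov, cov)
        cols.append(df[src].to_numpy(dtype=float))
        names.append(cov)
    X = np.column_stack(cols)

    cluster_codes, cluster_ids = pd.factorize(df["cluster_id"])
    district_codes, district_ids = pd.factorize(df["district_id"])
    round_codes, round_values = pd.factorize(df["round"], sort=True)

    graph = Q = comp_ind = None
    if use_spatial:
        sites = (
            dataset.clusters.set_index("cluster_id")
            .loc[list(cluster_ids)]
            .reset_index()
            .rename(columns={"cluster_id": "id"})
        )
        graph = build_adjacency(sites, method=spec.adjacency_method, k=spec.adjacency_k)
        Q = icar_precision(graph).Q
        comp_ind = graph.component_indicator()

    nl_codes, nl_sizes, nl_R = {}, {}, {}
    for nl in spec.nonlinear_covariates:
        name = nl["name"]
        n_bins = int(nl.get("n_bins", 10))
        vals = df[_SOURCE_COLUMNS.get(name, name)].to_numpy(dtype=float)
        edges = np.linspace(vals.min(), vals.max(), n_bins + 1)
        codes = np.clip(np.searchsorted(edges, vals, side="right") - 1, 0, n_bins - 1)
        nl_codes[name] = codes
        nl_sizes[name] = n_bins
        nl_R[name] = _rw_structure(n_bins, 2 if nl.get("rw2", True) else 1)

    return ModelData(
        spec=spec,
        y=y,
        X=X,
        colnames=names,
        cluster_ids=list(cluster_ids),
        cluster_codes=cluster_codes.astype(int),
        district_ids=list(district_ids),
        district_codes=district_codes.astype(int),
        round_values=list(round_values),
        round_codes=round_codes.astype(int),
        graph=graph,
        Q=Q,
        comp_indicator=comp_ind,
        R_rw1=_rw_structure(len(round_values), 1),
        nl_codes=nl_codes,
        nl_sizes=nl_sizes,
        nl_R=nl_R,
        n_dropped_missing=n_missing,
        n_dropped_unlocated=n_unloc,
    )


@dataclass
class ParameterState:
    """One point in parameter space (fixed effects, random fields, precisions)."""

    beta: np.ndarray
    u: np.ndarray
    v: np.ndarray
    w: np.ndarray
    t: np.ndarray
    f: dict = field(default_factory=dict)
    tau: dict = field(default_factory=dict)

    @classmethod
    def zeros(cls, design: ModelData, tau: float = 1.0) -> "ParameterState":
        taus = {"spatial": tau, "cluster": tau, "district": tau, "temporal": tau}
        f = {name: np.zeros(nb) for name, nb in design.nl_sizes.items()}
        taus.update({f"nl_{name}": tau for name in design.nl_sizes})
        return cls(
            beta=np.zeros(design.X.shape[1]),
            u=np.zeros(design.n_clusters),
            v=np.zeros(design.n_clusters),
            w=np.zeros(design.n_districts),
            t=np.zeros(design.n_rounds),
            f=f,
            tau=taus,
        )

    def validate(self, design: ModelData, atol: float = 1e-8) -> None:
        if design.comp_indicator is not None and len(self.u):
            sums = design.comp_indicator @ self.u
            if np.any(np.abs(sums) > atol):
                raise ValueError("u must sum to zero within each graph component")
        for name, fv in self.f.items():
            if abs(fv.sum()) > atol:
                raise ValueError(f"nonlinear effect {name} must sum to zero")
        if any(not tv > 0 for tv in self.tau.values()):
            raise ValueError("all precisions must be positive")


def linear_predictor(state: ParameterState, design: ModelData, i=None) -> np.ndarray:
    """Linear predictor eta for record ``i`` (or all records when ``i`` is None)."""
    if i is not None:
        eta = float(design.X[i] @ state.beta)
        eta += state.u[design.cluster_codes[i]] if len(state.u) else 0.0
        eta += state.v[design.cluster_codes[i]]
        eta += state.w[design.district_codes[i]]
        eta += state.t[design.round_codes[i]]
        for name, codes in design.nl_codes.items():
            eta += state.f[name][codes[i]]
        return eta
    eta = design.X @ state.beta
    terms = design.spec.random_terms
    if "spatial_icar" in terms and len(state.u):
        eta = eta + state.u[design.cluster_codes]
    if "cluster_iid" in terms:
        eta = eta + state.v[design.cluster_codes]
    if "district_iid" in terms:
        eta = eta + state.w[design.district_codes]
    if "temporal_rw1" in terms:
        eta = eta + state.t[design.round_codes]
    for name, codes in design.nl_codes.items():
        eta = eta + state.f[name][codes]
    return eta


def _gamma_logpdf(tau, shape, rate):
    return (shape - 1.0) * np.log(tau) - rate * tau


def log_posterior(state: ParameterState, design: ModelData) -> float:
    """Unnormalised log posterior density of the model at ``state``.

    Bernoulli log-likelihood + Gaussian/ICAR/random-walk priors (with their
    tau-dependent ``(rank/2) log tau`` terms) + gamma hyperprior densities.
    Constant terms not involving any parameter are dropped.
    """
    if not np.all(np.isfinite(state.beta)):
        raise ValueError("non-finite state")
    spec = design.spec
    eta = linear_predictor(state, design)
    if not np.all(np.isfinite(eta)):
        raise ValueError("non-finite linear predictor")
    lp = float(design.y @ eta - np.logaddexp(0.0, eta).sum())

    lp += -0.5 / spec.beta_prior_var * float(state.beta @ state.beta)

    a, b = spec.hyper_shape, spec.hyper_rate
    terms = spec.random_terms
    if "spatial_icar" in terms and design.Q is not None:
        tau = state.tau["spatial"]
        rank = design.n_clusters - design.graph.n_components
        lp += 0.5 * rank * np.log(tau) - 0.5 * tau * float(state.u @ (design.Q @ state.u))
        lp += _gamma_logpdf(tau, a, b)
    if "cluster_iid" in terms:
        tau = state.tau["cluster"]
        lp += 0.5 * design.n_clusters * np.log(tau) - 0.5 * tau * float(state.v @ state.v)
        lp += _gamma_logpdf(tau, a, b)
    if "district_iid" in terms:
        tau = state.tau["district"]
        lp += 0.5 * design.n_districts * np.log(tau) - 0.5 * tau * float(state.w @ state.w)
        lp += _gamma_logpdf(tau, a, b)
    if "temporal_rw1" in terms:
        tau = state.tau["temporal"]
        rank = max(design.n_rounds - 1, 0)
        lp += 0.5 * rank * np.log(tau) - 0.5 * tau * float(state.t @ (design.R_rw1 @ state.t))
        lp += _gamma_logpdf(tau, a, b)
    for name, R in design.nl_R.items():
        tau = state.tau[f"nl_{name}"]
        f = state.f[name]
        order = 2  # RW2 by default
        rank = max(design.nl_sizes[name] - order, 0)
        lp += 0.5 * rank * np.log(tau) - 0.5 * tau * float(f @ (R @ f))
        lp += _gamma_logpdf(tau, a, b)
    if not np.isfinite(lp):
        raise ValueError("log posterior is not finite at this state")
    return lp


@dataclass(frozen=True)
class EffectEstimate:
    """Posterior odds-ratio summary for one covariate."""

    name: str
    or_point: float
    cri_low: float
    cri_high: float
    percent_change: float


def summarize_effect(samples, name: str = "", level: float = 0.95) -> EffectEstimate:
    """OR and credible-interval summary of posterior draws of one log-odds beta.

    ``or_point`` is the posterior mean of ``exp(beta)``; the CrI bounds are
    the corresponding quantiles of ``exp(beta)``; ``percent_change`` is
    ``100 * (or_point - 1)``.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise ValueError("no posterior draws supplied")
    ors = np.exp(samples)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(ors, [alpha, 1.0 - alpha])
    point = float(ors.mean())
    return EffectEstimate(
        name=name,
        or_point=point,
        cri_low=float(lo),
        cri_high=float(hi),
        percent_change=100.0 * (point - 1.0),
    )


def effects_table(beta_draws: np.ndarray, colnames, level: float = 0.95) -> pd.DataFrame:
    """Table-2-style OR/CrI summary for every fixed effect (intercept excluded)."""
    rows = []
    for j, name in enumerate(colnames):
        if name == "intercept":
            continue
        est = summarize_effect(beta_draws[:, j], name=name, level=level)
        rows.append(
            {
                "covariate": est.name,
                "or": est.or_point,
                "cri_low": est.cri_low,
                "cri_high": est.cri_high,
                "percent_change": est.percent_change,
            }
        )
    return pd.DataFrame(rows)
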