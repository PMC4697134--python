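"""Posterior inference for the spatial-temporal Bernoulli model.

The default engine is a Polya-Gamma Gibbs sampler: conditional on latent
``omega_i ~ PG(1, eta_i)`` the logistic likelihood is Gaussian in the
linear predictor, so all location parameters (fixed effects, the BYM
cluster fields, district and temporal effects) are updated *jointly* from
one multivariate Gaussian full conditional, and every precision is updated
from its conjugate gamma full conditional.  Sum-to-zero constraints (the
ICAR field per graph component, the temporal random walk, nonlinear-effect
vectors) are imposed exactly by conditioning-by-kriging on the joint
Gaussian draw.

Internally the fixed-effect columns are standardised (centred and scaled)
for numerical conditioning; draws are mapped back to the raw-covariate
scale exactly, including the matching linear transform of the N(0, 100)
prior, so the sampler targets precisely the density of
:func:`nutsurv.model.log_posterior`.

An adaptive random-walk Metropolis fallback (``augmentation="metropolis"``)
updates the same blocks without augmentation; adaptation is frozen after
warmup.  A Gaussian-likelihood mode exists so the Gaussian-block machinery
can be validated against conjugate closed forms.

Convergence diagnostics (split-chain rhat, effective sample size) are
delegated to :mod:`arviz`.
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.sparse as sp

from ._polyagamma import pg_draw, seed_pg
from .model import ModelData, ModelSpec, build_design, effects_table

__all__ = ["SamplerConfig", "PosteriorResult", "fit", "diagnostics", "scalar_diagnostics"]


@dataclass
class SamplerConfig:
    """MCMC run settings.

    The default run (4 chains x 2000 iterations, 1000 warmup) is sized so
    a full synthetic-survey fit completes in minutes on one CPU.
    """

    n_chains: int = 4
    n_iter: int = 2000
    n_warmup: int = 1000
    thin: int = 1
    seed: int = 0
    augmentation: str = "latent-variable"  # or "metropolis"
    likelihood: str = "bernoulli"  # "gaussian" for conjugate validation runs
    noise_precision: float = 1.0  # Gaussian-likelihood mode only
    initial_scale: float = 0.1  # Metropolis proposal scale before adaptation
    rhat_threshold: float = 1.1

    def __post_init__(self):
        if not (self.n_iter > self.n_warmup >= 0):
            raise ValueError("need n_iter > n_warmup >= 0")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.augmentation not in ("latent-variable", "metropolis"):
            raise ValueError(f"unknown augmentation {self.augmentation!r}")


@dataclass
class PosteriorResult:
    """Posterior draws plus diagnostics for one fitted model."""

    beta: np.ndarray  # (chains, draws, p), raw covariate scale
    colnames: list
    u: np.ndarray
    v: np.ndarray
    w: np.ndarray
    t: np.ndarray
    f: dict
    tau: dict  # name -> (chains, draws)
    config: SamplerConfig
    design: ModelData
    acceptance: dict = field(default_factory=dict)
    runtime_s: float = 0.0
    log: list = field(default_factory=list)
    _diag: pd.DataFrame = None

    @property
    def n_draws(self) -> int:
        return self.beta.shape[0] * self.beta.shape[1]

    def beta_draws(self, name: str) -> np.ndarray:
        """Pooled draws of one fixed-effect coefficient (log-odds scale)."""
        j = self.colnames.index(name)
        return self.beta[:, :, j].reshape(-1)

    @property
    def diagnostics_table(self) -> pd.DataFrame:
        if self._diag is None:
            self._diag = diagnostics(self)
        return self._diag

    @property
    def converged(self) -> bool:
        """False when any monitored rhat exceeds the configured threshold."""
        return bool((self.diagnostics_table["rhat"] <= self.config.rhat_threshold).all())

    def effects(self, level: float = 0.95) -> pd.DataFrame:
        flat = self.beta.reshape(-1, self.beta.shape[2])
        return effects_table(flat, self.colnames, level=level)

    def save(self, out_dir) -> None:
        """Persist draws as CSV (one scalar per column) plus a JSON manifest."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        flat = {f"beta[{n}]": self.beta[:, :, j].reshape(-1) for j, n in enumerate(self.colnames)}
        for name, arr in self.tau.items():
            flat[f"tau[{name}]"] = arr.reshape(-1)
        pd.DataFrame(flat).to_csv(out / "draws.csv", index=False)
        diag = self.diagnostics_table
        manifest = {
            "seed": self.config.seed,
            "n_chains": self.config.n_chains,
            "n_iter": self.config.n_iter,
            "n_warmup": self.config.n_warmup,
            "thin": self.config.thin,
            "augmentation": self.config.augmentation,
            "indicator": self.design.spec.indicator,
            "runtime_s": self.runtime_s,
            "converged": self.converged,
            "max_rhat": float(diag["rhat"].max()),
            "min_ess": float(diag["ess"].min()),
            "acceptance": self.acceptance,
            "log": self.log,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


# ---------------------------------------------------------------------------
# internal machinery


class _Blocks:
    """Index bookkeeping for the joint Gaussian location update."""

    def __init__(self, design: ModelData):
        spec = design.spec
        p = design.X.shape[1]
        self.p = p
        self.terms = []
        offset = p
        self.slices = {"beta": slice(0, p)}
        n = design.n

        def add(name, dim):
            nonlocal offset
            self.slices[name] = slice(offset, offset + dim)
            self.terms.append(name)
            offset += dim

        if "spatial_icar" in spec.random_terms:
            add("u", design.n_clusters)
        if "cluster_iid" in spec.random_terms:
            add("v", design.n_clusters)
        if "district_iid" in spec.random_terms:
            add("w", design.n_districts)
        if "temporal_rw1" in spec.random_terms:
            add("t", design.n_rounds)
        for name, nb in design.nl_sizes.items():
            add(f"f_{name}", nb)
        self.dim = offset

        # sparse indicator loadings for all non-beta blocks, in block order
        mats = []
        for name in self.terms:
            if name in ("u", "v"):
                codes, m = design.cluster_codes, design.n_clusters
            elif name == "w":
                codes, m = design.district_codes, design.n_districts
            elif name == "t":
                codes, m = design.round_codes, design.n_rounds
            else:
                nl = name[2:]
                codes, m = design.nl_codes[nl], design.nl_sizes[nl]
            mats.append(
                sp.csr_matrix(
                    (np.ones(n), (np.arange(n), codes)), shape=(n, m)
                )
            )
        self.L_ind = sp.hstack(mats, format="csr") if mats else None

        # sum-to-zero constraint rows (u per component, t, each f)
        rows = []
        if "u" in self.slices:
            ci = design.comp_indicator
            for k in range(ci.shape[0]):
                row = np.zeros(self.dim)
                row[self.slices["u"]] = ci[k]
                rows.append(row)
        if "t" in self.slices and design.n_rounds > 1:
            row = np.zeros(self.dim)
            row[self.slices["t"]] = 1.0
            rows.append(row)
        for name in design.nl_sizes:
            row = np.zeros(self.dim)
            row[self.slices[f"f_{name}"]] = 1.0
            rows.append(row)
        self.A = np.vstack(rows) if rows else None
        # A'A regularises the exact null directions of the joint precision
        # (constant shifts of improper-prior blocks that the likelihood
        # cannot see); adding a multiple of it changes nothing on the
        # constraint subspace the draw is conditioned onto.
        self.AtA = self.A.T @ self.A if self.A is not None else None


def _standardise(X):
    """Centre/scale non-intercept columns; return (Xs, J) with theta_raw = J theta_s."""
    p = X.shape[1]
    m = X.mean(axis=0)
    s = X.std(axis=0)
    m[0] = 0.0
    s[s == 0] = 1.0
    s[0] = 1.0
    Xs = (X - m) / s
    J = np.diag(1.0 / s)
    J[0, 0] = 1.0
    J[0, 1:] = -m[1:] / s[1:]
    return Xs, J


def _prior_blocks(design: ModelData, blocks: _Blocks, taus: dict, P_beta: np.ndarray):
    """Dense prior precision contribution for the joint location update."""
    P0 = np.zeros((blocks.dim, blocks.dim))
    P0[: blocks.p, : blocks.p] = P_beta
    for name in blocks.terms:
        slc = blocks.slices[name]
        if name == "u":
            P0[slc, slc] += taus["spatial"] * design.Q.toarray()
        elif name == "v":
            P0[slc, slc] += taus["cluster"] * np.eye(design.n_clusters)
        elif name == "w":
            P0[slc, slc] += taus["district"] * np.eye(design.n_districts)
        elif name == "t":
            P0[slc, slc] += taus["temporal"] * design.R_rw1.toarray()
        else:
            nl = name[2:]
            P0[slc, slc] += taus[f"nl_{nl}"] * design.nl_R[nl].toarray()
    return P0


def _joint_gaussian_draw(rng, P, b, A, AtA=None):
    """Draw from N(P^-1 b, P^-1), then condition exactly on A theta = 0.

    The conditional law on the constraint subspace depends only on P
    restricted to that subspace, so the ``AtA`` ridge (which acts purely on
    the constrained directions) does not alter the target.
    """
    if AtA is not None:
        P = P + (np.trace(P) / len(P)) * AtA
    c, low = sla.cho_factor(P, lower=True, check_finite=False)
    mean = sla.cho_solve((c, low), b, check_finite=False)
    z = rng.standard_normal(len(b))
    theta = mean + sla.solve_triangular(c, z, lower=True, trans=1, check_finite=False)
    if A is not None and len(A):
        V = sla.cho_solve((c, low), A.T, check_finite=False)
        S = A @ V
        theta = theta - V @ np.linalg.solve(S, A @ theta)
    return theta


def _tau_updates(rng, design: ModelData, blocks: _Blocks, theta, spec: ModelSpec, taus):
    a, b0 = spec.hyper_shape, spec.hyper_rate
    out = dict(taus)
    if "u" in blocks.slices:
        u = theta[blocks.slices["u"]]
        rank = design.n_clusters - design.graph.n_components
        out["spatial"] = rng.gamma(a + 0.5 * rank, 1.0 / (b0 + 0.5 * float(u @ (design.Q @ u))))
    if "v" in blocks.slices:
        v = theta[blocks.slices["v"]]
        out["cluster"] = rng.gamma(a + 0.5 * design.n_clusters, 1.0 / (b0 + 0.5 * float(v @ v)))
    if "w" in blocks.slices:
        w = theta[blocks.slices["w"]]
        out["district"] = rng.gamma(a + 0.5 * design.n_districts, 1.0 / (b0 + 0.5 * float(w @ w)))
    if "t" in blocks.slices:
        t = theta[blocks.slices["t"]]
        rank = max(design.n_rounds - 1, 0)
        out["temporal"] = rng.gamma(
            a + 0.5 * rank, 1.0 / (b0 + 0.5 * float(t @ (design.R_rw1 @ t)))
        )
    for name in design.nl_sizes:
        fv = theta[blocks.slices[f"f_{name}"]]
        rank = max(design.nl_sizes[name] - 2, 0)
        out[f"nl_{name}"] = rng.gamma(
            a + 0.5 * rank, 1.0 / (b0 + 0.5 * float(fv @ (design.nl_R[name] @ fv)))
        )
    return out


_BLOCK_TAU = {"u": "spatial", "v": "cluster", "w": "district", "t": "temporal"}


def _block_codes(design: ModelData, name: str):
    if name in ("u", "v"):
        return design.cluster_codes
    if name == "w":
        return design.district_codes
    if name == "t":
        return design.round_codes
    return design.nl_codes[name[2:]]


def _scale_moves(rng, design, blocks, theta, taus, eta, scales, adapt):
    """Joint (x, tau) -> (c x, tau / c^2) Metropolis move per random block.

    The centred Gibbs sweep exchanges amplitude between a random field and
    its precision very slowly when the field is weak; this move proposes
    the exchange directly.  The ICAR/random-walk quadratic form is
    invariant under the move, and because each block's prior rank equals
    its effective (constrained) dimension the Jacobian and prior terms
    reduce to  -2a log c - b tau (c^-2 - 1)  plus the likelihood change.
    """
    y = design.y
    a, b0 = design.spec.hyper_shape, design.spec.hyper_rate
    for name in blocks.terms:
        slc = blocks.slices[name]
        x = theta[slc]
        tau_name = _BLOCK_TAU.get(name, f"nl_{name[2:]}")
        tau = taus[tau_name]
        eps = rng.normal(0.0, scales[name])
        c = np.exp(eps)
        contrib = x[_block_codes(design, name)]
        delta = (c - 1.0) * contrib
        eta_new = eta + delta
        dll = float(y @ delta - (np.logaddexp(0.0, eta_new) - np.logaddexp(0.0, eta)).sum())
        log_acc = dll - 2.0 * a * eps - b0 * tau * (c**-2 - 1.0)
        accepted = np.log(rng.random()) < log_acc
        if accepted:
            theta[slc] = c * x
            taus[tau_name] = tau / c**2
            eta = eta_new
        if adapt:
            scales[name] = float(
                np.clip(scales[name] * np.exp(0.05 * ((1.0 if accepted else 0.0) - 0.44)), 1e-3, 5.0)
            )
    return eta


def _eta_from_theta(Xs, blocks: _Blocks, theta):
    eta = Xs @ theta[: blocks.p]
    if blocks.L_ind is not None:
        eta = eta + blocks.L_ind @ theta[blocks.p :]
    return eta


def _run_chain_gibbs(design, config, chain_seed, pg_seed, Xs, J, P_beta, blocks):
    rng = np.random.default_rng(chain_seed)
    seed_pg(pg_seed)
    n = design.n
    y = design.y
    spec = design.spec
    gaussian = config.likelihood == "gaussian"

    theta = np.zeros(blocks.dim)
    taus = {k: 1.0 for k in ("spatial", "cluster", "district", "temporal")}
    taus.update({f"nl_{name}": 1.0 for name in design.nl_sizes})
    omega = np.empty(n)
    kappa = y - 0.5
    scale_scales = {name: 0.5 for name in blocks.terms}

    n_keep = (config.n_iter - config.n_warmup) // config.thin
    out_theta = np.empty((n_keep, blocks.dim))
    out_tau = {k: np.empty(n_keep) for k in taus}
    kept = 0

    for it in range(config.n_iter):
        eta = _eta_from_theta(Xs, blocks, theta)
        if gaussian:
            omega[:] = config.noise_precision
            bvec_w = config.noise_precision * y
        else:
            pg_draw(eta, omega)
            bvec_w = kappa

        # likelihood precision: [Xs | L_ind]' diag(omega) [Xs | L_ind]
        P = np.zeros((blocks.dim, blocks.dim))
        Xw = Xs * omega[:, None]
        P[: blocks.p, : blocks.p] = Xw.T @ Xs
        b = np.empty(blocks.dim)
        b[: blocks.p] = Xs.T @ bvec_w
        if blocks.L_ind is not None:
            cross = (blocks.L_ind.T @ Xw).T  # (p, d_ind)
            P[: blocks.p, blocks.p :] = cross
            P[blocks.p :, : blocks.p] = cross.T
            Lw = blocks.L_ind.multiply(omega[:, None]).tocsr()
            P[blocks.p :, blocks.p :] = (blocks.L_ind.T @ Lw).toarray()
            b[blocks.p :] = blocks.L_ind.T @ bvec_w

        P += _prior_blocks(design, blocks, taus, P_beta)
        theta = _joint_gaussian_draw(rng, P, b, blocks.A, blocks.AtA)
        taus = _tau_updates(rng, design, blocks, theta, spec, taus)
        if not gaussian and blocks.terms:
            eta = _eta_from_theta(Xs, blocks, theta)
            _scale_moves(rng, design, blocks, theta, taus, eta,
                         scale_scales, adapt=it < config.n_warmup)

        if it >= config.n_warmup and (it - config.n_warmup) % config.thin == 0:
            out_theta[kept] = theta
            for k in taus:
                out_tau[k][kept] = taus[k]
            kept += 1

    return out_theta, out_tau, {"rate": 1.0}


def _log_target(design, blocks, Xs, J, P_beta, theta, taus):
    """Log posterior in the standardised parameterisation (for Metropolis)."""
    spec = design.spec
    eta = _eta_from_theta(Xs, blocks, theta)
    lp = float(design.y @ eta - np.logaddexp(0.0, eta).sum())
    bvec = theta[: blocks.p]
    lp += -0.5 * float(bvec @ (P_beta @ bvec))
    a, b0 = spec.hyper_shape, spec.hyper_rate
    for name in blocks.terms:
        x = theta[blocks.slices[name]]
        if name == "u":
            tau, rank, qf = taus["spatial"], design.n_clusters - design.graph.n_components, float(
                x @ (design.Q @ x)
            )
        elif name == "v":
            tau, rank, qf = taus["cluster"], design.n_clusters, float(x @ x)
        elif name == "w":
            tau, rank, qf = taus["district"], design.n_districts, float(x @ x)
        elif name == "t":
            tau, rank, qf = taus["temporal"], max(design.n_rounds - 1, 0), float(
                x @ (design.R_rw1 @ x)
            )
        else:
            nl = name[2:]
            tau, rank, qf = (
                taus[f"nl_{nl}"],
                max(design.nl_sizes[nl] - 2, 0),
                float(x @ (design.nl_R[nl] @ x)),
            )
        lp += 0.5 * rank * np.log(tau) - 0.5 * tau * qf
        lp += (a - 1.0) * np.log(tau) - b0 * tau
    return lp


def _run_chain_metropolis(design, config, chain_seed, pg_seed, Xs, J, P_beta, blocks):
    rng = np.random.default_rng(chain_seed)
    theta = np.zeros(blocks.dim)
    taus = {k: 1.0 for k in ("spatial", "cluster", "district", "temporal")}
    taus.update({f"nl_{name}": 1.0 for name in design.nl_sizes})

    block_items = [("beta", blocks.slices["beta"])] + [
        (name, blocks.slices[name]) for name in blocks.terms
    ]
    log_scales = {name: np.log(config.initial_scale) for name, _ in block_items}
    acc = {name: 0 for name, _ in block_items}
    tries = {name: 0 for name, _ in block_items}

    def project(name, vec):
        # keep proposals on the constraint subspace
        if name == "u" and design.comp_indicator is not None:
            ci = design.comp_indicator
            return vec - (ci.T * ((ci @ vec) / ci.sum(axis=1))).sum(axis=1)
        if name == "t" or name.startswith("f_"):
            return vec - vec.mean()
        return vec

    lp = _log_target(design, blocks, Xs, J, P_beta, theta, taus)
    n_keep = (config.n_iter - config.n_warmup) // config.thin
    out_theta = np.empty((n_keep, blocks.dim))
    out_tau = {k: np.empty(n_keep) for k in taus}
    kept = 0
    target_rate = 0.234

    for it in range(config.n_iter):
        for name, slc in block_items:
            prop = theta.copy()
            step = rng.standard_normal(slc.stop - slc.start) * np.exp(log_scales[name])
            prop[slc] = prop[slc] + project(name, step)
            try:
                lp_prop = _log_target(design, blocks, Xs, J, P_beta, prop, taus)
            except (ValueError, FloatingPointError):
                lp_prop = -np.inf
            tries[name] += 1
            if np.log(rng.random()) < lp_prop - lp:
                theta, lp = prop, lp_prop
                acc[name] += 1
            if it < config.n_warmup and tries[name] % 50 == 0:
                rate = acc[name] / tries[name]
                log_scales[name] += 0.5 * (rate - target_rate)
        taus = _tau_updates(rng, design, blocks, theta, design.spec, taus)
        lp = _log_target(design, blocks, Xs, J, P_beta, theta, taus)
        if it >= config.n_warmup and (it - config.n_warmup) % config.thin == 0:
            out_theta[kept] = theta
            for k in taus:
                out_tau[k][kept] = taus[k]
            kept += 1

    rates = {name: (acc[name] / max(tries[name], 1)) for name, _ in block_items}
    return out_theta, out_tau, rates


def fit(dataset, spec: ModelSpec = None, config: SamplerConfig = None) -> PosteriorResult:
    """Sample the posterior of the spatial-temporal model.

    ``dataset`` may be a :class:`~nutsurv.synthetic.SurveyDataset` (compiled
    with :func:`~nutsurv.model.build_design`) or an already-built
    :class:`~nutsurv.model.ModelData`.
    """
    t0 = time.perf_counter()
    config = config or SamplerConfig()
    if isinstance(dataset, ModelData):
        design = dataset
    else:
        if spec is None:
            spec = ModelSpec()
        design = build_design(dataset, spec)

    Xs, J = _standardise(design.X)
    P_beta = (J.T @ J) / design.spec.beta_prior_var
    blocks = _Blocks(design)

    runner = _run_chain_gibbs if config.augmentation == "latent-variable" else _run_chain_metropolis
    ss = np.random.SeedSequence(config.seed)
    child = ss.spawn(config.n_chains)
    thetas, taus_all, rates = [], [], []
    for c in range(config.n_chains):
        chain_seed = child[c]
        pg_seed = int(chain_seed.generate_state(1, dtype=np.uint32)[0] % (2**31 - 1)) + 1
        th, ta, rate = runner(design, config, chain_seed, pg_seed, Xs, J, P_beta, blocks)
        thetas.append(th)
        taus_all.append(ta)
        rates.append(rate)

    theta = np.stack(thetas)  # (chains, draws, dim)
    n_chains, n_keep, _ = theta.shape
    beta_raw = theta[:, :, : blocks.p] @ J.T

    def block_draws(name):
        if name in blocks.slices and name != "beta":
            return theta[:, :, blocks.slices[name]]
        return np.zeros((n_chains, n_keep, 0))

    f_draws = {name: theta[:, :, blocks.slices[f"f_{name}"]] for name in design.nl_sizes}
    tau_names = list(taus_all[0].keys())
    tau = {k: np.stack([ta[k] for ta in taus_all]) for k in tau_names}
    active = {"u": "spatial", "v": "cluster", "w": "district", "t": "temporal"}
    tau = {
        k: v
        for k, v in tau.items()
        if k.startswith("nl_") or any(blk in blocks.slices and k == nm for blk, nm in active.items())
    }

    result = PosteriorResult(
        beta=beta_raw,
        colnames=list(design.colnames),
        u=block_draws("u"),
        v=block_draws("v"),
        w=block_draws("w"),
        t=block_draws("t"),
        f=f_draws,
        tau=tau,
        config=config,
        design=design,
        acceptance={f"chain_{i}": r for i, r in enumerate(rates)},
        runtime_s=time.perf_counter() - t0,
    )
    if n_chains >= 2 and n_keep >= 100:
        if not result.converged:
            bad = result.diagnostics_table.query("rhat > @config.rhat_threshold")
            msg = f"non-convergence: rhat > {config.rhat_threshold} for {list(bad['param'])[:5]}"
            result.log.append(msg)
            warnings.warn(msg)
    return result


def scalar_diagnostics(draws: np.ndarray):
    """(rhat, ess) for one scalar parameter's (chains, draws) array."""
    import arviz as az

    draws = np.asarray(draws, dtype=float)
    if draws.ndim != 2 or draws.shape[0] < 2:
        raise ValueError("rhat needs at least 2 chains of draws")
    if draws.shape[1] < 2:
        raise ValueError("need at least 2 draws per chain")
    data = az.convert_to_dataset(draws[:, :, None], group="posterior")
    rhat = float(az.rhat(data)["x"].values.ravel()[0])
    ess = float(az.ess(data)["x"].values.ravel()[0])
    return rhat, ess


def diagnostics(result: PosteriorResult) -> pd.DataFrame:
    """Split-chain rhat and effective sample size for every reported scalar."""
    if result.beta.shape[0] < 2:
        raise ValueError("rhat requires at least 2 chains")
    rows = []
    for j, name in enumerate(result.colnames):
        rhat, ess = scalar_diagnostics(result.beta[:, :, j])
        rows.append({"param": f"beta[{name}]", "rhat": rhat, "ess": ess})
    for name, arr in result.tau.items():
        rhat, ess = scalar_diagnostics(np.log(arr))
        rows.append({"param": f"log_tau[{name}]", "rhat": rhat, "ess": ess})
    return pd.DataFrame(rows)
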