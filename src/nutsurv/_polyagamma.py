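"""Polya-Gamma PG(1, z) random variates (numba-compiled).

Logistic likelihoods admit a latent-variable representation: with
``omega ~ PG(1, eta)``, the Bernoulli logit likelihood becomes Gaussian in
the linear predictor, which is what makes the Gibbs sampler in
:mod:`nutsurv.mcmc` fully conjugate.

The sampler is the alternating-series rejection method of Devroye for the
Jacobi-type distribution J*(1, z/2), with PG(1, z) = J*(1, z/2) / 4.  The
proposal mixes a truncated inverse-Gaussian on (0, t] and a truncated
exponential on (t, inf) with the standard changeover t = 0.64; acceptance
is decided by partial sums of the series expansion of the density, so the
draw is exact (no truncation error).

Useful moments for testing:  E[PG(1, z)] = tanh(z/2) / (2 z)  and
Var[PG(1, 0)] = 1/16 - ... (see the moment helper below).
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = ["pg_draw", "seed_pg", "pg_mean"]

_T = 0.64  # changeover point of the two-piece proposal
_HALF_PI2 = math.pi * math.pi / 8.0


@njit(cache=True)
def _norm_cdf(x):
    return 0.5 * (1.0 + math.erf(x / math.sqrt(2.0)))


@njit(cache=True)
def _a_coef(n, x):
    """n-th coefficient of the alternating series for the J*(1,0) density."""
    nph = n + 0.5
    if x > _T:
        return math.pi * nph * math.exp(-nph * nph * math.pi * math.pi * x / 2.0)
    return math.pi * nph * math.pow(2.0 / (math.pi * x), 1.5) * math.exp(-2.0 * nph * nph / x)


@njit(cache=True)
def _mass_texpon(z):
    """Probability that the proposal draws from the exponential piece."""
    fz = _HALF_PI2 + z * z / 2.0
    b = math.sqrt(1.0 / _T) * (_T * z - 1.0)
    a = -math.sqrt(1.0 / _T) * (_T * z + 1.0)
    x0 = math.log(fz) + fz * _T
    xb = x0 - z + math.log(_norm_cdf(b))
    xa = x0 + z + math.log(_norm_cdf(a))
    qdivp = 4.0 / math.pi * (math.exp(xb) + math.exp(xa))
    return 1.0 / (1.0 + qdivp)


@njit(cache=True)
def _rtigauss(z):
    """Inverse-Gaussian(mu=1/z, lambda=1) truncated to (0, t]."""
    mu = 1.0 / z if z > 0 else 1e18
    x = _T + 1.0
    if mu > _T:
        # rejection via truncated chi-square proposal
        alpha = 0.0
        while np.random.random() > alpha:
            e1 = np.random.exponential(1.0)
            e2 = np.random.exponential(1.0)
            while e1 * e1 > 2.0 * e2 / _T:
                e1 = np.random.exponential(1.0)
                e2 = np.random.exponential(1.0)
            x = _T / ((1.0 + _T * e1) * (1.0 + _T * e1))
            alpha = math.exp(-0.5 * z * z * x)
    else:
        while x > _T:
            y = np.random.standard_normal()
            y = y * y
            half = mu / 2.0
            x = mu + half * mu * y - half * math.sqrt(4.0 * mu * y + (mu * y) * (mu * y))
            if np.random.random() > mu / (mu + x):
                x = mu * mu / x
    return x


@njit(cache=True)
def _pg1(z):
    """One exact draw from PG(1, z)."""
    z = abs(z) * 0.5
    fz = _HALF_PI2 + z * z / 2.0
    while True:
        if np.random.random() < _mass_texpon(z):
            x = _T + np.random.exponential(1.0) / fz
        else:
            x = _rtigauss(z)
        s = _a_coef(0, x)
        y = np.random.random() * s
        n = 0
        accept = False
        while True:
            n += 1
            if n % 2 == 1:
                s -= _a_coef(n, x)
                if y <= s:
                    accept = True
                    break
            else:
                s += _a_coef(n, x)
                if y > s:
                    break
        if accept:
            return 0.25 * x


@njit(cache=True)
def pg_draw(z, out):
    """Fill ``out`` with PG(1, z_i) draws (uses numba's global RNG stream)."""
    for i in range(z.shape[0]):
        out[i] = _pg1(z[i])


@njit(cache=True)
def seed_pg(seed):
    """Seed the numba RNG stream used by :func:`pg_draw`."""
    np.random.seed(seed)


def pg_mean(z):
    """E[PG(1, z)] = tanh(z/2)/(2z), with the z->0 limit 1/4."""
    z = np.asarray(z, dtype=float)
    out = np.where(np.abs(z) < 1e-8, 0.25, np.tanh(z / 2.0) / np.where(z == 0, 1.0, 2.0 * z))
    return out if out.ndim else float(out)
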