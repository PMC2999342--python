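"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's own closed-form paths: posterior
moments by 2-D quadrature, logistic fits by grid search, mixture
evidence by dense grid integration, PR curves by explicit confusion
matrices.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln, log_expit, logsumexp


def nig_quad_moments(
    e,
    mu0: float,
    k0: float,
    a0: float,
    b0: float,
    n_v: int = 3000,
    n_mu: int = 601,
    v_lo: float = 1e-6,
    v_hi: float = 1e8,
) -> tuple[float, float]:
    """Posterior E[mu], E[sigma^2] of Normal data under a NIG prior.

    Brute-force 2-D quadrature: log-spaced grid over sigma^2 with, for
    each variance, a mean grid adapted to the conditional spread
    sqrt(sigma^2 / (kappa0 + n)) — a fixed mean grid misses the mass at
    large variances where mu|sigma^2 spreads arbitrarily wide.
    """
    e = np.asarray(e, dtype=float)
    n = e.size
    v = np.exp(np.linspace(np.log(v_lo), np.log(v_hi), n_v))
    dlv = np.log(v[1]) - np.log(v[0])
    kn = k0 + n
    center = (k0 * mu0 + e.sum()) / kn
    log_mass = np.empty(n_v)
    emu_v = np.empty(n_v)
    for i, vi in enumerate(v):
        sd = np.sqrt(vi / kn)
        mu = np.linspace(center - 12 * sd, center + 12 * sd, n_mu)
        dmu = mu[1] - mu[0]
        lp = (
            0.5 * np.log(k0 / (2 * np.pi * vi))
            - k0 * (mu - mu0) ** 2 / (2 * vi)
            + a0 * np.log(b0)
            - gammaln(a0)
            - (a0 + 1) * np.log(vi)
            - b0 / vi
        )
        lp = lp + np.sum(
            -0.5 * np.log(2 * np.pi * vi) - (e[:, None] - mu[None, :]) ** 2 / (2 * vi),
            axis=0,
        )
        m = lp.max()
        weights = np.exp(lp - m)
        log_mass[i] = m + np.log(weights.sum() * dmu)
        emu_v[i] = (weights @ mu) / weights.sum()
    lw = log_mass + np.log(v) + np.log(dlv)
    w = np.exp(lw - logsumexp(lw))
    return float(w @ emu_v), float(w @ v)


def logistic_grid_fit(
    s, t, regularization: float = 1e-6, rounds: int = 14
) -> tuple[float, float]:
    """Coarse-to-fine grid search minimizing the penalized cross-entropy."""
    s = np.asarray(s, dtype=float)
    t = np.asarray(t, dtype=float)
    y = 2.0 * t - 1.0

    def nll(a0: float, a1: float) -> float:
        z = a0 + a1 * s
        return float(-np.sum(log_expit(y * z)) + 0.5 * regularization * (a0**2 + a1**2))

    c0 = c1 = 0.0
    h = 8.0
    for _ in range(rounds):
        g0 = np.linspace(c0 - h, c0 + h, 21)
        g1 = np.linspace(c1 - h, c1 + h, 21)
        vals = np.array([[nll(x, y1) for y1 in g1] for x in g0])
        i, j = np.unravel_index(vals.argmin(), vals.shape)
        c0, c1 = float(g0[i]), float(g1[j])
        h /= 5.0
    return c0, c1


def mixture_log_evidence(
    e,
    prior_pos: tuple[float, float, float, float],
    prior_neg: tuple[float, float, float, float],
    dirichlet: tuple[float, float],
    n_mu: int = 35,
    n_v: int = 35,
    n_pi: int = 41,
    mu_rng: tuple[float, float] = (-4.0, 4.0),
    v_rng: tuple[float, float] = (0.02, 20.0),
) -> float:
    """log p(e) of the 2-component mixture by dense 5-D grid quadrature."""
    e = np.asarray(e, dtype=float)

    def nig_logpdf(mu, v, p):
        m0, k0, a0, b0 = p
        return (
            0.5 * np.log(k0 / (2 * np.pi * v))
            - k0 * (mu - m0) ** 2 / (2 * v)
            + a0 * np.log(b0)
            - gammaln(a0)
            - (a0 + 1) * np.log(v)
            - b0 / v
        )

    mu = np.linspace(*mu_rng, n_mu)
    v = np.exp(np.linspace(np.log(v_rng[0]), np.log(v_rng[1]), n_v))
    dmu = mu[1] - mu[0]
    dlv = np.log(v[1]) - np.log(v[0])
    MU, V = np.meshgrid(mu, v, indexing="ij")
    mu_f, v_f = MU.ravel(), V.ravel()  # n_mu*n_v component-parameter combos
    # per-gene Normal densities for every (mu, v) combo
    dens = np.exp(
        -0.5 * np.log(2 * np.pi * v_f)[None, :]
        - (e[:, None] - mu_f[None, :]) ** 2 / (2 * v_f)[None, :]
    )
    lw_pos = nig_logpdf(mu_f, v_f, prior_pos) + np.log(v_f) + np.log(dmu * dlv)
    lw_neg = nig_logpdf(mu_f, v_f, prior_neg) + np.log(v_f) + np.log(dmu * dlv)
    g1, g2 = dirichlet
    pi = np.linspace(0.5 / n_pi, 1 - 0.5 / n_pi, n_pi)
    lw_pi = (
        gammaln(g1 + g2) - gammaln(g1) - gammaln(g2)
        + (g1 - 1) * np.log(pi) + (g2 - 1) * np.log(1 - pi)
        + np.log(1.0 / n_pi)
    )
    n_c = mu_f.size
    chunks = []
    for jp in range(n_c):  # loop over positive-component combos to bound memory
        mix = pi[None, None, :] * dens[:, jp, None, None] + (1 - pi)[None, None, :] * dens[:, :, None]
        with np.errstate(divide="ignore"):  # log(0) -> -inf is a valid weight
            loglik = np.log(mix).sum(axis=0)  # (n_c_neg, n_pi)
        chunks.append(lw_pos[jp] + lw_neg[:, None] + lw_pi[None, :] + loglik)
    return float(logsumexp(np.stack(chunks)))


def pr_points_bruteforce(ranked_ids, truth):
    """Precision/recall at every cut via explicit confusion matrices."""
    precisions, recalls = [], []
    for k in range(1, len(ranked_ids) + 1):
        predicted = set(ranked_ids[:k])
        tp = len(predicted & truth)
        fp = len(predicted - truth)
        fn = len(truth - predicted)
        precisions.append(tp / (tp + fp))
        recalls.append(tp / (tp + fn))
    return np.array(recalls), np.array(precisions)
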