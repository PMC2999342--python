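"""Prior construction for the two-component fold-change mixture.

The mixture places a Normal-Inverse-Gamma (NIG) prior on each
component's (mean, variance) and a Dirichlet prior on the weights.
NIG(mu, kappa, alpha, beta) means

    mu | sigma^2 ~ Normal(mu, sigma^2 / kappa)
    sigma^2      ~ Inverse-Gamma(alpha, beta)

The positive (target) component receives an *informative* prior: the
conjugate posterior of a noninformative NIG after observing the fold
changes of experimentally verified targets. The negative component keeps
the noninformative NIG. The Dirichlet prior (200, 20000) encodes the
common belief that a miRNA regulates on the order of 200 of ~20000
genes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .io_formats import VerifiedExpressionSet

__all__ = [
    "NIGParams",
    "DirichletParams",
    "PriorBundle",
    "NONINFORMATIVE_NIG",
    "DEFAULT_WEIGHTS",
    "nig_posterior_update",
    "default_prior_bundle",
]


@dataclass(frozen=True)
class NIGParams:
    """Normal-Inverse-Gamma hyperparameters for one mixture component."""

    mu: float
    kappa: float
    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not (self.kappa > 0 and self.alpha > 0 and self.beta > 0):
            raise ValueError("kappa, alpha, beta must all be positive")

    @property
    def mean_of_mu(self) -> float:
        """Posterior/prior mean of the component mean."""
        return self.mu

    @property
    def mean_of_var(self) -> float:
        """Mean of sigma^2 when alpha > 1, else the mode (degenerate fits)."""
        if self.alpha > 1:
            return self.beta / (self.alpha - 1)
        return self.beta / (self.alpha + 1)


@dataclass(frozen=True)
class DirichletParams:
    """Dirichlet concentration over (positive, negative) mixture weights."""

    gamma_pos: float
    gamma_neg: float

    def __post_init__(self) -> None:
        if not (self.gamma_pos > 0 and self.gamma_neg > 0):
            raise ValueError("Dirichlet concentrations must be positive")

    @property
    def mean_pos(self) -> float:
        return self.gamma_pos / (self.gamma_pos + self.gamma_neg)


@dataclass(frozen=True)
class PriorBundle:
    """Priors for the full mixture: two NIG components plus weights."""

    positive: NIGParams
    negative: NIGParams
    weights: DirichletParams

    def save(self, path: str | Path) -> None:
        d = {
            "positive": vars(self.positive),
            "negative": vars(self.negative),
            "weights": vars(self.weights),
        }
        Path(path).write_text(json.dumps(d, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "PriorBundle":
        d = json.loads(Path(path).read_text())
        return cls(
            NIGParams(**d["positive"]),
            NIGParams(**d["negative"]),
            DirichletParams(**d["weights"]),
        )


NONINFORMATIVE_NIG = NIGParams(mu=0.0, kappa=0.2, alpha=0.2, beta=0.2)
DEFAULT_WEIGHTS = DirichletParams(gamma_pos=200.0, gamma_neg=20000.0)


def nig_posterior_update(prior: NIGParams, data: VerifiedExpressionSet) -> NIGParams:
    """Standard conjugate NIG update with a Gaussian likelihood.

    With N observations of sample mean ``m`` and scatter ``S = sum (e-m)^2``:

        mu'    = (kappa*mu + N*m) / (kappa + N)
        kappa' = kappa + N
        alpha' = alpha + N/2
        beta'  = beta + S/2 + kappa*N*(m - mu)^2 / (2*(kappa + N))
    """
    e = np.asarray(data.values, dtype=float)
    if e.size == 0:
        raise ValueError("cannot update a prior with empty data")
    n = e.size
    m = e.mean()
    scatter = float(np.sum((e - m) ** 2))
    kappa_n = prior.kappa + n
    return NIGParams(
        mu=(prior.kappa * prior.mu + n * m) / kappa_n,
        kappa=kappa_n,
        alpha=prior.alpha + n / 2.0,
        beta=prior.beta
        + 0.5 * scatter
        + prior.kappa * n * (m - prior.mu) ** 2 / (2.0 * kappa_n),
    )


def default_prior_bundle(verified: VerifiedExpressionSet | None = None) -> PriorBundle:
    """Build the default prior bundle.

    When ``verified`` fold changes are supplied the positive prior is the
    conjugate update of the noninformative NIG with them; otherwise it
    stays noninformative. The negative prior is always noninformative,
    and the weights default to Dirichlet(200, 20000).
    """
    if verified is not None and len(verified) > 0:
        positive = nig_posterior_update(NONINFORMATIVE_NIG, verified)
    else:
        positive = replace(NONINFORMATIVE_NIG)
    return PriorBundle(
        positive=positive,
        negative=replace(NONINFORMATIVE_NIG),
        weights=DEFAULT_WEIGHTS,
    )
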