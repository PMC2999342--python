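"""Evidence fusion: alpha(e) from the fitted mixture, Naive Bayes product, ranking.

alpha(e) is the posterior probability that a gene is a target given its
fold change, computed from the fitted mixture point estimates:

    alpha(e) = pi_pos N(e; mu_pos, var_pos) /
               (pi_pos N(e; mu_pos, var_pos) + pi_neg N(e; mu_neg, var_neg))

Because the positive component has the heavier tail, the raw curve ramps
back up for strongly up-regulated genes, which contradicts the biology;
alpha is therefore clamped to its value at a threshold (default 0.5 on
the log scale) for all larger fold changes, keeping it continuous.

The combined score is the Naive Bayes product alpha(e) * beta(s); the
posterior's normalization constant is dropped since it does not affect
ranking or thresholding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .calibration import LogisticParams, beta_prob
from .vbem import ThetaHat

__all__ = ["AlphaFunction", "PredictionRecord", "alpha_prob", "combine", "rank_predictions", "build_predictions"]


@dataclass
class AlphaFunction:
    """alpha(e) with the constant-clamp extension above `clamp_threshold`."""

    theta: ThetaHat
    clamp_threshold: float = 0.5
    clamp_value: float = field(init=False)

    def __post_init__(self) -> None:
        self.clamp_value = float(self._raw(np.asarray(self.clamp_threshold)))

    def _raw(self, e: np.ndarray) -> np.ndarray:
        th = self.theta
        num = th.pi_pos * norm.pdf(e, th.mu_pos, np.sqrt(th.var_pos))
        den = num + th.pi_neg * norm.pdf(e, th.mu_neg, np.sqrt(th.var_neg))
        with np.errstate(invalid="ignore"):
            out = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
        return out

    def __call__(self, e):
        e = np.asarray(e, dtype=float)
        scalar = e.ndim == 0
        e = np.atleast_1d(e)
        out = np.where(e > self.clamp_threshold, self.clamp_value, self._raw(e))
        return float(out[0]) if scalar else out


def alpha_prob(e, f: AlphaFunction):
    """Evaluate alpha(e); scalar in, scalar out."""
    return f(e)


def combine(beta, alpha):
    """Naive Bayes fusion: the product alpha * beta (unnormalized posterior)."""
    return np.asarray(alpha, dtype=float) * np.asarray(beta, dtype=float)


@dataclass
class PredictionRecord:
    """One gene's evidence, fused score, and rank."""

    gene_id: str
    s: float
    beta: float
    e: float
    alpha: float
    combined: float
    rank: int = 0


def rank_predictions(records: list[PredictionRecord]) -> list[PredictionRecord]:
    """Sort descending by combined score and assign ranks 1..n.

    Ties break toward the more down-regulated gene (smaller e), then
    lexicographic gene_id, so the ordering is fully deterministic.
    """
    ordered = sorted(records, key=lambda r: (-r.combined, r.e, r.gene_id))
    for i, r in enumerate(ordered, start=1):
        r.rank = i
    return ordered


def build_predictions(
    aligned: list[tuple[str, float, float]],
    logistic: LogisticParams,
    alpha_fn: AlphaFunction,
) -> list[PredictionRecord]:
    """Score and rank aligned (gene_id, e, s) triples."""
    genes = [g for g, _, _ in aligned]
    e = np.array([ei for _, ei, _ in aligned])
    s = np.array([si for _, _, si in aligned])
    betas = beta_prob(s, logistic)
    alphas = alpha_fn(e)
    combined = combine(betas, alphas)
    records = [
        PredictionRecord(g, float(si), float(b), float(ei), float(a), float(c))
        for g, si, b, ei, a, c in zip(genes, s, betas, e, alphas, combined)
    ]
    return rank_predictions(records)
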