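"""Logistic calibration of sequence scores to target probabilities.

A sequence-based predictor emits a real-valued score s per gene; the
calibration maps it to beta(s) = p(t=1 | s) = 1 / (1 + exp(-(a0 + a1*s))).
Parameters are fitted by minimizing the (optionally ridge-penalized)
binary cross-entropy. The ridge acts on both intercept and slope, which
also regularizes away perfect separation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, log_expit

from .errors import FitError
from .io_formats import LabeledScoreSet

__all__ = ["LogisticParams", "fit_logistic", "beta_prob"]


@dataclass
class LogisticParams:
    """Intercept and slope of the score-to-probability logistic map."""

    a0: float
    a1: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.a0) and np.isfinite(self.a1)):
            raise ValueError("logistic parameters must be finite")

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({"a0": self.a0, "a1": self.a1}, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "LogisticParams":
        d = json.loads(Path(path).read_text())
        return cls(float(d["a0"]), float(d["a1"]))


def _is_separable(s: np.ndarray, t: np.ndarray) -> bool:
    return s[t == 1].min() > s[t == 0].max() or s[t == 1].max() < s[t == 0].min()


def fit_logistic(data: LabeledScoreSet, regularization: float = 1e-6) -> LogisticParams:
    """Fit the logistic calibration by penalized maximum likelihood.

    Parameters
    ----------
    data
        Scores with binary target labels; both classes must be present.
    regularization
        Ridge penalty ``lam/2 * (a0^2 + a1^2)`` added to the negative
        log-likelihood. The small default guards against quasi-separation
        without visibly biasing the fit.
    """
    if regularization < 0:
        raise ValueError("regularization must be non-negative")
    s, t = data.s, data.t
    n_pos, n_neg = int(t.sum()), int((1 - t).sum())
    if n_pos == 0 or n_neg == 0:
        raise FitError("logistic fit needs both classes present")
    if regularization == 0 and _is_separable(s, t):
        raise FitError(
            "perfectly separable scores: the unpenalized MLE diverges; "
            "use regularization > 0"
        )
    # y in {-1,+1}: nll = -sum log sigma(y * (a0 + a1 s))
    y = 2.0 * t - 1.0

    def objective(params: np.ndarray) -> tuple[float, np.ndarray]:
        a0, a1 = params
        z = a0 + a1 * s
        nll = -np.sum(log_expit(y * z))
        nll += 0.5 * regularization * (a0 * a0 + a1 * a1)
        # d/dz -log sigma(y z) = sigma(z) - t
        resid = expit(z) - t
        grad = np.array(
            [resid.sum() + regularization * a0, resid @ s + regularization * a1]
        )
        return nll, grad

    res = minimize(objective, x0=np.zeros(2), jac=True, method="BFGS",
                   options={"gtol": 1e-10, "maxiter": 500})
    if not np.all(np.isfinite(res.x)):
        raise FitError(f"logistic fit failed: {res.message}")
    return LogisticParams(float(res.x[0]), float(res.x[1]))


def beta_prob(s, params: LogisticParams):
    """Evaluate beta(s) = 1 / (1 + exp(-(a0 + a1*s))).

    Accepts a scalar or an array; strictly increasing in s when a1 > 0
    and always in (0, 1) for finite s.
    """
    return expit(params.a0 + params.a1 * np.asarray(s, dtype=float))
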