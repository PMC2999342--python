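"""End-to-end prediction pipeline: priors -> VBEM -> alpha/beta -> product -> rank."""

from __future__ import annotations

import numpy as np

from .calibration import LogisticParams
from .combiner import AlphaFunction, PredictionRecord, build_predictions
from .io_formats import ExpressionProfile, ScoreTable, VerifiedExpressionSet, align_genes
from .priors import default_prior_bundle
from .vbem import MixturePosterior, VBEMConfig, vbem_fit

__all__ = ["predict_targets"]


def predict_targets(
    profile: ExpressionProfile,
    scores: ScoreTable,
    logistic: LogisticParams,
    verified: VerifiedExpressionSet | None = None,
    clamp_threshold: float = 0.5,
    vbem_config: VBEMConfig | None = None,
) -> tuple[list[PredictionRecord], MixturePosterior]:
    """Run the full fusion pipeline and return ranked records plus the fit.

    The mixture is fitted to the full genome-wide fold-change vector;
    the combined ranking covers only genes present in both evidence
    sources.
    """
    priors = default_prior_bundle(verified)
    fit = vbem_fit(np.asarray(profile.e, dtype=float), priors, vbem_config)
    alpha_fn = AlphaFunction(fit.theta_hat, clamp_threshold=clamp_threshold)
    aligned = align_genes(profile, scores)
    records = build_predictions(aligned, logistic, alpha_fn)
    return records, fit
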