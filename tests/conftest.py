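import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mirbayes import (
    LabeledScoreSet,
    SimulationConfig,
    default_prior_bundle,
    fit_logistic,
    pr_curve,
    rank_only_records,
    predict_targets,
    simulate_dataset,
    simulate_verified_targets,
    vbem_fit,
)

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

N_REPLICATES = 20


@pytest.fixture(scope="session")
def study_replicates():
    """Twenty seeded replicates of the full simulation study.

    Each replicate simulates the default two-population dataset, builds
    the informative prior from a fresh 209-value verified set, fits the
    mixture by VBEM, runs the fused ranking, and records the PR areas of
    the combined, score-only and expression-only rankers.
    """
    out = []
    for seed in range(N_REPLICATES):
        ds = simulate_dataset(SimulationConfig(seed=seed))
        verified = simulate_verified_targets(seed=seed + 1000)
        cal = simulate_dataset(SimulationConfig(seed=seed + 5000))
        logistic = fit_logistic(LabeledScoreSet(cal.scores, cal.labels))
        records, fit = predict_targets(
            ds.to_expression_profile(), ds.to_score_table(), logistic, verified
        )
        truth = ds.truth_set()
        out.append(
            {
                "dataset": ds,
                "fit": fit,
                "theta": fit.theta_hat,
                "records": records,
                "truth": truth,
                "auc_combined": pr_curve(records, truth).auc_pr,
                "auc_score": pr_curve(
                    rank_only_records(list(ds.gene_ids), ds.scores, descending=True),
                    truth,
                ).auc_pr,
                "auc_expression": pr_curve(
                    rank_only_records(list(ds.gene_ids), ds.fold_changes, descending=False),
                    truth,
                ).auc_pr,
            }
        )
    return out


@pytest.fixture(scope="session")
def default_priors():
    return default_prior_bundle(simulate_verified_targets(seed=11))


@pytest.fixture(scope="session")
def study_fit(default_priors):
    """One representative VBEM fit on a default simulated dataset."""
    ds = simulate_dataset(SimulationConfig(seed=3))
    return vbem_fit(ds.fold_changes, default_priors)
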