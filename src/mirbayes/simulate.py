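"""Synthetic data mirroring the validation simulation.

Generates the labeled two-population dataset used throughout: positive
(target) genes draw their sequence score from N(0.75, 0.5) and their
fold change from N(-0.5, 0.5); negatives draw from N(-0.75, 0.5) and
N(0, 0.4) respectively, at 200 positives to 19800 negatives (a 1%
positive fraction). All second parameters are variances. Scores and
fold changes are independent given the label, matching the Naive Bayes
assumption. Also generates verified-target fold-change sets for
building the informative prior (default 209 values, drawn from the
positive component's fold-change distribution).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_formats import ExpressionProfile, ScoreTable, VerifiedExpressionSet

__all__ = ["SimulationConfig", "SimulatedDataset", "simulate_dataset", "simulate_verified_targets", "write_dataset"]


@dataclass(frozen=True)
class SimulationConfig:
    """Population parameters of the simulation; (mean, variance) pairs."""

    n_pos: int = 200
    n_neg: int = 19800
    score_pos: tuple[float, float] = (0.75, 0.5)
    score_neg: tuple[float, float] = (-0.75, 0.5)
    fc_pos: tuple[float, float] = (-0.5, 0.5)
    fc_neg: tuple[float, float] = (0.0, 0.4)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 0 or self.n_neg < 0:
            raise ValueError("sample sizes must be non-negative")
        for name in ("score_pos", "score_neg", "fc_pos", "fc_neg"):
            if getattr(self, name)[1] <= 0:
                raise ValueError(f"{name} variance must be positive")


@dataclass
class SimulatedDataset:
    """Labeled synthetic genes with scores and fold changes."""

    gene_ids: np.ndarray
    labels: np.ndarray
    scores: np.ndarray
    fold_changes: np.ndarray

    def to_score_table(self) -> ScoreTable:
        return ScoreTable(self.gene_ids, self.scores)

    def to_expression_profile(self) -> ExpressionProfile:
        return ExpressionProfile(self.gene_ids, self.fold_changes)

    def truth_set(self) -> set[str]:
        return set(self.gene_ids[self.labels == 1])

    def __len__(self) -> int:
        return len(self.gene_ids)


def simulate_dataset(config: SimulationConfig | None = None) -> SimulatedDataset:
    """Draw a labeled dataset from the configured Gaussian populations.

    Gene identifiers are zero-padded ("G000001", ...) so lexicographic
    tie-breaks in downstream ranking are deterministic; positives come
    first in the identifier sequence.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    n = config.n_pos + config.n_neg
    gene_ids = np.array([f"G{i:06d}" for i in range(1, n + 1)], dtype=object)
    labels = np.concatenate(
        [np.ones(config.n_pos, dtype=int), np.zeros(config.n_neg, dtype=int)]
    )
    scores = np.concatenate([
        rng.normal(config.score_pos[0], np.sqrt(config.score_pos[1]), config.n_pos),
        rng.normal(config.score_neg[0], np.sqrt(config.score_neg[1]), config.n_neg),
    ])
    fold_changes = np.concatenate([
        rng.normal(config.fc_pos[0], np.sqrt(config.fc_pos[1]), config.n_pos),
        rng.normal(config.fc_neg[0], np.sqrt(config.fc_neg[1]), config.n_neg),
    ])
    return SimulatedDataset(gene_ids, labels, scores, fold_changes)


def simulate_verified_targets(
    n: int = 209,
    mean: float = -0.5,
    variance: float = 0.5,
    seed: int = 0,
) -> VerifiedExpressionSet:
    """Draw fold changes of verified targets for the informative prior.

    Defaults emulate a 209-strong verified set drawn from the positive
    component's fold-change distribution.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if variance < 0:
        raise ValueError("variance must be non-negative")
    rng = np.random.default_rng(seed)
    return VerifiedExpressionSet(rng.normal(mean, np.sqrt(variance), n))


def write_dataset(dataset: SimulatedDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write scores.tsv, expression.tsv, labels.tsv in the formats io_formats reads."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "scores": out_dir / "scores.tsv",
        "expression": out_dir / "expression.tsv",
        "labels": out_dir / "labels.tsv",
    }
    with open(paths["scores"], "w") as fh:
        for g, s in zip(dataset.gene_ids, dataset.scores):
            fh.write(f"{g}\t{s:.6g}\n")
    with open(paths["expression"], "w") as fh:
        for g, e in zip(dataset.gene_ids, dataset.fold_changes):
            fh.write(f"{g}\t{e:.6g}\n")
    with open(paths["labels"], "w") as fh:
        for g, t in zip(dataset.gene_ids, dataset.labels):
            fh.write(f"{g}\t{t}\n")
    return paths
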