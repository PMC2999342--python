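"""Tabular input/output and gene-set alignment.

All tables are tab-delimited text with optional ``#``-prefixed comment
lines; a comma delimiter can be requested explicitly. Gene identifiers
are matched by exact string equality after whitespace trimming — no
symbol/accession conversion is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import AlignmentError, FormatError, InputError

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionProfile",
    "ScoreTable",
    "LabeledScoreSet",
    "VerifiedExpressionSet",
    "read_expression_profile",
    "read_score_table",
    "read_labeled_scores",
    "read_verified_expression",
    "align_genes",
    "write_predictions",
    "read_predictions",
]


def _check_unique_finite(gene_ids: np.ndarray, values: np.ndarray, what: str) -> None:
    if len(gene_ids) != len(values):
        raise ValueError(f"{what}: gene_ids and values length mismatch")
    if len(np.unique(gene_ids)) != len(gene_ids):
        raise ValueError(f"{what}: gene identifiers must be unique")
    if not np.all(np.isfinite(values)):
        raise ValueError(f"{what}: values must be finite")


@dataclass
class ExpressionProfile:
    """Per-gene log fold changes from one miRNA transfection experiment."""

    gene_ids: np.ndarray
    e: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.e = np.asarray(self.e, dtype=float)
        _check_unique_finite(self.gene_ids, self.e, "ExpressionProfile")

    def __len__(self) -> int:
        return len(self.gene_ids)


@dataclass
class ScoreTable:
    """Per-gene sequence-level prediction scores (e.g. SVMicrO output)."""

    gene_ids: np.ndarray
    s: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.s = np.asarray(self.s, dtype=float)
        _check_unique_finite(self.gene_ids, self.s, "ScoreTable")

    def __len__(self) -> int:
        return len(self.gene_ids)


@dataclass
class LabeledScoreSet:
    """Scores with 0/1 target labels, for fitting the logistic calibration."""

    s: np.ndarray
    t: np.ndarray

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        self.t = np.asarray(self.t, dtype=int)
        if len(self.s) != len(self.t):
            raise ValueError("LabeledScoreSet: scores and labels length mismatch")
        if not np.all(np.isin(self.t, (0, 1))):
            raise ValueError("LabeledScoreSet: labels must be 0 or 1")

    def __len__(self) -> int:
        return len(self.s)


@dataclass
class VerifiedExpressionSet:
    """Log fold changes of experimentally verified targets.

    Feeds the informative prior on the positive mixture component.
    """

    values: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size and not np.all(np.isfinite(self.values)):
            raise ValueError("VerifiedExpressionSet: values must be finite")

    def __len__(self) -> int:
        return len(self.values)


def _read_two_column(path: str | Path, delimiter: str | None) -> pd.DataFrame:
    path = Path(path)
    if not path.is_file():
        raise InputError(f"cannot read {path}: no such file")
    try:
        df = pd.read_csv(
            path,
            sep=delimiter if delimiter is not None else r"\t|,",
            engine="python",
            comment="#",
            header=None,
            skip_blank_lines=True,
            dtype=str,
        )
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: no parseable rows") from None
    except OSError as exc:
        raise InputError(f"cannot read {path}: {exc}") from exc
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected at least two columns")
    df = df.iloc[:, :2].copy()
    df.columns = ["gene_id", "value"]
    df["gene_id"] = df["gene_id"].str.strip()
    df["value"] = pd.to_numeric(df["value"].str.strip(), errors="coerce")
    # a non-numeric first row is an (optional) header
    if len(df) and np.isnan(df["value"].iloc[0]):
        df = df.iloc[1:]
    df = df.dropna(subset=["value"])
    df = df[np.isfinite(df["value"])]
    if df.empty:
        raise FormatError(f"{path}: no parseable rows")
    return df


def _collapse_duplicates(df: pd.DataFrame, path: str | Path) -> pd.DataFrame:
    n_dup = df["gene_id"].duplicated().sum()
    if n_dup:
        logger.warning("%s: %d duplicate gene rows collapsed by mean", path, n_dup)
        df = df.groupby("gene_id", sort=False, as_index=False)["value"].mean()
    return df


def read_expression_profile(path: str | Path, delimiter: str | None = None) -> ExpressionProfile:
    """Read a (gene_id, log fold change) table.

    Duplicate gene rows are averaged (probe-level exports commonly repeat
    genes) with a logged warning.
    """
    df = _collapse_duplicates(_read_two_column(path, delimiter), path)
    return ExpressionProfile(df["gene_id"].to_numpy(object), df["value"].to_numpy(float))


def read_score_table(path: str | Path, delimiter: str | None = None) -> ScoreTable:
    """Read a (gene_id, sequence score) table; duplicates averaged."""
    df = _collapse_duplicates(_read_two_column(path, delimiter), path)
    return ScoreTable(df["gene_id"].to_numpy(object), df["value"].to_numpy(float))


def read_labeled_scores(path: str | Path, delimiter: str | None = None) -> LabeledScoreSet:
    """Read a (score, 0/1 label) table for logistic calibration."""
    df = _read_two_column(path, delimiter)
    scores = pd.to_numeric(df["gene_id"], errors="coerce").to_numpy(float)
    labels = df["value"].to_numpy(float)
    keep = np.isfinite(scores)
    if not keep.any():
        raise FormatError(f"{path}: no parseable rows")
    return LabeledScoreSet(scores[keep], labels[keep].round().astype(int))


def read_verified_expression(path: str | Path) -> VerifiedExpressionSet:
    """Read a one-value-per-line list of verified-target fold changes."""
    path = Path(path)
    if not path.is_file():
        raise InputError(f"cannot read {path}: no such file")
    values = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        try:
            values.append(float(line))
        except ValueError:
            continue
    if not values:
        raise FormatError(f"{path}: no parseable rows")
    return VerifiedExpressionSet(np.array(values))


def align_genes(
    profile: ExpressionProfile, scores: ScoreTable
) -> list[tuple[str, float, float]]:
    """Intersect the two evidence sources by gene identifier.

    Returns ``(gene_id, e, s)`` triples in the profile's order; counts of
    genes dropped from each side are logged.
    """
    if len(profile) == 0 or len(scores) == 0:
        raise AlignmentError("both inputs must be non-empty")
    score_map = dict(zip(scores.gene_ids, scores.s))
    aligned = [
        (g, float(e), float(score_map[g]))
        for g, e in zip(profile.gene_ids, profile.e)
        if g in score_map
    ]
    if not aligned:
        raise AlignmentError("expression profile and score table share no genes")
    logger.info(
        "aligned %d genes (%d dropped from expression, %d from scores)",
        len(aligned),
        len(profile) - len(aligned),
        len(scores) - len(aligned),
    )
    return aligned


_PRED_COLUMNS = ("gene_id", "s", "beta", "e", "alpha", "combined", "rank")


def write_predictions(records: Sequence, path: str | Path) -> None:
    """Write ranked prediction records as TSV.

    Columns: gene_id, s, beta, e, alpha, combined, rank. Numeric values
    carry 6 significant digits so a write/read round trip is lossless at
    that precision.
    """
    path = Path(path)
    if not records:
        logger.warning("writing header-only prediction file: no records")
    try:
        with open(path, "w") as fh:
            fh.write("\t".join(_PRED_COLUMNS) + "\n")
            for r in records:
                fh.write(
                    f"{r.gene_id}\t{r.s:.6g}\t{r.beta:.6g}\t{r.e:.6g}"
                    f"\t{r.alpha:.6g}\t{r.combined:.6g}\t{r.rank}\n"
                )
    except OSError as exc:
        raise InputError(f"cannot write {path}: {exc}") from exc


def read_predictions(path: str | Path) -> pd.DataFrame:
    """Read a prediction TSV written by :func:`write_predictions`."""
    path = Path(path)
    if not path.is_file():
        raise InputError(f"cannot read {path}: no such file")
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(_PRED_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    return df
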