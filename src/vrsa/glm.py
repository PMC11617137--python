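"""Condition beta estimation and assembly of the condition-by-voxel U matrix.

Betas are estimated per run by ordinary least squares against the
HRF-convolved design matrix; the 8 no-go condition betas (canonical order)
form the run's pattern matrix, and runs are pooled — by averaging, the
default — into one U per subject and region.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .task_design import CONDITION_LABELS, DesignMatrix

logger = logging.getLogger(__name__)

__all__ = ["PatternMatrix", "RankDeficientError", "estimate_betas", "assemble_U"]


class RankDeficientError(np.linalg.LinAlgError):
    """Raised when the design matrix is rank deficient (no silent pseudo-inverse)."""


@dataclass
class PatternMatrix:
    """Condition-by-voxel activity estimates for one subject/region."""

    values: np.ndarray  # (8, n_voxels)
    condition_labels: tuple[str, ...] = CONDITION_LABELS
    subject: int | str | None = None
    run: int | str | None = None
    epoch: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != len(self.condition_labels):
            raise ValueError(
                f"expected {len(self.condition_labels)} condition rows, got shape "
                f"{self.values.shape}"
            )

    @property
    def n_voxels(self) -> int:
        return self.values.shape[1]

    def permuted(self, perm: np.ndarray) -> "PatternMatrix":
        """Rows (condition labels) shuffled by ``perm``; voxel order untouched."""
        return PatternMatrix(
            values=self.values[np.asarray(perm)],
            condition_labels=self.condition_labels,
            subject=self.subject,
            run=self.run,
            epoch=self.epoch,
        )

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.values.T, columns=list(self.condition_labels))
        df.to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_tsv(cls, path, **meta) -> "PatternMatrix":
        df = pd.read_csv(path, sep="\t")
        return cls(
            values=df.to_numpy(dtype=float).T,
            condition_labels=tuple(df.columns),
            **meta,
        )


def estimate_betas(
    y: np.ndarray, X: DesignMatrix, conditions_only: bool = False
) -> np.ndarray:
    """Ordinary least-squares regression weights, one column per voxel.

    Returns the full (n_regressors, n_voxels) beta matrix, or only the 8
    condition rows in canonical order when ``conditions_only`` is set.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    M = X.values
    if y.shape[0] != M.shape[0]:
        raise ValueError(
            f"scan count mismatch: y has {y.shape[0]} rows, design has {M.shape[0]}"
        )
    if np.linalg.matrix_rank(M) < M.shape[1]:
        raise RankDeficientError("design matrix is rank deficient")
    beta, *_ = np.linalg.lstsq(M, y, rcond=None)
    if conditions_only:
        beta = beta[X.condition_columns]
    return beta


def assemble_U(
    run_patterns: list[PatternMatrix], pooling: str = "average"
) -> PatternMatrix:
    """Pool per-run condition patterns into one U matrix.

    ``average`` (default) averages each condition's pattern across runs;
    ``concatenate_runs`` stacks runs along the voxel axis.  Voxel columns with
    any non-finite value are dropped (logged).
    """
    if not run_patterns:
        raise ValueError("need at least one run")
    labels = run_patterns[0].condition_labels
    n_vox = run_patterns[0].n_voxels
    for pm in run_patterns[1:]:
        if pm.condition_labels != labels:
            raise ValueError("runs have mismatched condition labels")
        if pooling == "average" and pm.n_voxels != n_vox:
            raise ValueError("runs have mismatched voxel counts")
    if pooling == "average":
        values = np.mean([pm.values for pm in run_patterns], axis=0)
    elif pooling == "concatenate_runs":
        values = np.concatenate([pm.values for pm in run_patterns], axis=1)
    else:
        raise ValueError(f"unknown pooling {pooling!r}")
    finite = np.all(np.isfinite(values), axis=0)
    if not finite.all():
        logger.info("dropping %d voxel(s) with non-finite betas", (~finite).sum())
        values = values[:, finite]
    first = run_patterns[0]
    return PatternMatrix(
        values=values,
        condition_labels=labels,
        subject=first.subject,
        run="pooled",
        epoch=first.epoch,
    )
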