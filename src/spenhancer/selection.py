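"""Chi-squared removal of uninformative SeqPose positions.

Each encoded position column is a categorical variable (the k-mer ID at a
fixed window offset).  For every column the observed class-by-category
contingency table is compared with its independence expectation:

    vObserved = Y_label^T X              (one-hot labels x one-hot IDs)
    vExpected = vProbClass^T vFeatureSum (class proportions x column sums)
    cell statistic = (obs - exp)^2 / exp

The per-category statistic (summed over classes) is referred to a
chi-square distribution with ``n_classes - 1`` degrees of freedom, and a
column's score, ``vFeaturePvalue``, is the *sum* of its category p-values
— a ranking score, not a probability (it can exceed 1).  Columns with the
largest summed p-values carry the least label information and are removed
from every matrix, training and test alike.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .seqpose import EncodedMatrix
from .seq_io import ValidationError

DEFAULT_K_REMOVED = 45


@dataclass
class Chi2Work:
    """Intermediate quantities for one position column."""

    categories: np.ndarray     # distinct IDs, ascending
    X: np.ndarray              # samples x categories one-hot
    Y_label: np.ndarray        # samples x classes one-hot (class 0, class 1)
    vObserved: np.ndarray      # classes x categories counts
    vFeatureSum: np.ndarray    # per-category totals
    vProbClass: np.ndarray     # (P(class 0), P(class 1))
    vExpected: np.ndarray      # classes x categories expected counts
    N: int
    N1: int
    N0: int

    @property
    def vProbP(self) -> float:
        return self.vProbClass[1]

    @property
    def vProbN(self) -> float:
        return self.vProbClass[0]


@dataclass
class PositionScoreTable:
    """Per-position summed p-values with a removal mask."""

    position_pvalues: np.ndarray   # (n_columns,)
    ranking: np.ndarray            # column indices, p-value descending
    removed: np.ndarray            # boolean mask, True = removed
    K: int

    def to_tsv(self, path: str | Path) -> None:
        rank_of = np.empty(len(self.ranking), dtype=int)
        rank_of[self.ranking] = np.arange(len(self.ranking))
        with open(path, "w") as fh:
            fh.write("position\tpvalue\trank\tremoved\n")
            for pos, pval in enumerate(self.position_pvalues):
                fh.write(
                    f"{pos}\t{pval:.8f}\t{rank_of[pos]}\t"
                    f"{int(self.removed[pos])}\n"
                )


def onehot_expand(column: Sequence[int], labels: Sequence[int]) -> Chi2Work:
    """One-hot expand a position column and its binary labels.

    Categories are the distinct IDs present in the column, in ascending ID
    order; label columns are ordered (class 0, class 1).
    """
    col = np.asarray(column, dtype=np.int64)
    y = np.asarray(labels, dtype=np.int64)
    if col.shape != y.shape or col.ndim != 1 or col.size == 0:
        raise ValidationError("column and labels must be equal-length 1-D, non-empty")
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValidationError(
            "labels must contain both classes (expected counts for an "
            "absent class are zero)"
        )
    categories, inverse = np.unique(col, return_inverse=True)
    X = np.zeros((col.size, categories.size))
    X[np.arange(col.size), inverse] = 1.0
    Y = np.zeros((col.size, 2))
    Y[np.arange(col.size), y] = 1.0
    observed = Y.T @ X
    feature_sum = X.sum(axis=0)
    prob_class = np.array([n0, n1]) / col.size
    expected = np.outer(prob_class, feature_sum)
    return Chi2Work(
        categories=categories,
        X=X,
        Y_label=Y,
        vObserved=observed,
        vFeatureSum=feature_sum,
        vProbClass=prob_class,
        vExpected=expected,
        N=col.size,
        N1=n1,
        N0=n0,
    )


def chi2_position(
    work: Chi2Work,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Per-category chi-square statistics and the summed position p-value.

    Returns ``(statistics, pvalues, position_pvalue)`` where the arrays
    have one entry per k-mer category.  Degrees of freedom are
    ``n_classes - 1`` (1 for binary labels).
    """
    if np.any(work.vExpected == 0):
        raise ValidationError("zero expected cell: a class has zero samples")
    cells = (work.vObserved - work.vExpected) ** 2 / work.vExpected
    statistics = cells.sum(axis=0)
    df = work.Y_label.shape[1] - 1
    pvalues = stats.chi2.sf(statistics, df)
    return statistics, pvalues, float(pvalues.sum())


def score_all_positions(matrix: EncodedMatrix) -> PositionScoreTable:
    """Score every column of a labelled matrix (vFeaturePvalue per column).

    The ranking sorts columns by p-value descending (most removable
    first); ties break toward the lower column index.
    """
    if matrix.labels is None:
        raise ValidationError("matrix must carry labels")
    pvals = np.empty(matrix.n_columns)
    for j in range(matrix.n_columns):
        work = onehot_expand(matrix.ids[:, j], matrix.labels)
        _, _, pvals[j] = chi2_position(work)
    # stable sort on -p so equal p-values keep ascending column order
    ranking = np.argsort(-pvals, kind="stable")
    removed = np.zeros(matrix.n_columns, dtype=bool)
    return PositionScoreTable(
        position_pvalues=pvals, ranking=ranking, removed=removed, K=0
    )


def remove_top_k(table: PositionScoreTable, K: int = DEFAULT_K_REMOVED) -> np.ndarray:
    """Mask the K columns with the largest summed p-values.

    Ties remove the lower column index first.  Returns the boolean mask
    (True = removed) and records it on the table.
    """
    n = len(table.position_pvalues)
    if not 0 <= K < n:
        raise ValidationError(f"K={K} out of range [0, {n})")
    removed = np.zeros(n, dtype=bool)
    removed[table.ranking[:K]] = True
    table.removed = removed
    table.K = K
    return removed


def apply_mask(matrix: EncodedMatrix, mask: np.ndarray) -> EncodedMatrix:
    """Drop masked columns from a matrix (train or test identically)."""
    mask = np.asarray(mask, dtype=bool)
    if mask.size != matrix.n_columns:
        raise ValidationError(
            f"mask length {mask.size} != column count {matrix.n_columns}"
        )
    out = EncodedMatrix.__new__(EncodedMatrix)
    out.ids = matrix.ids[:, ~mask]
    out.k = matrix.k
    out.track_mode = matrix.track_mode
    out.n = matrix.n
    out.labels = matrix.labels
    return out


def save_mask(
    mask: np.ndarray, path: str | Path, k: int, track_mode: str
) -> None:
    """Serialize a removal mask as JSON (removed indices + provenance)."""
    mask = np.asarray(mask, dtype=bool)
    payload = {
        "removed_columns": [int(i) for i in np.flatnonzero(mask)],
        "K": int(mask.sum()),
        "n_columns": int(mask.size),
        "k": k,
        "track_mode": track_mode,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


def load_mask(path: str | Path) -> np.ndarray:
    with open(path) as fh:
        payload = json.load(fh)
    mask = np.zeros(payload["n_columns"], dtype=bool)
    mask[payload["removed_columns"]] = True
    return mask


def removal_sweep(
    matrix: EncodedMatrix,
    evaluator: Callable[[np.ndarray], dict[str, float]],
    coarse_step: int = 5,
    coarse_max: int = DEFAULT_K_REMOVED,
    fine_steps: int = 5,
    pivot: int | None = None,
) -> list[dict[str, float]]:
    """Performance-vs-K curve for coarse then fine removal.

    ``evaluator`` receives a removal mask and returns a metric dict (Sn,
    Sp, Acc, MCC, AUC).  Coarse rows run K = 0, coarse_step, ...,
    coarse_max; fine rows run K = pivot+1 .. pivot+fine_steps (pivot
    defaults to coarse_max).
    """
    table = score_all_positions(matrix)
    if pivot is None:
        pivot = coarse_max
    rows: list[dict[str, float]] = []
    ks = list(range(0, coarse_max + 1, coarse_step))
    ks += list(range(pivot + 1, pivot + fine_steps + 1))
    for K in ks:
        mask = remove_top_k(table, K)
        row = {"K": float(K)}
        row.update(evaluator(mask))
        rows.append(row)
    return rows
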