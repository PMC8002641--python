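"""Performance metrics and validation protocols.

Metrics follow the convention common in this literature: with S+ positive
and S− negative samples, S−+ incorrectly predicted positives (false
negatives) and S+− incorrectly predicted negatives (false positives),

    Sn  = 1 − S−+/S+
    Sp  = 1 − S+−/S−
    Acc = 1 − (S−+ + S+−)/(S+ + S−)
    MCC = (1 − (S−+/S+ + S+−/S−)) /
          sqrt((1 + (S+− − S−+)/S+) · (1 + (S−+ − S+−)/S−))

The MCC form above is an algebraic rearrangement of the standard
TP/TN/FP/FN formula (asserted by exhaustive enumeration in the tests).
AUC is the threshold-independent area under the ROC curve.

Protocols: a seeded stratified 10%/10% test/validation split, leave-one-
out cross-validation, the 8-fold hyperparameter grid search, and the
word-vector-dimension sweep.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.metrics import roc_auc_score

from .classifier import ModelConfig, predict, train_head
from .seq_io import ValidationError
from .seqpose import EncodedMatrix

DEFAULT_SEED = 75

FULL_GRID = {
    "pLSTMSize": (64, 128, 192),
    "pDropoutRatio": (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7),
    "pBatchSize": (16, 32, 64, 128, 256, 512),
}
QSWEEP_DIMS = (12, 24, 48, 96, 192, 394, 768, 1536)


@dataclass
class ConfusionCounts:
    """Positive/negative totals and the two error counts."""

    S_plus: int        # number of positive samples
    S_minus: int       # number of negative samples
    S_minus_plus: int  # incorrectly predicted positives (false negatives)
    S_plus_minus: int  # incorrectly predicted negatives (false positives)

    def __post_init__(self) -> None:
        if not 0 <= self.S_minus_plus <= self.S_plus:
            raise ValidationError("S−+ must satisfy 0 <= S−+ <= S+")
        if not 0 <= self.S_plus_minus <= self.S_minus:
            raise ValidationError("S+− must satisfy 0 <= S+− <= S−")


@dataclass
class MetricsReport:
    Sn: float
    Sp: float
    Acc: float
    MCC: float
    AUC: float | None = None

    def as_dict(self) -> dict[str, float]:
        d = {"Acc": self.Acc, "Sn": self.Sn, "Sp": self.Sp, "MCC": self.MCC}
        if self.AUC is not None:
            d["AUC"] = self.AUC
        return d


@dataclass
class GridResult:
    rows: list[dict]
    best: dict


def confusion(labels: Sequence[int], calls: Sequence[int]) -> ConfusionCounts:
    """Tally the four confusion counts from 0/1 labels and calls."""
    y = np.asarray(labels)
    c = np.asarray(calls)
    if y.shape != c.shape:
        raise ValidationError(
            f"labels length {y.size} != calls length {c.size}"
        )
    return ConfusionCounts(
        S_plus=int((y == 1).sum()),
        S_minus=int((y == 0).sum()),
        S_minus_plus=int(((y == 1) & (c == 0)).sum()),
        S_plus_minus=int(((y == 0) & (c == 1)).sum()),
    )


def metrics(
    counts: ConfusionCounts,
    probs: Sequence[float] | None = None,
    labels: Sequence[int] | None = None,
) -> MetricsReport:
    """Compute Sn, Sp, Acc, MCC (and AUC when probabilities are given).

    Sn/Sp/MCC require at least one sample in each class.  The MCC
    denominator vanishes only when a predicted class is empty; the
    standard value 0 is returned then.
    """
    sp, sm = counts.S_plus, counts.S_minus
    fn, fp = counts.S_minus_plus, counts.S_plus_minus
    if sp == 0 or sm == 0:
        raise ValidationError("Sn/Sp/MCC need both classes present")
    sn_metric = 1.0 - fn / sp
    sp_metric = 1.0 - fp / sm
    acc = 1.0 - (fn + fp) / (sp + sm)
    denom = (1.0 + (fp - fn) / sp) * (1.0 + (fn - fp) / sm)
    if denom <= 0.0:
        mcc = 0.0
    else:
        mcc = (1.0 - (fn / sp + fp / sm)) / math.sqrt(denom)
    auc = None
    if probs is not None:
        if labels is None:
            raise ValidationError("labels are required to compute AUC")
        auc = float(roc_auc_score(np.asarray(labels), np.asarray(probs)))
    return MetricsReport(Sn=sn_metric, Sp=sp_metric, Acc=acc, MCC=mcc, AUC=auc)


def evaluate_predictions(
    labels: Sequence[int], calls: Sequence[int], probs: Sequence[float] | None = None
) -> MetricsReport:
    """Convenience wrapper: confusion + metrics in one call."""
    return metrics(confusion(labels, calls), probs=probs, labels=labels)


def _stratified_split(
    labels: np.ndarray, fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified held-out selection under the floor rounding rule.

    The held-out total is floor(fraction * N) — the remainder stays with
    the larger (kept) part.  Class quotas take their floors first; any
    shortfall is distributed by largest fractional remainder (ties to
    the smaller class label), keeping the split stratified.
    """
    n_held_total = int(np.floor(fraction * labels.size))
    classes = np.unique(labels)
    sizes = np.array([(labels == c).sum() for c in classes])
    exact = fraction * sizes
    quotas = np.floor(exact).astype(int)
    shortfall = n_held_total - quotas.sum()
    if shortfall > 0:
        # stable argsort on -remainder → ties resolve to smaller class
        order = np.argsort(-(exact - quotas), kind="stable")
        for j in order[:shortfall]:
            quotas[j] += 1
    held, kept = [], []
    for cls, quota in zip(classes, quotas):
        idx = np.flatnonzero(labels == cls)
        idx = idx[rng.permutation(idx.size)]
        held.append(idx[:quota])
        kept.append(idx[quota:])
    return np.sort(np.concatenate(kept)), np.sort(np.concatenate(held))


def split_protocol(
    labels: Sequence[int], seed: int = DEFAULT_SEED
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Seeded stratified split: 10% test, then 10% of the rest validation.

    Returns (train_idx, val_idx, test_idx) — disjoint, covering, sorted.
    Held-out sizes use the floor rule per class, remainder to the larger
    (training) part.
    """
    y = np.asarray(labels)
    if y.size < 10:
        raise ValidationError("need at least 10 samples to split")
    rng = np.random.default_rng(seed)
    rest, test_idx = _stratified_split(y, 0.10, rng)
    rest_kept, val_rel = _stratified_split(y[rest], 0.10, rng)
    return rest[rest_kept], rest[val_rel], test_idx


def _submatrix(matrix: EncodedMatrix, idx: np.ndarray) -> EncodedMatrix:
    out = EncodedMatrix.__new__(EncodedMatrix)
    out.ids = matrix.ids[idx]
    out.k = matrix.k
    out.track_mode = matrix.track_mode
    out.n = matrix.n
    out.labels = None if matrix.labels is None else matrix.labels[idx]
    return out


def loocv(
    matrix: EncodedMatrix,
    config: ModelConfig,
    max_n: int | None = None,
    seed: int = DEFAULT_SEED,
) -> MetricsReport:
    """Leave-one-out cross-validation on a labelled matrix.

    Each sample is predicted by a head trained (fixed seed) on all other
    samples, which double as the validation set for epoch selection.
    ``max_n`` subsamples the matrix (stratified, seeded) for desk-scale
    runs; full-scale LOOCV retrains once per sample and is long-running.
    """
    if matrix.labels is None:
        raise ValidationError("matrix must carry labels")
    idx = np.arange(matrix.ids.shape[0])
    if max_n is not None and max_n < idx.size:
        rng = np.random.default_rng(seed)
        keep, _ = _stratified_split(matrix.labels, 1.0 - max_n / idx.size, rng)
        idx = keep
    probs = np.empty(idx.size)
    calls = np.empty(idx.size, dtype=int)
    for i, held in enumerate(idx):
        rest = idx[idx != held]
        train = _submatrix(matrix, rest)
        head = train_head(train, train, config)
        p, c = predict(head, _submatrix(matrix, np.array([held])))
        probs[i], calls[i] = p[0], c[0]
    labels = matrix.labels[idx]
    return evaluate_predictions(labels, calls, probs)


def _stratified_folds(
    labels: np.ndarray, n_folds: int, rng: np.random.Generator
) -> list[np.ndarray]:
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        idx = idx[rng.permutation(idx.size)]
        for i, j in enumerate(idx):
            folds[i % n_folds].append(int(j))
    return [np.sort(np.array(f)) for f in folds]


def cross_validate(
    matrix: EncodedMatrix,
    config: ModelConfig,
    n_folds: int = 8,
    seed: int = DEFAULT_SEED,
) -> MetricsReport:
    """Stratified k-fold cross-validation; pooled held-out predictions."""
    if matrix.labels is None:
        raise ValidationError("matrix must carry labels")
    rng = np.random.default_rng(seed)
    folds = _stratified_folds(matrix.labels, n_folds, rng)
    all_idx = np.arange(matrix.ids.shape[0])
    probs = np.empty(all_idx.size)
    calls = np.empty(all_idx.size, dtype=int)
    for fold in folds:
        rest = np.setdiff1d(all_idx, fold)
        head = train_head(_submatrix(matrix, rest), _submatrix(matrix, rest), config)
        p, c = predict(head, _submatrix(matrix, fold))
        probs[fold], calls[fold] = p, c
    return evaluate_predictions(matrix.labels, calls, probs)


def grid_search(
    matrix: EncodedMatrix,
    base_config: ModelConfig,
    grid: dict[str, Sequence] | None = None,
    n_folds: int = 8,
    seed: int = DEFAULT_SEED,
) -> GridResult:
    """Exhaustive hyperparameter grid, selected by cross-validated Acc.

    The full published grid is 3 LSTM sizes x 7 dropout ratios x 6 batch
    sizes = 126 combinations; pass a restricted ``grid`` for desk-scale
    runs.  Ties keep the first row in grid order.
    """
    grid = dict(FULL_GRID if grid is None else grid)
    names = list(grid)
    rows: list[dict] = []
    for values in itertools.product(*(grid[n] for n in names)):
        cfg_kwargs = {**base_config.__dict__, **dict(zip(names, values))}
        cfg = ModelConfig(**cfg_kwargs)
        report = cross_validate(matrix, cfg, n_folds=n_folds, seed=seed)
        row = dict(zip(names, values))
        row.update(report.as_dict())
        rows.append(row)
    best = max(rows, key=lambda r: r["Acc"])  # max keeps the first argmax
    return GridResult(rows=rows, best=best)


def qsweep(
    train: EncodedMatrix,
    val: EncodedMatrix,
    test: EncodedMatrix,
    base_config: ModelConfig,
    dims: Sequence[int] = QSWEEP_DIMS,
) -> list[dict]:
    """Word-vector-dimension sweep: one trained/evaluated model per Q."""
    rows = []
    for q in dims:
        cfg = ModelConfig(**{**base_config.__dict__, "Q": q})
        head = train_head(train, val, cfg)
        probs, calls = predict(head, test)
        report = evaluate_predictions(test.labels, calls, probs)
        row = {"Q": q}
        row.update(report.as_dict())
        rows.append(row)
    return rows


def report_table(rows: list[dict]) -> str:
    """Render metric rows as a TSV table (Acc Sn Sp MCC AUC layout)."""
    if not rows:
        return ""
    metric_cols = [c for c in ("Acc", "Sn", "Sp", "MCC", "AUC") if c in rows[0]]
    param_cols = [c for c in rows[0] if c not in metric_cols]
    header = "\t".join(param_cols + metric_cols)
    lines = [header]
    for row in rows:
        cells = [str(row[c]) for c in param_cols]
        cells += [f"{row[c]:.4f}" for c in metric_cols]
        lines.append("\t".join(cells))
    return "\n".join(lines) + "\n"
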