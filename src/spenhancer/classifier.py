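"""The spEnhancer classifier: training protocol and two-layer cascade.

Each head is an attention BiLSTM over embedded position-ID vectors
(:class:`~spenhancer.nn.SequenceClassifierNet`).  The detection head
separates enhancers from non-enhancers; the strength head separates
strong from weak enhancers among detected ones.  Both heads share one
architecture and training protocol: Adam, up to six epochs, batch size
64, and the epoch with the best validation accuracy is retained.

Defaults follow the published configuration: embedding dimension Q=768,
64 LSTM units per direction, dropout 0.5, batch size 64, seed 75,
decision threshold 0.5.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from . import nn
from .seq_io import SequenceRecord, ValidationError
from .seqpose import EncodedMatrix, KmerDictionary, encode_dataset
from .selection import apply_mask

ROLES = ("detection", "strength", "three_class")
CATEGORY_ORDER = ("strong_enhancer", "weak_enhancer", "non_enhancer")


@dataclass
class ModelConfig:
    """Hyperparameters of one classifier head."""

    Q: int = 768                 # word-vector (embedding) dimension
    pLSTMSize: int = 64          # recurrent units per direction
    pDropoutRatio: float = 0.5
    pBatchSize: int = 64
    max_epochs: int = 6
    seed: int = 75
    threshold: float = 0.5       # probability cutoff (call 1 iff p >= threshold)
    P: int = 0                   # dictionary size; embedding vocabulary is P+1

    def __post_init__(self) -> None:
        if not 0.0 <= self.pDropoutRatio < 1.0:
            raise ValueError("pDropoutRatio must be in [0, 1)")
        if min(self.Q, self.pLSTMSize, self.pBatchSize, self.max_epochs) < 1:
            raise ValueError("Q, pLSTMSize, pBatchSize, max_epochs must be >= 1")


@dataclass
class TrainedHead:
    """A trained head plus its provenance and per-epoch training log."""

    role: str
    weights: dict[str, np.ndarray]
    config: ModelConfig
    input_columns: int
    training_log: list[dict] = field(default_factory=list)

    def network(self) -> nn.SequenceClassifierNet:
        net = build_network(
            self.config,
            self.input_columns,
            role=self.role,
        )
        net.set_weights(self.weights)
        return net


@dataclass
class SpEnhancerModel:
    """Two-head cascade with shared dictionary and removal mask."""

    detection: TrainedHead
    strength: TrainedHead
    dictionary: KmerDictionary
    mask: np.ndarray
    track_mode: str = "duplex"


def build_network(
    config: ModelConfig,
    input_columns: int,
    role: str = "detection",
    rng: np.random.Generator | None = None,
) -> nn.SequenceClassifierNet:
    """Instantiate the (untrained) network for a head.

    Layer order: embedding (P+1 x Q) -> bidirectional LSTM (2*pLSTMSize
    per timestep) -> batch normalization -> additive attention pooling ->
    dropout -> dense sigmoid (binary roles) or softmax over three units.
    """
    if role not in ROLES:
        raise ValueError(f"unknown role {role!r}")
    if input_columns < 1:
        raise ValueError("input_columns must be >= 1")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    units = 3 if role == "three_class" else 1
    return nn.SequenceClassifierNet(
        vocab_size=config.P + 1,
        embed_dim=config.Q,
        lstm_size=config.pLSTMSize,
        dropout_ratio=config.pDropoutRatio,
        output_units=units,
        rng=rng,
    )


def _check_training_inputs(
    train: EncodedMatrix, val: EncodedMatrix, n_classes: int
) -> None:
    if train.labels is None or val.labels is None:
        raise ValidationError("train and val matrices must carry labels")
    if train.ids.shape[0] == 0:
        raise ValidationError("empty training data")
    if train.ids.shape[1] != val.ids.shape[1]:
        raise ValidationError(
            f"train has {train.ids.shape[1]} columns but val has "
            f"{val.ids.shape[1]}"
        )
    present = np.unique(train.labels)
    if present.size < n_classes:
        raise ValidationError(
            f"training labels contain {present.size} class(es); "
            f"{n_classes} required"
        )


def _train(
    net: nn.SequenceClassifierNet,
    train: EncodedMatrix,
    val: EncodedMatrix,
    config: ModelConfig,
    rng: np.random.Generator,
    loss_fn,
    n_classes: int,
    role: str,
) -> TrainedHead:
    """Shared Adam training loop; retains the best-validation-Acc epoch."""
    optimizer = nn.Adam(net.params)
    X, y = train.ids, train.labels.astype(np.float64 if n_classes == 2 else np.int64)
    if n_classes > 2:
        y = train.labels
    n = X.shape[0]
    log: list[dict] = []
    best_acc, best_state = -1.0, None
    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        epoch_loss, batches = 0.0, 0
        for start in range(0, n, config.pBatchSize):
            idx = order[start : start + config.pBatchSize]
            optimizer.zero_grad()
            logits = net.forward(X[idx], train=True)
            loss, _, dlogits = loss_fn(logits, y[idx])
            net.backward(dlogits)
            optimizer.step()
            epoch_loss += loss
            batches += 1
        net.recalibrate_bn(X)
        val_acc = _accuracy(net, val, config.threshold)
        log.append(
            {
                "epoch": epoch + 1,
                "train_loss": round(epoch_loss / max(batches, 1), 8),
                "val_acc": round(val_acc, 8),
            }
        )
        if val_acc > best_acc:
            best_acc = val_acc
            best_state = net.get_weights()
    net.set_weights(best_state)
    return TrainedHead(
        role=role,
        weights=best_state,
        config=config,
        input_columns=X.shape[1],
        training_log=log,
    )


def _accuracy(
    net: nn.SequenceClassifierNet, matrix: EncodedMatrix, threshold: float
) -> float:
    probs = net.predict_proba(matrix.ids)
    if probs.ndim == 1:
        calls = (probs >= threshold).astype(int)
    else:
        calls = probs.argmax(axis=1)
    return float(np.mean(calls == matrix.labels))


def train_head(
    train: EncodedMatrix,
    val: EncodedMatrix,
    config: ModelConfig,
    role: str = "detection",
) -> TrainedHead:
    """Train one binary head (detection or strength).

    Runs up to ``max_epochs`` epochs of Adam with seeded shuffling; the
    epoch with the highest validation accuracy is kept.  Deterministic
    for a fixed (config, seed, data) triple within one environment.
    """
    if role not in ("detection", "strength"):
        raise ValueError(f"role must be detection or strength, got {role!r}")
    _check_training_inputs(train, val, n_classes=2)
    rng = np.random.default_rng(config.seed)
    net = build_network(config, train.ids.shape[1], role=role, rng=rng)
    return _train(net, train, val, config, rng, nn.sigmoid_bce, 2, role)


def train_three_class(
    train: EncodedMatrix,
    val: EncodedMatrix,
    config: ModelConfig,
) -> TrainedHead:
    """Train the direct three-class variant (softmax over the classes).

    Labels are integer codes 0=strong, 1=weak, 2=non; all three must be
    present in the training matrix.
    """
    _check_training_inputs(train, val, n_classes=3)
    rng = np.random.default_rng(config.seed)
    net = build_network(config, train.ids.shape[1], role="three_class", rng=rng)
    return _train(net, train, val, config, rng, nn.softmax_ce, 3, "three_class")


def predict(head: TrainedHead, matrix: EncodedMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Probabilities and 0/1 calls (call 1 iff probability >= threshold).

    For the three-class head the calls are argmax category codes.
    """
    if matrix.ids.shape[0] and matrix.ids.shape[1] != head.input_columns:
        raise ValidationError(
            f"matrix has {matrix.ids.shape[1]} columns but the head was "
            f"trained on {head.input_columns}"
        )
    net = head.network()
    probs = net.predict_proba(matrix.ids)
    if probs.ndim == 1:
        calls = (probs >= head.config.threshold).astype(int)
    else:
        calls = probs.argmax(axis=1)
    return probs, calls


def predict_two_layer(
    model: SpEnhancerModel, records: Sequence[SequenceRecord | str]
) -> list[dict]:
    """Cascade prediction: detection first, then strength for positives.

    A record called non-enhancer by the first layer is never given a
    strength category; its layer-2 probability is reported as NaN.
    """
    matrix = encode_dataset(records, model.dictionary, model.track_mode)
    masked = apply_mask(matrix, model.mask)
    p1, c1 = predict(model.detection, masked)
    p2, c2 = predict(model.strength, masked)
    out = []
    for i, rec in enumerate(records):
        rec_id = rec.id if isinstance(rec, SequenceRecord) else f"seq{i}"
        if c1[i] == 0:
            category, prob2 = "non_enhancer", float("nan")
        else:
            category = "strong_enhancer" if c2[i] == 1 else "weak_enhancer"
            prob2 = float(p2[i])
        out.append(
            {
                "id": rec_id,
                "prob_layer1": float(p1[i]),
                "prob_layer2": prob2,
                "category": category,
            }
        )
    return out


def save_head(head: TrainedHead, directory: str | Path) -> None:
    """Write a head bundle: weights (npz) + manifest.json + training log."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.savez(directory / "weights.npz", **head.weights)
    manifest = asdict(head.config)
    manifest.update(
        {
            "role": head.role,
            "input_columns": head.input_columns,
            "training_log": head.training_log,
        }
    )
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
        fh.write("\n")


def load_head(directory: str | Path) -> TrainedHead:
    directory = Path(directory)
    with open(directory / "manifest.json") as fh:
        manifest = json.load(fh)
    role = manifest.pop("role")
    input_columns = manifest.pop("input_columns")
    training_log = manifest.pop("training_log")
    config = ModelConfig(**manifest)
    with np.load(directory / "weights.npz") as npz:
        weights = {name: npz[name] for name in npz.files}
    return TrainedHead(
        role=role,
        weights=weights,
        config=config,
        input_columns=input_columns,
        training_log=training_log,
    )
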