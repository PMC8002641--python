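"""Sequence and label I/O for the enhancer benchmark.

The benchmark is a three-class collection of fixed-length DNA sequences:
strong enhancers, weak enhancers, and non-enhancers.  The canonical public
dataset has 742 + 742 + 1484 sequences of 200 bp each.  This module reads
per-class FASTA files (or a FASTA plus a two-column label TSV), assembles
them into a validated :class:`BenchmarkDataset`, and exposes the two binary
views used by the cascade classifier: enhancer-vs-non (detection) and
strong-vs-weak (strength).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

LABELS = ("strong_enhancer", "weak_enhancer", "non_enhancer")
DEFAULT_LENGTH = 200


class FastaError(ValueError):
    """Raised for malformed or empty FASTA input."""


class ValidationError(ValueError):
    """Raised when records violate dataset invariants."""


@dataclass
class SequenceRecord:
    """One DNA sequence with an optional class label."""

    id: str
    sequence: str
    label: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValidationError(f"record {self.id!r} has an empty sequence")
        if self.label is not None and self.label not in LABELS:
            raise ValidationError(
                f"record {self.id!r} has unknown label {self.label!r}; "
                f"expected one of {LABELS}"
            )


@dataclass
class BenchmarkDataset:
    """Ordered record collection with per-class counts.

    Records are stored strong, then weak, then non-enhancer (stable within
    each class).
    """

    records: list[SequenceRecord]
    expected_length: int = DEFAULT_LENGTH
    class_counts: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def labels(self) -> list[str | None]:
        return [r.label for r in self.records]


def read_fasta(path: str | Path, label: str | None = None) -> list[SequenceRecord]:
    """Read a FASTA file into uppercased :class:`SequenceRecord` objects.

    Parameters
    ----------
    path:
        FASTA file (single- or multi-line sequences).
    label:
        Optional class label attached to every record.

    Raises
    ------
    FastaError
        If the file is empty, or content precedes the first header line.
    """
    path = Path(path)
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise FastaError(
                    f"{path}: line {lineno}: expected a '>' header before "
                    f"sequence data: {stripped[:40]!r}"
                )
            break
        else:
            raise FastaError(f"{path}: empty FASTA file")

    records = [
        SequenceRecord(id=rec.id, sequence=str(rec.seq).upper(), label=label)
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise FastaError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records to FASTA, one sequence per line (round-trip safe)."""
    with open(path, "w") as handle:
        for rec in records:
            handle.write(f">{rec.id}\n{rec.sequence}\n")


def read_label_table(path: str | Path) -> dict[str, str]:
    """Read a two-column ``id<TAB>label`` TSV (header row optional)."""
    table: dict[str, str] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValidationError(
                    f"{path}: line {lineno}: expected 2 tab-separated columns"
                )
            rec_id, lab = parts
            if lineno == 1 and lab not in LABELS:
                continue  # header row
            if lab not in LABELS:
                raise ValidationError(
                    f"{path}: line {lineno}: unknown label {lab!r}"
                )
            table[rec_id] = lab
    return table


def attach_labels(
    records: Sequence[SequenceRecord], table: dict[str, str]
) -> list[SequenceRecord]:
    """Return records with labels looked up from an id->label table."""
    missing = [r.id for r in records if r.id not in table]
    if missing:
        raise ValidationError(f"no label for record ids: {missing[:5]}")
    return [
        SequenceRecord(id=r.id, sequence=r.sequence, label=table[r.id])
        for r in records
    ]


def _relabel(records: Sequence[SequenceRecord], label: str) -> list[SequenceRecord]:
    out = []
    for r in records:
        if r.label is not None and r.label != label:
            raise ValidationError(
                f"record {r.id!r} labelled {r.label!r}, expected {label!r}"
            )
        out.append(SequenceRecord(id=r.id, sequence=r.sequence, label=label))
    return out


def assemble_dataset(
    strong: Sequence[SequenceRecord],
    weak: Sequence[SequenceRecord],
    non: Sequence[SequenceRecord],
    expected_length: int = DEFAULT_LENGTH,
    strict_length: bool = True,
) -> BenchmarkDataset:
    """Assemble the three class collections into one dataset.

    Order is strong, weak, non (stable).  In strict mode every sequence
    must have exactly ``expected_length`` bases.
    """
    records = (
        _relabel(strong, "strong_enhancer")
        + _relabel(weak, "weak_enhancer")
        + _relabel(non, "non_enhancer")
    )
    if strict_length:
        bad = [r.id for r in records if len(r.sequence) != expected_length]
        if bad:
            raise ValidationError(
                f"{len(bad)} records deviate from expected length "
                f"{expected_length}: {bad[:5]}"
            )
    counts = {
        "strong_enhancer": len(strong),
        "weak_enhancer": len(weak),
        "non_enhancer": len(non),
    }
    return BenchmarkDataset(
        records=records, expected_length=expected_length, class_counts=counts
    )


def binary_view(
    dataset: BenchmarkDataset, layer: str
) -> tuple[list[SequenceRecord], list[int]]:
    """Project the three-class dataset onto one binary problem.

    ``layer="detection"``: enhancers (strong or weak) are positives (1),
    non-enhancers negatives (0); all records kept.
    ``layer="strength"``: strong enhancers are positives (1), weak
    negatives (0); non-enhancers are dropped.
    """
    if layer not in ("detection", "strength"):
        raise ValueError(f"unknown layer {layer!r}")
    unlabelled = [r.id for r in dataset.records if r.label is None]
    if unlabelled:
        raise ValidationError(f"unlabelled records: {unlabelled[:5]}")
    records: list[SequenceRecord] = []
    labels: list[int] = []
    for rec in dataset.records:
        if layer == "detection":
            records.append(rec)
            labels.append(0 if rec.label == "non_enhancer" else 1)
        else:
            if rec.label == "non_enhancer":
                continue
            records.append(rec)
            labels.append(1 if rec.label == "strong_enhancer" else 0)
    return records, labels
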