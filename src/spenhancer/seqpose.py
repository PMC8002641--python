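"""Position-specific k-mer (SeqPose) encoding.

A sequence of length ``n`` is sliced into ``n-k+1`` overlapping k-mers with
a step-1 sliding window.  A dictionary built from the training set maps
each distinct k-mer to a positive integer ID (first-appearance order);
k-mers absent from the dictionary (or containing non-ACGT characters) map
to ID 0.  A sequence thus becomes an ordered ID vector in which *position*
is a feature, not just composition.

Two track modes exist.  ``forward`` encodes the given strand only
(``n-k+1`` positions).  ``duplex``, the default, appends the positions of
the reverse-complement strand read 5'->3', doubling the feature count to
``2*(n-k+1)`` — 398 positions for 200 bp 2-mers — reflecting that a DNA
duplex carries the same information on both strands.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .seq_io import SequenceRecord, ValidationError

ALPHABET = frozenset("ACGT")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

TRACK_MODES = ("forward", "duplex")


@dataclass
class KmerDictionary:
    """k-mer -> positive-integer ID table (IDs are exactly 1..P)."""

    k: int
    entries: dict[str, int]

    @property
    def size(self) -> int:
        """P — the number of distinct k-mers in the dictionary."""
        return len(self.entries)

    def lookup(self, kmer: str) -> int:
        """ID of ``kmer``, or 0 when unknown (the out-of-dictionary rule)."""
        return self.entries.get(kmer, 0)

    def to_files(self, tsv_path: str | Path, meta: dict | None = None) -> None:
        """Serialize as ``kmer<TAB>id`` sorted by ID, plus a JSON sidecar."""
        tsv_path = Path(tsv_path)
        with open(tsv_path, "w") as fh:
            for kmer, kid in sorted(self.entries.items(), key=lambda kv: kv[1]):
                fh.write(f"{kmer}\t{kid}\n")
        header = {"k": self.k, "P": self.size}
        if meta:
            header.update(meta)
        with open(tsv_path.with_suffix(".json"), "w") as fh:
            json.dump(header, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_files(cls, tsv_path: str | Path) -> "KmerDictionary":
        tsv_path = Path(tsv_path)
        with open(tsv_path.with_suffix(".json")) as fh:
            header = json.load(fh)
        entries: dict[str, int] = {}
        with open(tsv_path) as fh:
            for line in fh:
                kmer, kid = line.split("\t")
                entries[kmer] = int(kid)
        return cls(k=int(header["k"]), entries=entries)


@dataclass
class EncodedMatrix:
    """Samples x position-features ID matrix, optionally labelled."""

    ids: np.ndarray  # (n_samples, n_columns) int
    k: int
    track_mode: str
    n: int  # source sequence length in bp
    labels: np.ndarray | None = None  # (n_samples,) 0/1 ints

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=np.int64)
        if self.ids.ndim != 2:
            raise ValidationError("ids must be a 2-D matrix")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int64)
            if self.labels.shape[0] != self.ids.shape[0]:
                raise ValidationError("labels length must equal row count")
        expected = expected_columns(self.n, self.k, self.track_mode)
        if self.ids.shape[1] != expected:
            raise ValidationError(
                f"column count {self.ids.shape[1]} != expected {expected} "
                f"for n={self.n}, k={self.k}, track_mode={self.track_mode}"
            )

    @property
    def n_columns(self) -> int:
        return self.ids.shape[1]

    def to_csv(self, path: str | Path) -> None:
        cols = self.ids
        if self.labels is not None:
            cols = np.column_stack([cols, self.labels])
        np.savetxt(path, cols, fmt="%d", delimiter=",")


def expected_columns(n: int, k: int, track_mode: str) -> int:
    """Column-count law: tracks * (n - k + 1)."""
    if track_mode not in TRACK_MODES:
        raise ValueError(f"unknown track_mode {track_mode!r}")
    tracks = 2 if track_mode == "duplex" else 1
    return tracks * (n - k + 1)


def reverse_complement(sequence: str) -> str:
    """Watson–Crick reverse complement (A<->T, C<->G, sequence reversed)."""
    return sequence.translate(_COMPLEMENT)[::-1]


def extract_kmers(sequence: str, k: int) -> list[str]:
    """All k-mers by a step-1 sliding window, left to right.

    Returns ``len(sequence) - k + 1`` k-mers; the i-th starts at offset i.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(sequence) < k:
        raise ValidationError(
            f"sequence of length {len(sequence)} is shorter than k={k}"
        )
    return [sequence[i : i + k] for i in range(len(sequence) - k + 1)]


def _record_sequences(
    records: Sequence[SequenceRecord | str],
) -> list[str]:
    return [r.sequence if isinstance(r, SequenceRecord) else r for r in records]


def build_dictionary(
    training_records: Sequence[SequenceRecord | str],
    k: int,
    track_mode: str = "duplex",
    fraction: float = 1.0,
    seed: int | None = None,
    shuffle_ids: bool = False,
) -> KmerDictionary:
    """Build the k-mer ID dictionary from training sequences.

    IDs are assigned from 1 in order of first appearance, scanning records
    in input order and each record left to right; in duplex mode the
    forward strand of a record is scanned before its reverse complement.
    k-mers containing non-ACGT characters never enter the dictionary.

    Parameters
    ----------
    fraction:
        Build the dictionary from a seeded random subsample of the records
        (robustness experiments); 1.0 uses all records.
    shuffle_ids:
        Randomly permute the IDs after collection (seeded).  The default
        keeps the deterministic first-appearance assignment.
    """
    if track_mode not in TRACK_MODES:
        raise ValueError(f"unknown track_mode {track_mode!r}")
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    seqs = _record_sequences(training_records)
    if fraction < 1.0:
        rng = np.random.default_rng(seed)
        n_keep = max(1, int(round(fraction * len(seqs))))
        idx = np.sort(rng.choice(len(seqs), size=n_keep, replace=False))
        seqs = [seqs[i] for i in idx]

    entries: dict[str, int] = {}
    for seq in seqs:
        tracks = [seq] if track_mode == "forward" else [seq, reverse_complement(seq)]
        for track in tracks:
            if len(track) < k:
                continue
            for kmer in extract_kmers(track, k):
                if kmer not in entries and ALPHABET.issuperset(kmer):
                    entries[kmer] = len(entries) + 1
    if not entries:
        raise ValidationError("no valid k-mer found in the training records")

    if shuffle_ids:
        rng = np.random.default_rng(seed)
        perm = rng.permutation(len(entries)) + 1
        entries = {kmer: int(perm[i]) for i, (kmer, _) in enumerate(entries.items())}
    return KmerDictionary(k=k, entries=entries)


def encode(
    record: SequenceRecord | str,
    dictionary: KmerDictionary,
    track_mode: str = "duplex",
) -> np.ndarray:
    """Encode one sequence as a position-ID vector.

    Forward mode yields ``n-k+1`` entries; duplex mode appends the
    reverse-complement strand's positions (5'->3' on that strand), giving
    ``2*(n-k+1)``.  Unknown k-mers encode as 0.
    """
    seq = record.sequence if isinstance(record, SequenceRecord) else record
    k = dictionary.k
    ids = [dictionary.lookup(kmer) for kmer in extract_kmers(seq, k)]
    if track_mode == "duplex":
        rc = reverse_complement(seq)
        ids += [dictionary.lookup(kmer) for kmer in extract_kmers(rc, k)]
    elif track_mode != "forward":
        raise ValueError(f"unknown track_mode {track_mode!r}")
    return np.asarray(ids, dtype=np.int64)


def encode_dataset(
    records: Sequence[SequenceRecord | str],
    dictionary: KmerDictionary,
    track_mode: str = "duplex",
    labels: Sequence[int] | None = None,
    strict_length: bool = True,
) -> EncodedMatrix:
    """Encode a record collection into an :class:`EncodedMatrix`.

    Row order preserves record order.  In strict mode all sequences must
    share one length.
    """
    seqs = _record_sequences(records)
    if strict_length and seqs:
        lengths = {len(s) for s in seqs}
        if len(lengths) > 1:
            raise ValidationError(f"mixed sequence lengths: {sorted(lengths)}")
    n = len(seqs[0]) if seqs else dictionary.k  # declared length for empty input
    n_cols = expected_columns(n, dictionary.k, track_mode)
    if seqs:
        ids = np.stack([encode(s, dictionary, track_mode) for s in seqs])
    else:
        ids = np.empty((0, n_cols), dtype=np.int64)
    lab = None if labels is None else np.asarray(labels, dtype=np.int64)
    return EncodedMatrix(ids=ids, k=dictionary.k, track_mode=track_mode, n=n, labels=lab)
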