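"""Synthetic benchmark generator with planted position-specific signal.

Emulates the shape of the public enhancer benchmark — three classes
(742 strong + 742 weak + 1484 non-enhancers by default), fixed-length
200 bp sequences — while planting a controllable position-specific
k-mer signal: at chosen offsets a short motif overwrites the i.i.d.
background with a per-class probability, so that strong enhancers carry
the motif most often, weak enhancers less often, and non-enhancers
rarely.  The class gradient ``p_strong >= p_weak >= p_background`` makes
the detection task easier than the strength task, mirroring the real
benchmark, and the planted offsets give exact ground truth for the
position-selection stage.

The generator validates the machinery; it does not imitate real enhancer
sequence statistics (GC content, chromatin context).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .seq_io import BenchmarkDataset, SequenceRecord, assemble_dataset
from .seqpose import expected_columns

BASES = np.array(list("ACGT"))


@dataclass
class MotifSpec:
    """A motif planted at fixed offsets with per-class probabilities."""

    positions: tuple[int, ...]
    motif: str
    p_strong: float = 0.9
    p_weak: float = 0.6
    p_background: float = 0.1

    def __post_init__(self) -> None:
        probs = (self.p_strong, self.p_weak, self.p_background)
        if not all(0.0 <= p <= 1.0 for p in probs):
            raise ValueError("planting probabilities must be in [0, 1]")
        if not self.p_strong >= self.p_weak >= self.p_background:
            raise ValueError(
                "expected the class gradient p_strong >= p_weak >= p_background"
            )

    def probability(self, label: str) -> float:
        return {
            "strong_enhancer": self.p_strong,
            "weak_enhancer": self.p_weak,
            "non_enhancer": self.p_background,
        }[label]


def default_motifs(length: int = 200) -> list[MotifSpec]:
    """One 6-bp motif planted at 25% and 60% of the sequence length."""
    return [MotifSpec(positions=(length // 4, (3 * length) // 5), motif="GATAAG")]


@dataclass
class SyntheticConfig:
    """Benchmark-shaped generator settings (counts mirror the public set)."""

    n_strong: int = 742
    n_weak: int = 742
    n_non: int = 1484
    length: int = 200
    motifs: list[MotifSpec] | None = None
    base_composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    seed: int = 75

    def __post_init__(self) -> None:
        if self.motifs is None:
            self.motifs = default_motifs(self.length)
        if min(self.n_strong, self.n_weak, self.n_non) < 0:
            raise ValueError("class counts must be non-negative")
        if abs(sum(self.base_composition) - 1.0) > 1e-9:
            raise ValueError("base_composition must sum to 1")
        for spec in self.motifs:
            for off in spec.positions:
                if off < 0 or off + len(spec.motif) > self.length:
                    raise ValueError(
                        f"motif {spec.motif!r} at offset {off} overflows a "
                        f"{self.length} bp sequence"
                    )


def generate(config: SyntheticConfig) -> BenchmarkDataset:
    """Generate a labelled dataset, fully reproducible from the seed.

    Background bases are i.i.d. from ``base_composition``; each motif
    then overwrites the sequence at each listed offset with the class's
    planting probability (decided independently per record and offset).
    """
    rng = np.random.default_rng(config.seed)
    per_class = {
        "strong_enhancer": config.n_strong,
        "weak_enhancer": config.n_weak,
        "non_enhancer": config.n_non,
    }
    prefix = {"strong_enhancer": "strong", "weak_enhancer": "weak", "non_enhancer": "non"}
    by_class: dict[str, list[SequenceRecord]] = {}
    for label, count in per_class.items():
        records = []
        for i in range(count):
            chars = rng.choice(BASES, size=config.length, p=config.base_composition)
            for spec in config.motifs:
                p = spec.probability(label)
                if p == 0.0:
                    continue  # draw nothing: zero planting == pure background
                for off in spec.positions:
                    if rng.random() < p:
                        chars[off : off + len(spec.motif)] = list(spec.motif)
            records.append(
                SequenceRecord(
                    id=f"{prefix[label]}_{i:05d}",
                    sequence="".join(chars),
                    label=label,
                )
            )
        by_class[label] = records
    return assemble_dataset(
        by_class["strong_enhancer"],
        by_class["weak_enhancer"],
        by_class["non_enhancer"],
        expected_length=config.length,
    )


def planted_truth(
    config: SyntheticConfig, k: int, track_mode: str = "duplex"
) -> set[int]:
    """Encoded-matrix columns whose window overlaps a planted offset.

    A forward-track column i (window [i, i+k-1]) carries signal iff it
    overlaps some planted interval [off, off+len(motif)-1].  In duplex
    mode the reverse-complement track mirrors: forward window
    [i, i+k-1] appears on the second track at column (n-k-i), offset by
    the track boundary n-k+1.
    """
    n = config.length
    n_win = n - k + 1
    columns: set[int] = set()
    for spec in config.motifs:
        for off in spec.positions:
            lo, hi = off, off + len(spec.motif) - 1
            for i in range(n_win):
                if i <= hi and i + k - 1 >= lo:
                    columns.add(i)
                    if track_mode == "duplex":
                        columns.add(n_win + (n - k - i))
    return columns


def write_ground_truth(config: SyntheticConfig, path: str | Path, k: int,
                       track_mode: str = "duplex") -> None:
    """JSON ground-truth sidecar: motif specs, planted columns, seed."""
    payload = {
        "seed": config.seed,
        "length": config.length,
        "k": k,
        "track_mode": track_mode,
        "n_columns": expected_columns(config.length, k, track_mode),
        "motifs": [
            {
                "motif": s.motif,
                "positions": list(s.positions),
                "p_strong": s.p_strong,
                "p_weak": s.p_weak,
                "p_background": s.p_background,
            }
            for s in config.motifs
        ],
        "planted_columns": sorted(planted_truth(config, k, track_mode)),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


def effect_size_curve(
    p_strong_grid: Sequence[float],
    n_per_class: int = 100,
    length: int = 60,
    k: int = 2,
    track_mode: str = "forward",
    n_seeds: int = 20,
    p_background: float = 0.0,
    motif: str = "GATAAG",
    offset: int = 20,
    base_seed: int = 0,
) -> list[dict]:
    """Selection-recovery fraction as a function of planting effect size.

    For each ``p_strong`` value, generates ``n_seeds`` two-class datasets
    (enhancers vs background), scores all positions, and reports the mean
    fraction of planted columns ranked in the informative (small-p) half.
    """
    from .selection import score_all_positions
    from .seq_io import binary_view
    from .seqpose import build_dictionary, encode_dataset

    rows = []
    for p in p_strong_grid:
        fractions = []
        for s in range(n_seeds):
            cfg = SyntheticConfig(
                n_strong=n_per_class,
                n_weak=0,
                n_non=n_per_class,
                length=length,
                motifs=[
                    MotifSpec(
                        positions=(offset,),
                        motif=motif,
                        p_strong=p,
                        p_weak=min(p, p_background),
                        p_background=p_background,
                    )
                ],
                seed=base_seed + 1000 * s + int(round(1e6 * p)) % 997,
            )
            dataset = generate(cfg)
            records, labels = binary_view(dataset, "detection")
            dictionary = build_dictionary(records, k, track_mode=track_mode)
            matrix = encode_dataset(records, dictionary, track_mode, labels=labels)
            table = score_all_positions(matrix)
            planted = planted_truth(cfg, k, track_mode)
            half = set(table.ranking[matrix.n_columns // 2 :].tolist())
            hit = sum(1 for c in planted if c in half)
            fractions.append(hit / len(planted))
        rows.append(
            {
                "p_strong": p,
                "p_background": p_background,
                "recovery": float(np.mean(fractions)),
                "n_seeds": n_seeds,
            }
        )
    return rows
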