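"""Synthetic two-class protein datasets with controllable composition signal.

The generator emulates the statistics of the curated TNF / non-TNF corpus:
18 positives vs 133 negatives, lengths roughly 100-600 residues, with the
positive class carrying (a) an additive residue-frequency shift — by default
elevated K, G, L and I, the residues that separate the real classes — and
(b) planted short motifs (by default the discriminative tripeptides GLY and
FFG) overwritten at random non-overlapping positions. Sequences are i.i.d.
draws over the 20-letter alphabet; no homology or phylogenetic structure is
simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .seqdata import AMINO_ACIDS, POSITIVE, NEGATIVE, LabeledDataset, ProteinSequence

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


@dataclass(frozen=True)
class BiasProfile:
    """Class-dependent signal: frequency shift for positives, planted motifs.

    ``residue_shift`` deltas are added to the positive class's residue
    distribution and must net to zero; ``planted_motifs`` is a list of
    (kmer, insertions per sequence, class label).
    """

    residue_shift: dict[str, float] = field(default_factory=dict)
    planted_motifs: tuple[tuple[str, int, int], ...] = ()
    base_frequencies: tuple[float, ...] = tuple([0.05] * 20)

    def __post_init__(self) -> None:
        base = np.asarray(self.base_frequencies)
        if base.shape != (20,) or not np.isclose(base.sum(), 1.0):
            raise ValueError("base_frequencies must be a 20-length probability vector")
        if self.residue_shift and not np.isclose(sum(self.residue_shift.values()), 0.0):
            raise ValueError("residue_shift deltas must net to zero")
        if np.any(self.positive_frequencies() < 0):
            raise ValueError("shifted positive-class frequencies must stay non-negative")
        for motif, count, label in self.planted_motifs:
            if not motif or any(c not in _AA_INDEX for c in motif) or count < 0:
                raise ValueError(f"invalid planted motif {(motif, count, label)}")

    def positive_frequencies(self) -> np.ndarray:
        freq = np.asarray(self.base_frequencies, dtype=np.float64).copy()
        for res, delta in self.residue_shift.items():
            freq[_AA_INDEX[res]] += delta
        return freq


def default_bias_profile() -> BiasProfile:
    """Uniform base composition; +0.02 on K, G, L, I balanced by -0.005 on the
    sixteen other residues; tripeptides GLY and FFG planted twice per positive."""
    shift = {a: -0.005 for a in AMINO_ACIDS}
    for a in "KGLI":
        shift[a] = 0.02
    return BiasProfile(
        residue_shift=shift,
        planted_motifs=(("GLY", 2, POSITIVE), ("FFG", 2, POSITIVE)),
    )


def null_bias_profile() -> BiasProfile:
    """No class signal at all: both classes share the base composition."""
    return BiasProfile()


@dataclass(frozen=True)
class SynthConfig:
    n_pos: int = 18
    n_neg: int = 133
    length_range: tuple[int, int] = (100, 600)
    bias: BiasProfile = field(default_factory=default_bias_profile)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 0 or self.n_neg < 0:
            raise ValueError("class sizes must be non-negative")
        if self.length_range[0] < 1 or self.length_range[0] > self.length_range[1]:
            raise ValueError(f"invalid length range {self.length_range}")


def _plant(residues: list[str], motifs, label: int, rng: np.random.Generator) -> None:
    """Overwrite motifs at random non-overlapping positions (length preserved)."""
    taken: list[tuple[int, int]] = []
    for motif, count, motif_label in motifs:
        if motif_label != label:
            continue
        for _ in range(count):
            for _attempt in range(200):
                start = int(rng.integers(0, len(residues) - len(motif) + 1))
                span = (start, start + len(motif))
                if all(span[1] <= a or span[0] >= b for a, b in taken):
                    taken.append(span)
                    residues[span[0] : span[1]] = list(motif)
                    break
            else:
                raise RuntimeError(f"could not place motif {motif!r}; sequence too short?")


def generate_dataset(config: SynthConfig = SynthConfig()) -> LabeledDataset:
    """Draw the configured numbers of positive and negative sequences.

    Residues are i.i.d. from the class-specific frequency vector; motifs are
    then planted for the designated class. Fully reproducible by seed, and
    every emitted sequence passes alphabet validation by construction.
    """
    rng = np.random.default_rng(config.seed)
    alphabet = np.array(list(AMINO_ACIDS))
    base = np.asarray(config.bias.base_frequencies, dtype=np.float64)
    pos_freq = config.bias.positive_frequencies()
    lo, hi = config.length_range

    records: list[ProteinSequence] = []
    for label, n, freq, prefix in (
        (POSITIVE, config.n_pos, pos_freq, "TNF"),
        (NEGATIVE, config.n_neg, base, "CYT"),
    ):
        for i in range(n):
            length = int(rng.integers(lo, hi + 1))
            residues = list(rng.choice(alphabet, size=length, p=freq))
            _plant(residues, config.bias.planted_motifs, label, rng)
            records.append(ProteinSequence(f"{prefix}_{i:03d}", "".join(residues), label))
    return LabeledDataset(records)


def write_dataset(data: LabeledDataset, fasta_path: str | Path, labels_path: str | Path,
                  width: int = 60) -> None:
    """Standard wrapped FASTA plus an (id, label) TSV."""
    fasta_lines = []
    label_lines = ["id\tlabel"]
    for rec in data.records:
        fasta_lines.append(f">{rec.id}")
        fasta_lines.extend(rec.residues[i : i + width] for i in range(0, len(rec), width))
        label_lines.append(f"{rec.id}\t{rec.label}")
    Path(fasta_path).write_text("\n".join(fasta_lines) + "\n")
    Path(labels_path).write_text("\n".join(label_lines) + "\n")
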