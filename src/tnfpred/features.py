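"""Feature assembly: count-weighted embedding vectors and classical baselines.

The embedding-based representation fixes an ordered vocabulary L of v
training-corpus words; a sequence's feature vector has one coordinate per
word, equal to (occurrences of that word in the sequence's n-gram
segmentation) x (the word's embedding scalar), zero when absent. Vectors for
different gram sizes can be concatenated, so e.g. 2-g (v=398) + 3-g (v=1915)
gives a 2313-dimensional hybrid.

Baselines: amino-acid composition (AAC, 20 frequencies), dipeptide
composition (DPC, 400 frequencies), and a fixed-length transform of
PSI-BLAST PSSM profiles.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .embedding import EmbeddingModel, model_vocabulary
from .seqdata import AMINO_ACIDS
from .tokenize import segment


@dataclass(frozen=True)
class Vocabulary:
    """The ordered list L of v words fixing feature-vector coordinates."""

    words: tuple[str, ...]
    n: int  # gram size the words were segmented at

    @property
    def v(self) -> int:
        return len(self.words)

    def index_of(self, word: str) -> int:
        return self.words.index(word)

    @classmethod
    def from_model(cls, model: EmbeddingModel, n: int) -> "Vocabulary":
        return cls(tuple(model_vocabulary(model)), n)


@dataclass(frozen=True)
class FeatureVector:
    coords: tuple[float, ...]
    gram_sizes: tuple[int, ...]

    def __len__(self) -> int:
        return len(self.coords)


def embed_sequence(
    residues: str, n: int, vocab: Vocabulary, model: EmbeddingModel
) -> FeatureVector:
    """Count-weighted embedding vector of one sequence at gram size ``n``.

    Coordinate i = (occurrences of word i among the sequence's stride-1
    n-grams) x (embedding scalar of word i). Words absent from the sequence
    contribute 0; sequence words outside the vocabulary contribute nothing.
    A sequence shorter than ``n`` yields the all-zero vector.
    """
    if vocab.n != n:
        raise ValueError(f"vocabulary gram size {vocab.n} != requested {n}")
    occurrences = Counter(segment(residues, n).tokens)
    coords = tuple(
        float(occurrences[w]) * model.vectors[w] if w in occurrences else 0.0
        for w in vocab.words
    )
    return FeatureVector(coords, (n,))


def combine_grams(vectors: Sequence[FeatureVector]) -> FeatureVector:
    """Concatenate per-gram vectors of one sequence in ascending gram order."""
    grams = [g for v in vectors for g in v.gram_sizes]
    if len(set(grams)) != len(grams):
        raise ValueError(f"duplicate gram sizes in combination: {sorted(grams)}")
    ordered = sorted(vectors, key=lambda v: v.gram_sizes[0])
    coords = tuple(x for v in ordered for x in v.coords)
    return FeatureVector(coords, tuple(g for v in ordered for g in v.gram_sizes))


def feature_matrix(
    sequences: Sequence, grams: Sequence[int], vocabs: dict[int, Vocabulary],
    models: dict[int, EmbeddingModel],
) -> np.ndarray:
    """Sequence-major matrix of (possibly combined) embedding features."""
    rows = []
    for seq in sequences:
        per_gram = [embed_sequence(seq.residues, g, vocabs[g], models[g]) for g in grams]
        rows.append(combine_grams(per_gram).coords if len(per_gram) > 1 else per_gram[0].coords)
    return np.array(rows, dtype=np.float64)


def column_manifest(grams: Sequence[int], vocabs: dict[int, Vocabulary]) -> list[str]:
    """Per-column "gram:word" labels, matching feature_matrix's layout."""
    return [f"{g}:{w}" for g in sorted(grams) for w in vocabs[g].words]


def write_feature_matrix(
    matrix: np.ndarray, ids: Sequence[str], manifest: Sequence[str], path: str | Path
) -> None:
    """TSV with a header manifest line; rows are id + feature values."""
    lines = ["id\t" + "\t".join(manifest)]
    for seq_id, row in zip(ids, matrix):
        lines.append(seq_id + "\t" + "\t".join(repr(x) for x in row))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Classical baselines
# ---------------------------------------------------------------------------

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
DIPEPTIDES = tuple(a + b for a in AMINO_ACIDS for b in AMINO_ACIDS)
_DP_INDEX = {d: i for i, d in enumerate(DIPEPTIDES)}


def aac(residues: str) -> np.ndarray:
    """Amino-acid composition: 20 frequencies in fixed alphabetical order."""
    if not residues:
        raise ValueError("empty sequence")
    out = np.zeros(20)
    for r in residues:
        out[_AA_INDEX[r]] += 1
    return out / len(residues)


def dpc(residues: str) -> np.ndarray:
    """Dipeptide composition: 400 stride-1 pair frequencies (AA, AC, ..., YY)."""
    if len(residues) < 2:
        raise ValueError("sequence must have length >= 2 for dipeptide composition")
    out = np.zeros(400)
    for i in range(len(residues) - 1):
        out[_DP_INDEX[residues[i : i + 2]]] += 1
    return out / (len(residues) - 1)


@dataclass(frozen=True)
class PssmProfile:
    sequence_id: str
    sequence: str  # per-position residues, from the profile's second column
    matrix: np.ndarray  # (length, 20) log-odds scores
    column_order: tuple[str, ...]  # residue order of the 20 score columns


def read_pssm(path: str | Path, sequence_id: str | None = None) -> PssmProfile:
    """Parse a PSI-BLAST ASCII PSSM (the -out_ascii_pssm format).

    Only the first 20 score columns (log-odds) are used. Raises with the line
    number on malformed rows.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    header_idx = None
    for i, line in enumerate(lines):
        parts = line.split()
        if len(parts) >= 40 and all(p in _AA_INDEX for p in parts[:20]):
            header_idx = i
            break
        if len(parts) == 20 and all(p in _AA_INDEX for p in parts):
            header_idx = i
            break
    if header_idx is None:
        raise ValueError(f"{path}: no PSSM residue-column header found")
    column_order = tuple(lines[header_idx].split()[:20])

    seq_chars: list[str] = []
    rows: list[list[int]] = []
    expected_pos = 1
    for lineno, line in enumerate(lines[header_idx + 1 :], start=header_idx + 2):
        parts = line.split()
        if not parts:
            break  # blank line terminates the matrix block
        if not parts[0].isdigit():
            break  # trailer (Lambda/K statistics)
        if int(parts[0]) != expected_pos or len(parts) < 22:
            raise ValueError(f"{path}:{lineno}: malformed PSSM row")
        try:
            scores = [int(x) for x in parts[2:22]]
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-integer score") from exc
        seq_chars.append(parts[1])
        rows.append(scores)
        expected_pos += 1
    if not rows:
        raise ValueError(f"{path}: empty PSSM matrix")
    return PssmProfile(
        sequence_id or path.stem, "".join(seq_chars), np.array(rows, dtype=np.float64),
        column_order,
    )


def pssm_features(profile: PssmProfile) -> np.ndarray:
    """400-dimensional residue-pair PSSM composition.

    For each ordered residue pair (a, b): the mean, over positions whose
    sequence residue is a, of the sigmoid-squashed score in column b; zero
    when residue a does not occur. Averaging per residue makes the features
    independent of sequence length (duplicating the sequence leaves them
    unchanged).
    """
    squashed = 1.0 / (1.0 + np.exp(-profile.matrix))  # (L, 20)
    # reorder columns into fixed alphabetical order
    col_perm = [profile.column_order.index(a) for a in AMINO_ACIDS]
    squashed = squashed[:, col_perm]
    out = np.zeros((20, 20))
    counts = np.zeros(20)
    for pos, res in enumerate(profile.sequence):
        i = _AA_INDEX.get(res)
        if i is None:
            continue  # non-canonical residue in profile; skipped
        out[i] += squashed[pos]
        counts[i] += 1
    nz = counts > 0
    out[nz] /= counts[nz, None]
    return out.reshape(400)
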