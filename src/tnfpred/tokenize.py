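"""Segmentation of protein sequences into overlapping n-gram "protein sentences".

A sequence of length ``M`` yields ``max(0, M - n + 1)`` biological words at
stride 1, e.g. ``QIGEF`` with n=3 gives ``QIG, IGE, GEF``. During embedding
training each word is additionally decomposed into boundary-marked character
n-grams ("<QI", "QIG", ..., "EF>") plus the whole-word token "<QIGEF>", so
that words sharing substrings share parameters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .seqdata import ProteinSequence

logger = logging.getLogger("tnfpred")


@dataclass(frozen=True)
class ProteinSentence:
    source_id: str
    n: int
    tokens: tuple[str, ...]


@dataclass(frozen=True)
class Corpus:
    """All protein sentences of one gram size, built from training data only."""

    sentences: tuple[ProteinSentence, ...]
    n: int

    def __len__(self) -> int:
        return len(self.sentences)


def segment(residues: str, n: int, source_id: str = "") -> ProteinSentence:
    """Cut a residue string into consecutive length-``n`` windows at stride 1.

    Sequences shorter than ``n`` give an empty token list (and, downstream, a
    zero feature vector).
    """
    if n < 1:
        raise ValueError(f"gram size must be >= 1, got {n}")
    tokens = tuple(residues[i : i + n] for i in range(len(residues) - n + 1))
    return ProteinSentence(source_id, n, tokens)


def subword_ngrams(word: str, n_min: int, n_max: int) -> list[str]:
    """Character n-grams of "<word>" with lengths in [n_min, n_max], plus the
    boundary-marked whole word appended once (deduplicated against interior
    n-grams of the same length).
    """
    if not word:
        raise ValueError("word must be non-empty")
    if n_min > n_max:
        raise ValueError(f"n_min={n_min} > n_max={n_max}")
    wrapped = f"<{word}>"
    grams = [
        wrapped[i : i + size]
        for size in range(n_min, n_max + 1)
        for i in range(len(wrapped) - size + 1)
        if wrapped[i : i + size] != wrapped
    ]
    grams.append(wrapped)
    return grams


def build_corpus(sequences: Sequence[ProteinSequence], n: int) -> Corpus:
    """One sentence per sequence, order-preserving.

    Sequences shorter than ``n`` contribute an empty sentence with a warning.
    """
    sentences = []
    for seq in sequences:
        sent = segment(seq.residues, n, seq.id)
        if not sent.tokens:
            logger.warning("%s: length %d < gram size %d, empty sentence", seq.id, len(seq), n)
        sentences.append(sent)
    if not sequences:
        logger.warning("building corpus from an empty sequence list")
    return Corpus(tuple(sentences), n)


def write_corpus(corpus: Corpus, path: str | Path) -> None:
    """Dump sentences one per line, tokens space-separated (plain-text corpus)."""
    Path(path).write_text("\n".join(" ".join(s.tokens) for s in corpus.sentences) + "\n")
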