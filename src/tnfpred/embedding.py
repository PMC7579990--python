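"""Subword-aware skip-gram word embeddings of dimension 1 for biological words.

Each admitted corpus word is represented, on the input side, as the mean of
the vectors of its boundary-marked character n-grams (lengths 3..6 by
default) plus a whole-word token; training is skip-gram with negative
sampling (SGNS). The embedding dimension defaults to 1, so every biological
word ends up described by a single real number — the scalar later multiplied
by occurrence counts during feature assembly.

The trainer is a seeded mini-batch SGD implementation: within a batch,
gradient contributions to a shared parameter are accumulated rather than
applied sequentially. Runs are bit-reproducible for a fixed config and corpus
(single numpy RNG, no threading).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import sparse

from .tokenize import Corpus, subword_ngrams

ARCHIVE_FORMAT_VERSION = 1


@dataclass(frozen=True)
class TrainingConfig:
    """Hyperparameters of the subword SGNS trainer.

    Defaults follow the conventional settings of subword embedding tools:
    context window 5, 5 epochs, vocabulary cutoff min_count=5, character
    n-grams 3..6, 5 negative samples, starting learning rate 0.05, and the
    single-scalar embedding dimension used throughout this package.
    """

    dim: int = 1
    window: int = 5
    epochs: int = 5
    min_count: int = 5
    subword_min: int = 3
    subword_max: int = 6
    negative: int = 5
    learning_rate: float = 0.05
    seed: int = 0
    batch_size: int = 4096

    def __post_init__(self) -> None:
        if self.dim < 1:
            raise ValueError("dim must be >= 1")
        if self.min_count < 1:
            raise ValueError("min_count must be >= 1")
        if self.subword_min > self.subword_max:
            raise ValueError("subword_min must be <= subword_max")


@dataclass
class EmbeddingModel:
    """Trained word -> scalar (or length-dim vector) map with its vocabulary."""

    config: TrainingConfig
    vocab_words: list[tuple[str, int]]  # (word, corpus count), admission order
    vectors: dict[str, float | tuple[float, ...]]

    def __contains__(self, word: str) -> bool:
        return word in self.vectors


def _count_words(corpus: Corpus) -> dict[str, int]:
    counts: dict[str, int] = {}
    for sent in corpus.sentences:
        for tok in sent.tokens:
            counts[tok] = counts.get(tok, 0) + 1
    return counts


def _admitted(counts: dict[str, int], min_count: int) -> list[tuple[str, int]]:
    """Vocabulary ordering: descending corpus count, ties lexicographic."""
    return sorted(
        ((w, c) for w, c in counts.items() if c >= min_count),
        key=lambda wc: (-wc[1], wc[0]),
    )


def _epoch_pairs(
    sentence_ids: list[np.ndarray], window: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """(center, context) id pairs with a per-position window drawn from 1..window."""
    centers, contexts = [], []
    for ids in sentence_ids:
        m = ids.size
        if m < 2:
            continue
        b = rng.integers(1, window + 1, size=m)
        for d in range(1, window + 1):
            # center i with context i+d, and center i+d with context i
            ok = np.nonzero(b[: m - d] >= d)[0]
            centers.append(ids[ok])
            contexts.append(ids[ok + d])
            ok2 = np.nonzero(b[d:] >= d)[0] + d
            centers.append(ids[ok2])
            contexts.append(ids[ok2 - d])
    if not centers:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    return np.concatenate(centers), np.concatenate(contexts)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    np.clip(x, -30.0, 30.0, out=out)
    np.exp(-out, out=out)
    out += 1.0
    np.reciprocal(out, out=out)
    return out


def train_embedding(corpus: Corpus, config: TrainingConfig = TrainingConfig()) -> EmbeddingModel:
    """Train subword SGNS embeddings on a protein-word corpus.

    The model vocabulary is exactly the set of distinct corpus words with
    count >= ``config.min_count``. Raises if the corpus is empty or no word
    reaches the cutoff.
    """
    counts = _count_words(corpus)
    if not counts:
        raise ValueError("corpus is empty")
    vocab = _admitted(counts, config.min_count)
    if not vocab:
        raise ValueError(
            f"no word reaches min_count={config.min_count}; lower min_count "
            f"(max observed count is {max(counts.values())})"
        )
    words = [w for w, _ in vocab]
    word_id = {w: i for i, w in enumerate(words)}
    n_vocab = len(words)

    # Exact subword-unit table over the (small) vocabulary: every character
    # n-gram of every admitted word, plus whole-word tokens, gets its own row.
    unit_id: dict[str, int] = {}
    rows, cols, vals = [], [], []
    for i, w in enumerate(words):
        grams = subword_ngrams(w, config.subword_min, config.subword_max)
        for g in grams:
            j = unit_id.setdefault(g, len(unit_id))
            rows.append(i)
            cols.append(j)
            vals.append(1.0 / len(grams))  # input vector = mean of unit vectors
    compose = sparse.csr_matrix(
        (vals, (rows, cols)), shape=(n_vocab, len(unit_id)), dtype=np.float64
    )

    rng = np.random.default_rng(config.seed)
    Z = rng.uniform(-1.0 / config.dim, 1.0 / config.dim, size=(len(unit_id), config.dim))
    O = np.zeros((n_vocab, config.dim))

    # Negative-sampling noise distribution: unigram^0.75.
    freq = np.array([c for _, c in vocab], dtype=np.float64) ** 0.75
    noise = freq / freq.sum()

    sentence_ids = [
        np.array([word_id[t] for t in sent.tokens if t in word_id], dtype=np.int64)
        for sent in corpus.sentences
    ]

    # Total pair count for the linear learning-rate decay, estimated from the
    # first epoch's draw; subsequent epochs redraw windows.
    lr0 = config.learning_rate
    neg = config.negative
    batch = config.batch_size
    all_epoch_pairs = [_epoch_pairs(sentence_ids, config.window, rng) for _ in range(config.epochs)]
    total = sum(c.size for c, _ in all_epoch_pairs)
    if total == 0:
        raise ValueError("corpus yields no skip-gram pairs (sentences too short?)")

    processed = 0
    for centers, contexts in all_epoch_pairs:
        order = rng.permutation(centers.size)
        centers, contexts = centers[order], contexts[order]
        for start in range(0, centers.size, batch):
            c = centers[start : start + batch]
            t_pos = contexts[start : start + batch]
            B = c.size
            lr = lr0 * max(1e-4, 1.0 - processed / total)
            processed += B

            negs = rng.choice(n_vocab, size=(B, neg), p=noise)
            targets = np.concatenate([t_pos[:, None], negs], axis=1)  # (B, 1+neg)
            labels = np.zeros((B, 1 + neg))
            labels[:, 0] = 1.0

            A = compose[c]  # (B, n_units) sparse
            H = A @ Z  # (B, dim)
            Ot = O[targets]  # (B, 1+neg, dim)
            scores = np.einsum("bd,bkd->bk", H, Ot)
            G = _sigmoid(scores) - labels  # (B, 1+neg)

            grad_h = np.einsum("bk,bkd->bd", G, Ot)
            grad_o = G[:, :, None] * H[:, None, :]
            # Per-parameter averaged batch gradient: summing raw contributions
            # overshoots badly when many pairs in a batch touch the same row
            # (inevitable for small vocabularies), so each row's accumulated
            # gradient is divided by its number of contributions.
            flat_t = targets.reshape(-1)
            buf_o = np.zeros_like(O)
            np.add.at(buf_o, flat_t, grad_o.reshape(-1, config.dim))
            hits_o = np.bincount(flat_t, minlength=n_vocab)
            O -= lr * buf_o / np.maximum(hits_o, 1)[:, None]

            buf_z = A.T @ grad_h
            a_bin = A.copy()
            a_bin.data[:] = 1.0
            hits_z = np.asarray(a_bin.sum(axis=0)).ravel()
            Z -= lr * buf_z / np.maximum(hits_z, 1.0)[:, None]

    word_vecs = compose @ Z  # (n_vocab, dim)
    if not np.all(np.isfinite(word_vecs)):
        raise FloatingPointError("non-finite embedding values after training")

    if config.dim == 1:
        vectors = {w: float(word_vecs[i, 0]) for i, w in enumerate(words)}
    else:
        vectors = {w: tuple(float(x) for x in word_vecs[i]) for i, w in enumerate(words)}
    return EmbeddingModel(config, vocab, vectors)


def lookup(model: EmbeddingModel, word: str):
    """Stored scalar for in-vocabulary words; ``None`` marks absence.

    Out-of-vocabulary words contribute nothing downstream (the feature space
    is fixed by the training vocabulary), so absence is a result, not an
    error.
    """
    return model.vectors.get(word)


def model_vocabulary(model: EmbeddingModel) -> list[str]:
    """The ordered word list L fixing feature coordinates (count desc, then lex)."""
    return [w for w, _ in model.vocab_words]


def save_model(model: EmbeddingModel, path: str | Path) -> None:
    """Persist as a plain-text archive: JSON config line + TSV (word, count, values)."""
    lines = [
        json.dumps(
            {"format_version": ARCHIVE_FORMAT_VERSION, "config": asdict(model.config)},
            sort_keys=True,
        )
    ]
    for w, c in model.vocab_words:
        v = model.vectors[w]
        vals = [v] if isinstance(v, float) else list(v)
        lines.append(f"{w}\t{c}\t" + "\t".join(repr(x) for x in vals))
    Path(path).write_text("\n".join(lines) + "\n")


def load_model(path: str | Path) -> EmbeddingModel:
    """Reload a saved model bit-exactly (values round-trip through repr)."""
    lines = Path(path).read_text().splitlines()
    header = json.loads(lines[0])
    if header.get("format_version") != ARCHIVE_FORMAT_VERSION:
        raise ValueError(f"unsupported archive version: {header.get('format_version')}")
    config = TrainingConfig(**header["config"])
    vocab: list[tuple[str, int]] = []
    vectors: dict[str, float | tuple[float, ...]] = {}
    for line in lines[1:]:
        parts = line.split("\t")
        word, count, vals = parts[0], int(parts[1]), [float(x) for x in parts[2:]]
        vocab.append((word, count))
        vectors[word] = vals[0] if config.dim == 1 else tuple(vals)
    return EmbeddingModel(config, vocab, vectors)
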