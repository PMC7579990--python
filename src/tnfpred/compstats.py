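"""Composition statistics: per-class k-mer profiles, F/t-tests, 2-D maps.

These analyses ask whether simple composition separates the two classes:
per-sequence k-mer frequency vectors (k = 1, 2, 3), per-class means and
variances, an F-test for equality of variances, unpaired equal-variance
t-tests per k-mer, and a p-value ranking of the most discriminative k-mers.
No multiple-testing correction is applied (the ranking is exploratory and
exported with a note saying so). A t-SNE driver exports 2-D coordinates of
feature vectors for visualization.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.manifold import TSNE

from .seqdata import AMINO_ACIDS, LabeledDataset

logger = logging.getLogger("tnfpred")


@dataclass
class CompositionTable:
    k: int
    kmers: tuple[str, ...]  # column order
    rows: np.ndarray  # (n_sequences, n_kmers), each row sums to 1
    labels: np.ndarray  # binary, aligned with rows
    ids: tuple[str, ...]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    df: tuple[float, ...]
    test_name: str
    critical_value: float | None = None


def composition_table(data: LabeledDataset, k: int) -> CompositionTable:
    """Per-sequence stride-1 k-mer frequency vectors.

    For k=1 the columns are the fixed 20-residue alphabet; for k=2,3 they are
    the k-mers observed in the dataset (sorted). Sequences shorter than k are
    excluded with a warning.
    """
    if k not in (1, 2, 3):
        raise ValueError(f"k must be 1, 2 or 3, got {k}")
    kept = [r for r in data.records if len(r) >= k]
    for r in data.records:
        if len(r) < k:
            logger.warning("%s: length %d < k=%d, excluded from composition table", r.id, len(r), k)
    if k == 1:
        kmers = tuple(AMINO_ACIDS)
    else:
        observed = set()
        for r in kept:
            observed.update(r.residues[i : i + k] for i in range(len(r) - k + 1))
        kmers = tuple(sorted(observed))
    index = {m: i for i, m in enumerate(kmers)}
    rows = np.zeros((len(kept), len(kmers)))
    for row, r in enumerate(kept):
        n_windows = len(r) - k + 1
        for i in range(n_windows):
            rows[row, index[r.residues[i : i + k]]] += 1
        rows[row] /= n_windows
    return CompositionTable(
        k, kmers, rows, np.array([r.label for r in kept]), tuple(r.id for r in kept)
    )


def class_profiles(table: CompositionTable) -> pd.DataFrame:
    """Per-k-mer class means and (within-class) variances, with the
    positive-minus-negative mean difference for ranking."""
    pos = table.rows[table.labels == 1]
    neg = table.rows[table.labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    df = pd.DataFrame({
        "kmer": table.kmers,
        "pos_mean": pos.mean(axis=0),
        "neg_mean": neg.mean(axis=0),
        "pos_var": pos.var(axis=0, ddof=1),
        "neg_var": neg.var(axis=0, ddof=1),
    })
    df["mean_diff"] = df["pos_mean"] - df["neg_mean"]
    return df


def f_test_equal_variance(x, y, alpha: float = 0.05) -> TestResult:
    """F-test of equal variances, oriented as larger variance over smaller.

    The orientation makes F >= 1, so a single right-tail critical value at
    ``alpha`` supports the "F < F-critical => accept equality" reading; the
    reported p-value is two-sided.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs >= 2 observations")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        raise ValueError("both variances are zero; F undefined")
    if vx >= vy:
        f, dfn, dfd = (vx / vy if vy > 0 else np.inf), x.size - 1, y.size - 1
    else:
        f, dfn, dfd = vy / vx, y.size - 1, x.size - 1
    p = 2.0 * min(stats.f.sf(f, dfn, dfd), stats.f.cdf(f, dfn, dfd))
    crit = stats.f.isf(alpha, dfn, dfd)
    return TestResult(float(f), float(min(p, 1.0)), (dfn, dfd), "F-test (variance ratio)", float(crit))


def unpaired_t_test(x, y, equal_variance: bool = True) -> TestResult:
    """Two-sided unpaired t-test; pooled variance when ``equal_variance``.

    Degenerate case of zero pooled variance: p = 1 for equal means, p = 0 for
    unequal means (the separation limit).
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs >= 2 observations")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        same = x.mean() == y.mean()
        return TestResult(
            0.0 if same else np.inf, 1.0 if same else 0.0,
            (x.size + y.size - 2.0,), "unpaired t-test (degenerate)",
        )
    res = stats.ttest_ind(x, y, equal_var=equal_variance)
    df = x.size + y.size - 2.0 if equal_variance else float(res.df)
    return TestResult(float(res.statistic), float(res.pvalue), (df,),
                      "unpaired t-test" + ("" if equal_variance else " (Welch)"))


def rank_discriminative_kmers(table: CompositionTable, equal_variance: bool = True) -> pd.DataFrame:
    """All k-mers ranked by ascending unpaired t-test p-value.

    Constant columns (zero variance in both classes) are skipped with a note
    column. No multiplicity correction is applied.
    """
    pos = table.rows[table.labels == 1]
    neg = table.rows[table.labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    records = []
    for j, kmer in enumerate(table.kmers):
        x, y = pos[:, j], neg[:, j]
        if x.var(ddof=1) == 0 and y.var(ddof=1) == 0 and x.mean() == y.mean():
            logger.debug("%s: constant column skipped", kmer)
            continue
        t = unpaired_t_test(x, y, equal_variance)
        records.append({
            "kmer": kmer, "pos_mean": x.mean(), "neg_mean": y.mean(),
            "t": t.statistic, "p_value": t.p_value,
        })
    ranked = pd.DataFrame.from_records(records).sort_values(
        ["p_value", "kmer"], kind="mergesort"
    ).reset_index(drop=True)
    return ranked


def project_2d(features: np.ndarray, perplexity: float, seed: int = 0) -> np.ndarray:
    """Seeded t-SNE projection to 2-D (thin driver over a standard implementation)."""
    X = np.asarray(features, dtype=np.float64)
    if perplexity >= X.shape[0]:
        raise ValueError(f"perplexity {perplexity} must be < number of samples {X.shape[0]}")
    if X.shape[0] < 3 * perplexity:
        logger.warning("fewer than 3x perplexity samples; projection may be unstable")
    tsne = TSNE(n_components=2, perplexity=perplexity, random_state=seed, init="pca")
    return tsne.fit_transform(X)


def write_stats_export(ranked: pd.DataFrame, path: str | Path, top: int | None = None) -> None:
    out = ranked.head(top) if top else ranked
    with open(path, "w") as fh:
        fh.write("# unpaired equal-variance t-tests; no multiple-testing correction applied\n")
        out.to_csv(fh, sep="\t", index=False)


def write_projection(coords: np.ndarray, ids, labels, path: str | Path) -> None:
    lines = ["id\tlabel\tx\ty"]
    for i, seq_id in enumerate(ids):
        lines.append(f"{seq_id}\t{labels[i]}\t{coords[i, 0]!r}\t{coords[i, 1]!r}")
    Path(path).write_text("\n".join(lines) + "\n")
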