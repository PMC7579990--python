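"""Metrics and the repeated 5-fold CV + independent-test protocol.

Metrics follow the usual binary-classification definitions with positive =
TNF: Sen = TP/(TP+FN), Spec = TN/(TN+FP), Acc = (TP+TN)/N, and
MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)), with MCC = 0 by
convention when any denominator factor vanishes (all-negative predictions do
occur on folds with few positives). AUC is the area under the ROC curve.

The protocol: for each of R random divisions (default 10), run stratified
5-fold CV on the CV part -- within each fold the embedding vocabulary and
scalars are retrained on the four training folds only, a classifier is tuned
and fit, and the held-out fold is scored; CV metrics are computed on the
pooled held-out predictions. The independent part is scored by a model refit
on the entire CV part. Aggregates are mean +/- sample standard deviation
over runs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.metrics import roc_auc_score

from .embedding import EmbeddingModel, TrainingConfig, train_embedding
from .features import Vocabulary, column_manifest, feature_matrix
from .model import (
    DEFAULT_C_GRID,
    DEFAULT_GAMMA_GRID,
    ClassifierSpec,
    predict_scores,
    train_classifier,
    tune_svm,
)
from .seqdata import LabeledDataset, SplitSpec
from .tokenize import build_corpus

logger = logging.getLogger("tnfpred")


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass(frozen=True)
class MetricSet:
    sensitivity: float
    specificity: float
    accuracy: float
    mcc: float
    auc: float | None = None


def confusion(labels: Sequence[int], predictions: Sequence[int]) -> ConfusionCounts:
    y = np.asarray(labels)
    p = np.asarray(predictions)
    if y.size == 0:
        raise ValueError("empty label vector")
    if y.shape != p.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {p.shape}")
    return ConfusionCounts(
        TP=int(np.sum((y == 1) & (p == 1))),
        TN=int(np.sum((y == 0) & (p == 0))),
        FP=int(np.sum((y == 0) & (p == 1))),
        FN=int(np.sum((y == 1) & (p == 0))),
    )


def metrics_from_counts(c: ConfusionCounts, auc: float | None = None) -> MetricSet:
    tp, tn, fp, fn = c.TP, c.TN, c.FP, c.FN
    sen = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    acc = (tp + tn) / c.total
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / np.sqrt(denom) if denom else 0.0
    return MetricSet(sen, spec, acc, float(mcc), auc)


def roc_auc(labels: Sequence[int], scores: Sequence[float]) -> float:
    """P(random positive outscores random negative), ties counting one half."""
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("AUC requires both classes present")
    return float(roc_auc_score(y, np.asarray(scores, dtype=np.float64)))


# ---------------------------------------------------------------------------
# Pipeline configuration and drivers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PipelineConfig:
    """One experiment cell: feature set x classifier x embedding settings.

    ``grams`` names the embedding feature set ((2, 3) = the 2-g+3-g hybrid).
    ``classifier`` of None means: tune an RBF SVM by inner-CV grid search.
    ``embed_mode`` "per_fold" retrains embeddings inside every CV fold (strict
    no-leakage default); "per_run" trains once per run on the whole CV part.
    """

    grams: tuple[int, ...] = (2, 3)
    embed_config: TrainingConfig = field(default_factory=TrainingConfig)
    classifier: ClassifierSpec | None = None
    c_grid: tuple[float, ...] = DEFAULT_C_GRID
    gamma_grid: tuple[float, ...] = DEFAULT_GAMMA_GRID
    inner_k: int = 3
    embed_mode: str = "per_fold"

    def __post_init__(self) -> None:
        if self.embed_mode not in ("per_fold", "per_run"):
            raise ValueError(f"unknown embed_mode {self.embed_mode!r}")
        if len(set(self.grams)) != len(self.grams):
            raise ValueError("duplicate gram sizes")


def _derived_seed(base: int, salt: int) -> int:
    return (base * 7919 + salt) % (2**31 - 1)


def fit_gram_models(
    train_seqs, grams: Sequence[int], embed_config: TrainingConfig, seed: int
) -> tuple[dict[int, Vocabulary], dict[int, EmbeddingModel]]:
    """Train one embedding model per gram size on the given training sequences."""
    vocabs: dict[int, Vocabulary] = {}
    models: dict[int, EmbeddingModel] = {}
    for g in sorted(grams):
        corpus = build_corpus(train_seqs, g)
        cfg = replace(embed_config, seed=_derived_seed(seed, g))
        models[g] = train_embedding(corpus, cfg)
        vocabs[g] = Vocabulary.from_model(models[g], g)
    return vocabs, models


def _fit_and_score(train_seqs, eval_seqs, config: PipelineConfig, seed: int,
                   vocabs=None, models=None):
    """Featurize, (optionally tune and) train, and score the eval sequences."""
    if vocabs is None:
        vocabs, models = fit_gram_models(train_seqs, config.grams, config.embed_config, seed)
    grams = sorted(config.grams)
    X_train = feature_matrix(train_seqs, grams, vocabs, models)
    X_eval = feature_matrix(eval_seqs, grams, vocabs, models)
    y_train = np.array([s.label for s in train_seqs])
    spec = config.classifier
    if spec is None:
        spec = tune_svm(X_train, y_train, config.c_grid, config.gamma_grid,
                        config.inner_k, seed=_derived_seed(seed, 97))
    manifest = tuple(column_manifest(grams, vocabs))
    model = train_classifier(X_train, y_train, spec, manifest)
    scores, preds = predict_scores(model, X_eval)
    return scores, preds, model, vocabs


def cross_validate(
    data: LabeledDataset, split: SplitSpec, config: PipelineConfig
) -> tuple[MetricSet, dict[str, tuple[float, int]]]:
    """Stratified k-fold CV on the split's CV part.

    Returns pooled-held-out metrics plus the per-sequence (score, prediction)
    map — each CV sequence is scored exactly once.
    """
    scored: dict[str, tuple[float, int]] = {}
    vocabs = models = None
    if config.embed_mode == "per_run":
        cv_seqs = data.subset(split.cv_ids)
        vocabs, models = fit_gram_models(cv_seqs, config.grams, config.embed_config, split.seed)
    for fold in range(split.n_folds):
        held_ids = split.fold_ids(fold)
        train_ids = [i for i in split.cv_ids if split.fold_of[i] != fold]
        train_seqs = data.subset(train_ids)
        held_seqs = data.subset(held_ids)
        if len({s.label for s in held_seqs}) < 2:
            logger.warning("run %d fold %d: held-out fold has a single class", split.run_index, fold)
        scores, preds, _, _ = _fit_and_score(
            train_seqs, held_seqs, config, _derived_seed(split.seed, fold),
            vocabs=vocabs, models=models,
        )
        for seq, sc, pr in zip(held_seqs, scores, preds):
            scored[seq.id] = (float(sc), int(pr))
    labels = [data.by_id(i).label for i in split.cv_ids]
    scores = [scored[i][0] for i in split.cv_ids]
    preds = [scored[i][1] for i in split.cv_ids]
    auc = roc_auc(labels, scores) if len(set(labels)) > 1 else None
    return metrics_from_counts(confusion(labels, preds), auc), scored


def independent_eval(
    data: LabeledDataset, split: SplitSpec, config: PipelineConfig
) -> tuple[MetricSet, object]:
    """Refit on the entire CV part and score the independent part."""
    cv_seqs = data.subset(split.cv_ids)
    ind_seqs = data.subset(split.independent_ids)
    scores, preds, model, _ = _fit_and_score(cv_seqs, ind_seqs, config, split.seed)
    labels = [s.label for s in ind_seqs]
    auc = roc_auc(labels, scores) if len(set(labels)) > 1 else None
    return metrics_from_counts(confusion(labels, preds), auc), model


@dataclass
class RunReport:
    """Per-run and aggregated metrics for one experiment cell."""

    name: str
    cv: list[MetricSet] = field(default_factory=list)
    independent: list[MetricSet] = field(default_factory=list)
    errors: list[str] = field(default_factory=list)

    @staticmethod
    def _agg(values: list[float | None]) -> tuple[float, float]:
        vals = [v for v in values if v is not None]
        if not vals:
            return float("nan"), float("nan")
        mean = float(np.mean(vals))
        sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        return mean, sd

    def aggregate(self, part: str, metric: str) -> tuple[float, float]:
        sets = self.cv if part == "cv" else self.independent
        return self._agg([getattr(m, metric) for m in sets])

    def cell(self, part: str, metric: str, percent: bool = False) -> str:
        m, d = self.aggregate(part, metric)
        scale = 100.0 if percent else 1.0
        return f"{m * scale:.3g} ± {d * scale:.2g}"


def run_protocol(
    data: LabeledDataset,
    splits: Sequence[SplitSpec],
    grid: dict[str, PipelineConfig],
    audit_path: str | Path | None = None,
) -> dict[str, RunReport]:
    """Run every experiment cell over every split; cell failures are recorded,
    not fatal to the grid."""
    if not splits:
        raise ValueError("need at least one split")
    reports = {name: RunReport(name) for name in grid}
    audit_lines = []
    for name, config in grid.items():
        for split in splits:
            try:
                cv_metrics, _ = cross_validate(data, split, config)
                ind_metrics, _ = independent_eval(data, split, config)
            except Exception as exc:  # recorded per spec; grid continues
                msg = f"{name} run {split.run_index}: {exc}"
                logger.error(msg)
                reports[name].errors.append(msg)
                continue
            reports[name].cv.append(cv_metrics)
            reports[name].independent.append(ind_metrics)
            audit_lines.append(json.dumps({
                "cell": name, "run": split.run_index,
                "cv": vars(cv_metrics), "independent": vars(ind_metrics),
            }, sort_keys=True))
    if audit_path is not None:
        Path(audit_path).write_text("\n".join(audit_lines) + "\n")
    return reports


def write_report_table(
    reports: dict[str, RunReport], path: str | Path, note: str | None = None
) -> None:
    """Comparison-table TSV: one row per cell and
    part, Acc/Spec/Sen in percent, MCC and AUC on [0,1], cells as "m ± d"."""
    lines = ["cell\tpart\tAcc(%)\tSpec(%)\tSen(%)\tMCC\tAUC"]
    for name, rep in reports.items():
        for part in ("cv", "independent"):
            lines.append("\t".join([
                name, part,
                rep.cell(part, "accuracy", percent=True),
                rep.cell(part, "specificity", percent=True),
                rep.cell(part, "sensitivity", percent=True),
                rep.cell(part, "mcc"),
                rep.cell(part, "auc"),
            ]))
        for err in rep.errors:
            lines.append(f"# error\t{err}")
    if note:
        lines.append(f"# {note}")
    Path(path).write_text("\n".join(lines) + "\n")
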