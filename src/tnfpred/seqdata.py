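"""Labeled protein sequence datasets and the repeated train/test split design.

The classification task compares a small positive class (TNF family members)
against a larger negative class (other cytokines). Because the curated corpus
is small (tens of positives), every experiment is repeated over several random
divisions into a cross-validation part and an independent test part, holding
the per-label counts fixed across repetitions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO

logger = logging.getLogger("tnfpred")

#: The 20 canonical amino acids, alphabetically.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)

#: Ambiguity / non-standard codes that disqualify a sequence at ingestion.
UNCOMMON_CODES = frozenset("BJOUXZ")

POSITIVE, NEGATIVE = 1, 0


class SequenceRejected(ValueError):
    """Raised (or returned as a record) when a sequence fails validation."""

    def __init__(self, seq_id: str, reason: str, offending: frozenset[str] = frozenset()):
        self.seq_id = seq_id
        self.reason = reason
        self.offending = offending
        super().__init__(f"{seq_id}: {reason}" + (f" (offending={sorted(offending)})" if offending else ""))


@dataclass(frozen=True)
class ProteinSequence:
    """One protein chain with a binary class label (positive = TNF)."""

    id: str
    residues: str
    label: int | None = None

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class LabeledDataset:
    """A list of validated, uniquely-identified protein sequences."""

    records: list[ProteinSequence] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sequence ids: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def by_id(self, seq_id: str) -> ProteinSequence:
        for r in self.records:
            if r.id == seq_id:
                return r
        raise KeyError(seq_id)

    def label_counts(self) -> dict[int, int]:
        counts: dict[int, int] = {}
        for r in self.records:
            counts[r.label] = counts.get(r.label, 0) + 1
        return counts

    def subset(self, ids: Iterable[str]) -> list[ProteinSequence]:
        wanted = set(ids)
        return [r for r in self.records if r.id in wanted]


@dataclass
class SplitSpec:
    """One random division into a CV part (with folds) and an independent part."""

    run_index: int
    seed: int
    cv_ids: list[str]
    independent_ids: list[str]
    fold_of: dict[str, int]

    def fold_ids(self, fold: int) -> list[str]:
        return [i for i in self.cv_ids if self.fold_of[i] == fold]

    @property
    def n_folds(self) -> int:
        return max(self.fold_of.values()) + 1 if self.fold_of else 0


def validate_sequence(seq: ProteinSequence) -> ProteinSequence:
    """Uppercase the residues and accept iff all lie in the 20-letter alphabet.

    Sequences containing ambiguity or non-standard codes (B, J, O, U, X, Z) are
    rejected, mirroring the curation rule of the surveyed dataset.

    Raises
    ------
    SequenceRejected
        If the sequence is empty or contains characters outside the alphabet.
    """
    residues = seq.residues.upper()
    if not residues:
        raise SequenceRejected(seq.id, "empty")
    bad = frozenset(residues) - _AA_SET
    if bad:
        raise SequenceRejected(seq.id, "non-canonical residues", bad)
    return ProteinSequence(seq.id, residues, seq.label)


def read_fasta(path: str | Path, label: int | None = None) -> list[ProteinSequence]:
    """Read a (possibly line-wrapped) FASTA file into unvalidated records.

    The header token before the first whitespace becomes the id; residues are
    uppercased. Duplicate ids raise; an empty file yields an empty list with a
    warning.
    """
    path = Path(path)
    records: list[ProteinSequence] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        seq_id = entry.id
        if seq_id in seen:
            raise ValueError(f"{path}: duplicate FASTA id {seq_id!r}")
        seen.add(seq_id)
        records.append(ProteinSequence(seq_id, str(entry.seq).upper(), label))
    if not records:
        logger.warning("%s: no FASTA records found", path)
    return records


def load_dataset(
    positive_fasta: str | Path,
    negative_fasta: str | Path,
) -> LabeledDataset:
    """Read positive and negative FASTA files, validate, and assemble a dataset.

    Records failing validation are logged and dropped, not fatal.
    """
    kept: list[ProteinSequence] = []
    for path, label in ((positive_fasta, POSITIVE), (negative_fasta, NEGATIVE)):
        for rec in read_fasta(path, label):
            try:
                kept.append(validate_sequence(rec))
            except SequenceRejected as exc:
                logger.warning("rejected %s", exc)
    return LabeledDataset(kept)


def load_dataset_with_labels(fasta: str | Path, labels_tsv: str | Path) -> LabeledDataset:
    """Read one FASTA plus a two-column (id, label) TSV written by the generator."""
    label_of: dict[str, int] = {}
    for line in Path(labels_tsv).read_text().splitlines():
        if not line or line.startswith("id\t"):
            continue
        seq_id, lab = line.split("\t")
        label_of[seq_id] = int(lab)
    kept = []
    for rec in read_fasta(fasta):
        try:
            kept.append(validate_sequence(ProteinSequence(rec.id, rec.residues, label_of[rec.id])))
        except SequenceRejected as exc:
            logger.warning("rejected %s", exc)
    return LabeledDataset(kept)


DesignCounts = Mapping[int, tuple[int, int]]

#: Default split design: per label, (CV count, independent count).
DEFAULT_DESIGN: DesignCounts = {POSITIVE: (14, 4), NEGATIVE: (103, 30)}


def stratified_folds(
    ids_by_label: Mapping[int, Sequence[str]], k: int, seed: int
) -> dict[str, int]:
    """Assign label-stratified folds 0..k-1; per-label sizes differ by <= 1."""
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    rng = np.random.default_rng(seed)
    fold_of: dict[str, int] = {}
    for label in sorted(ids_by_label):
        ids = list(ids_by_label[label])
        if len(ids) < k:
            logger.warning("label %s has %d < k=%d members in the CV part", label, len(ids), k)
        order = rng.permutation(len(ids))
        for pos, idx in enumerate(order):
            fold_of[ids[idx]] = pos % k
    return fold_of


def make_splits(
    data: LabeledDataset,
    n_runs: int = 10,
    design: DesignCounts = DEFAULT_DESIGN,
    base_seed: int = 0,
    k_folds: int = 5,
) -> list[SplitSpec]:
    """Draw ``n_runs`` independent CV/independent divisions with fixed counts.

    Each run uses the derived seed ``base_seed + run_index`` so identical
    inputs reproduce identical splits. The per-label design counts must sum to
    the per-label totals in ``data``.
    """
    totals = data.label_counts()
    for label, (n_cv, n_ind) in design.items():
        have = totals.get(label, 0)
        if n_cv + n_ind != have:
            raise ValueError(
                f"design for label {label} is ({n_cv},{n_ind}) but dataset has {have} records"
            )
        if n_ind == 0:
            logger.warning("label %s has an empty independent part", label)

    splits: list[SplitSpec] = []
    for run in range(n_runs):
        seed = base_seed + run
        rng = np.random.default_rng(seed)
        cv_by_label: dict[int, list[str]] = {}
        independent: list[str] = []
        for label in sorted(design):
            ids = sorted(r.id for r in data.records if r.label == label)
            order = rng.permutation(len(ids))
            n_cv = design[label][0]
            cv_by_label[label] = [ids[i] for i in order[:n_cv]]
            independent.extend(ids[i] for i in order[n_cv:])
        fold_of = stratified_folds(cv_by_label, k_folds, seed)
        cv_ids = [i for label in sorted(cv_by_label) for i in cv_by_label[label]]
        splits.append(SplitSpec(run, seed, cv_ids, independent, fold_of))
    return splits


def write_split_manifest(splits: Sequence[SplitSpec], data: LabeledDataset, path: str | Path) -> None:
    """Write splits as TSV: run_index, id, label, part, fold (-1 = independent)."""
    lines = ["run_index\tid\tlabel\tpart\tfold"]
    for s in splits:
        for seq_id in s.cv_ids:
            lines.append(f"{s.run_index}\t{seq_id}\t{data.by_id(seq_id).label}\tcv\t{s.fold_of[seq_id]}")
        for seq_id in s.independent_ids:
            lines.append(f"{s.run_index}\t{seq_id}\t{data.by_id(seq_id).label}\tindependent\t-1")
    Path(path).write_text("\n".join(lines) + "\n")
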