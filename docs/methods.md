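# Methods

## Problem and model

The task is binary classification of cytokine sequences: tumor necrosis
factors (positive) versus all other cytokine families (negative). A sequence
is treated as a sentence of overlapping biological words — its length-*n*
substrings at stride 1 — and represented by a count-weighted bag-of-words
vector over the training vocabulary, with per-word weights learned by an
unsupervised subword embedding of dimension 1.

Formally, let *L* = (w₁ … w_v) be the ordered vocabulary and e: L → ℝ the
trained scalar embedding. Sequence *s* with word-occurrence counts m_i(s)
maps to x(s) = (m₁(s)·e(w₁), …, m_v(s)·e(w_v)). Feature sets for several
gram sizes are concatenated in ascending gram order; dimensions add.

## Tokenization

Stride is fixed at 1 (windows overlap maximally); it is configurable in
principle but no other stride is used anywhere. Sequences shorter than *n*
yield an empty sentence (warning) and hence an all-zero feature vector.
During embedding training each word is decomposed into the character
n-grams (lengths 3–6) of `<word>` plus the whole-word token `<word>`
appended once; for a single-letter word the whole-word token `<A>` is
itself the only length-3 item and appears exactly once.

## Embedding trainer

The trainer is an in-package implementation of skip-gram with negative
sampling over subword units, written for the dim=1 regime this pipeline
uses (dim ≥ 2 is supported but non-default):

- **Vocabulary**: distinct corpus words with count ≥ `min_count` (default
  5), ordered by descending count with lexicographic tie-break. This
  ordering fixes feature coordinates; classifier results are invariant to
  it, only reproducibility depends on it. Out-of-vocabulary words are
  dropped from sentences before windowing and contribute no feature
  coordinate.
- **Inputs**: a word's input vector is the mean of its subword-unit vectors
  (exact table, no hashing — vocabularies here are small). Units initialize
  uniform on (−1/dim, 1/dim); output vectors start at zero.
- **Objective**: for each (center, context) pair, logistic loss against 1
  positive and `negative` = 5 noise words drawn from the unigram^0.75
  distribution. Context width per position is drawn uniformly from
  1..`window` (default 5). Epochs default 5, starting learning rate 0.05
  with linear decay to (nearly) zero over all pairs.
- **Optimization**: mini-batch SGD (batch 4096) with *per-parameter
  averaged* gradients: within a batch, the accumulated gradient of each
  parameter row is divided by the number of contributions to that row.
  With large vocabularies collisions are rare and this equals plain SGD;
  with tiny vocabularies (e.g. 20 unigrams) summed collisions would
  diverge, and averaging keeps updates bounded. No frequent-word
  subsampling is applied — k-mer corpora have no analogue of stop-word
  skew at these sizes.
- **Determinism**: one numpy generator seeded from the config; identical
  corpus + config reproduce bit-identical scalars. Training rejects
  corpora where no word reaches `min_count` and fails loudly on non-finite
  values.

## Feature assembly and baselines

Occurrence counts use the same stride-1 segmentation as tokenization.
Feature matrices carry a column manifest (`gram:word`) so experiments are
auditable; combined sets check for duplicate gram sizes.

Baselines: AAC (20 residue frequencies), DPC (400 stride-1 dipeptide
frequencies), both probability vectors; and a PSSM transform for
PSI-BLAST ASCII profiles. The PSSM transform is not standardized in the
literature we follow, so this package uses a 400-dimensional residue-pair
composition: entry (a, b) is the mean over positions carrying residue a of
the sigmoid-squashed log-odds score in column b, zero when a is absent.
Per-residue averaging (rather than division by sequence length) makes the
features exactly invariant under sequence duplication, which is the
property the transform needs; it is documented and swappable. Profile
generation by PSI-BLAST is out of scope — profiles are inputs.

## Classifiers

- **SVM (primary)**: RBF kernel behind a per-feature standardizer fit on
  training data only. Count-weighted coordinates span orders of magnitude
  (counts scale with sequence length), and an unstandardized RBF distance
  is dominated by length variance; standardization is the package's choice
  and can be disabled (`standardize: False`). Hyperparameters are
  grid-searched over C ∈ 2⁻⁵..2¹⁵ and γ ∈ 2⁻¹⁵..2³ (×4 steps) by mean
  inner-CV (k = 3) AUC, ties broken toward smaller C then smaller γ. AUC
  scores use the signed decision value, not calibrated probabilities.
- **Others**: kNN (k = 5), random forest (100 trees), Gaussian naive
  Bayes, and an RBF network (all training points as centers, width
  defaulting to 1/(d·Var(X)), ridge-regularized least-squares output
  weights against ±1 targets). The RBF network is a generic stand-in for
  the published QuickRBF binary and is labeled as such in report output.
- No class weighting by default despite the 14:103 imbalance (exposed as a
  hyperparameter); the consequence — degenerate all-negative thresholds on
  weakly separable folds — is expected and handled by the MCC = 0
  convention.

## Evaluation protocol

Splits are drawn by per-label counts, default (14 CV / 4 independent)
positives and (103 / 30) negatives, with derived per-run seeds
`base_seed + run`. Folds are label-stratified, sizes differing by ≤ 1.
Within each CV fold the embedding (and hence the feature space) is
retrained on the four training folds only — the strict no-leakage reading;
a `per_run` mode that trains once per run on the whole CV part is
available. CV metrics are computed on the pooled held-out predictions; the
independent part is scored by a model refit on the entire CV part with
freshly tuned hyperparameters (no fold ensembling). Aggregates use the
sample (n−1) standard deviation. Degenerate MCC denominators are reported
as 0; AUC is the pairwise-concordance probability with ties counting ½.

## Composition statistics

Per-sequence k-mer frequency tables (k = 1, 2, 3; rows are probability
vectors) feed: per-class means and within-class variances; an F-test of
variance equality oriented larger/smaller so F ≥ 1 and a single right-tail
critical value (α = 0.05) applies; and per-k-mer unpaired t-tests, pooled
variance by default. No multiple-testing correction is applied — the
ranking is exploratory, and exports carry a notice line. Zero-variance
degeneracies: equal means give p = 1, unequal give p = 0 (separation
limit); columns constant in both classes are skipped. The 2-D maps are a
thin seeded driver over a standard t-SNE implementation (perplexities 25
and 50 in the workflows), not a re-implementation.

## Synthetic data generator

The generator emulates the curated corpus's statistics: 18 positive vs 133
negative sequences, lengths uniform on 100–600. The default signal has two
parts, both motivated by the composition analyses the pipeline is meant to
recover: (a) a residue-frequency shift of +0.02 on K, G, L, I in the
positive class, balanced by −0.005 on the sixteen other residues over a
uniform (0.05) base; (b) the tripeptides GLY and FFG overwritten twice per
positive sequence at random non-overlapping positions (overwriting keeps
lengths intact). Residues are otherwise i.i.d.; the generator does not
simulate homology, domain structure, or phylogenetic correlation, so
passing tests demonstrate signal recovery under independence, not
performance on real protein families. A null profile (no shift, no motifs)
provides the chance-level control.

Under the default signal the tuned SVM on 2-g+3-g features reaches pooled
CV AUC ≥ 0.95 per run, while accuracy can sit at the majority rate with
sensitivity 0: the planted signal concentrates in a few coordinates, and
the unweighted SVM threshold stays conservative at 14 positives. Run-to-run
AUC spread is wide (≈0.7–1.0 across divisions) for the same reason — few
positives per split — mirroring the high between-run variance the protocol
is designed to expose.

## Problem sizes used in checks

The shipped end-to-end checks run the generator at its default 151-sequence
conditions for signal-recovery and protocol results (1 division for the
recovery check, 5 single-division seeds for the null control, 10 divisions
in `scripts/acceptance.py`), and a reduced 32-sequence configuration for
pipeline-mechanics checks (determinism, bookkeeping) where effect sizes are
irrelevant. Evaluation on the original curated corpus requires placing it
under `data/` as described in the README.

## Known limitations

- Embedding quality at dim 1 is intentionally crude; the scalar mostly
  encodes frequency/context polarity, and the discriminative power lives
  in the occurrence counts it weights.
- The vocabulary-size accounting on synthetic data differs from a natural
  corpus's (uniform residue usage admits more k-mers at the same
  `min_count`), so vocabulary figures are diagnostics, not targets, unless
  computed on the curated corpus.
- t-SNE layouts are seed-dependent and only qualitatively comparable.
- PSSM baseline features require externally generated profiles.
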