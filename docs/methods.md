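# Methods

## The model

The encoder follows the standard transformer recipe: a lexicon encoder
(token embedding + segment embedding for sentence 1/2 + learned position
embedding) followed by L blocks of multi-head self-attention and a
GELU feed-forward layer, each with residual connection and layer
normalization. All task heads consume the same contextual embeddings:
pooled predictions (similarity score, sentence or pair classification)
read h_[CLS], the embedding of the leading classification marker; token
classification reads h_[1:n] position-wise. Head objectives are mean
squared error for the similarity regression and cross-entropy for the
three classification head types.

The architecture is shape-faithful but size-configurable. Full-scale
systems initialize the shared layers from a pretrained BERT-class
checkpoint; here initialization is either seeded-random or a checkpoint
archive written by this package (`ModelState.save`/`load`). The
desk-scale default is 2 layers × width 64 (the benchmark experiments use
1 × 32); nothing in the contracts depends on scale.

The network is implemented in numpy over a small reverse-mode autodiff
core (`clinsts.autodiff`). Correctness rests on central-finite-difference
checks: analytic gradients of all four objectives, taken through the full
encoder, agree with numeric ones within 1e-4 relative error in the test
suite (typical agreement is ~1e-8).

Assumptions worth stating: attention masks exclude padding; special
markers and padding are excluded from the token-classification loss;
similarity scores are *not* squashed at prediction time — the head emits
an unbounded real, and clipping to [0,5] happens only at
evaluation/ensembling, where the label scale applies.

## Multi-task training

One epoch: each selected dataset is partitioned (seeded shuffle) into
mini-batches of the *same* batch size, so the number of batches a
dataset contributes is proportional to its size; remainder examples form
a final short batch (nothing is dropped — the suite asserts per-epoch
conservation). All batches merge into one schedule, shuffled by the same
seed stream, reshuffled every epoch with a per-epoch derived seed. Each
batch is homogeneous in task; only its task's objective is computed and
only the shared parameters plus that task's head are updated.

The literal update θ ← θ − η∇θ is available as the `sgd` optimizer and
is what the one-step oracle test pins; the default is an
adaptive-moment variant (lr 5e-3, β=0.9/0.999), which at these widths
converges an order of magnitude faster. Gradient-norm clipping (default
1.0) guards the early epochs. Fine-tuning is the same loop degenerated
to the single target dataset: shared layers plus the pair-similarity
head move, all other heads are untouched (asserted bit-exactly).

Iteration plans are executed, not discovered: the runner re-initializes
every plan from the same base state, trains on its dataset set, fine-
tunes, and scores the validation split; the best plan is the argmax with
ties to the lowest iteration index. Error-analysis-driven selection of
the next plan is a human step by design.

## Dataset construction conventions

The candidate-pair filter averages three surface similarities and keeps
pairs at mean ≥ 0.45. The individual metrics require conventions the
published description leaves open; the ones adopted here are:

- **Levenshtein similarity** = 1 − d(a,b)/max(|a|,|b|) (an average of
  *similarities* needs a [0,1] quantity; max-length normalization is the
  standard choice). Distance is computed by `edlib`; a DP implementation
  is the independent oracle in tests.
- **Cosine** over lowercase word-token raw counts, no idf.
- **Ratcliff/Obershelp** = 2M/(|a|+|b|) via `difflib` with autojunk
  disabled, symmetrized as the max over both argument orders (the raw
  matching-blocks recursion breaks ties asymmetrically).
- All three lowercase their inputs.

Under these conventions the first printed sample pair of the clinical
STS dataset scores a mean of ≈0.557, comfortably above the bound —
`scripts/acceptance.py` recomputes this.

Gold scores are the element-wise mean of two annotators' 0–5 scores.
The three-way split shuffles with a seed and partitions contiguously
with largest-remainder rounding; at the published fractions
(75.03/14.98/9.99%) on 1642 pairs this yields exactly 1232/246/164.

## Ensembling

"Normalized" outputs are min–max mapped onto [0,5] per prediction set
(z-scoring was the alternative; min–max keeps everything on the label
scale). A constant set cannot be normalized and passes through with a
flag. The mean ensemble itself is a plain per-id arithmetic mean of
already-normalized sets — normalization is a separate, visible step.
Stackers are least squares, ridge (λ default 1.0), and Bayesian ridge at
scikit-learn's conventional hyperpriors; the stacker is fit on
validation-split predictions, never on target-test gold. Final scores
clip to [0,5]. Rank-deficient designs are rejected under plain least
squares with a pointer to ridge; the pipeline additionally drops
zero-variance feature columns before fitting (on synthetic corpora the
medication features are all-zero, since the generated sentences contain
no lexicon drugs). Random-forest/boosting stackers are deliberately out:
they underperformed linear stacking in this setting.

The medication extractor is a transparent stand-in with the same
attribute schema as full clinical medication-extraction systems:
case-insensitive longest-match-first lexicon matching plus regex rules
for strength ("90 mcg"), dosage ("1-2 puffs"), form, route ("by mouth" →
mouth), frequency ("every 4 hours"), duration. Name overlap is Jaccard
over drug-name component tokens, so a combination product partially
overlaps its single agent.

## Evaluation

PCC is the headline metric (scipy, pinned to the textbook formula at
1e-12 in tests); degenerate inputs raise rather than return NaN.
Interval F1 bins gold and (first clipped) predictions into [0,1), [1,2),
[2,3), [3,4), [4,5] — half-open except the last, so 5.0 lands in [4,5] —
with TP requiring interval agreement, FP charged to the predicted
interval and FN to the gold interval. An interval empty on both sides
has *undefined* F1, reported as `None` rather than 0, so macro summaries
are not silently distorted. Range-restricted PCC filters by gold-score
membership; the default ranges contrast the extremes [0,2)∪[4,5] with
the middle [2,4).

## The synthetic benchmark

What it emulates: small scored target data built from high-lexical-
overlap pairs; a two-annotator gold protocol with disagreement noise; a
family of related auxiliary tasks (general-domain similarity regression,
entailment-style pair classification with an antonym-built contradiction
class, topic classification with disjoint keyword pools, medication-
style token tagging) sharing vocabulary and latent structure with the
target; and one pair task whose labels are coin flips.

Mechanics: a template draws m ∈ [6,10] content slots; the paired variant
applies e ∈ {0..m} edits (synonym swap from a generated synonym table,
deletion, substitution, insertion), so latent similarity is exactly
5·(m−e)/m; each simulated annotator adds truncated Gaussian noise
(σ = 0.25 by default) and the gold score is their mean. The
transfer-coupling knob (default 0.7) sets the fraction of auxiliary
content vocabulary shared with the target pool; at 0 the auxiliary
corpora share no content words with the target, so intermediate training
cannot carry target-relevant lexical signal (asserted in tests).
Surface noise (filler-word insertion, topic-keyword contamination at
rate 0.2) is uncounted and never changes a label's recoverability.

What it does **not** emulate — and what passing tests therefore do not
show about real data: natural language syntax and polysemy, clinical
abbreviations, the gap between surface edits and semantic change (here
they coincide by construction, which is why the phrasal edit-similarity
feature is a strong stacker input on synthetic corpora), annotator bias
beyond symmetric noise, and protected-health-information artifacts.

Benchmark study conditions (frozen in `clinsts.experiments`): generator
defaults (200 target pairs, auxiliary corpora of 160–320 examples,
σ = 0.25, coupling 0.7), 1-layer width-32 encoder with 48-token inputs,
4 epochs of multi-task training, 10 of fine-tuning, Adam at 5e-3, seeds
1–5, target split 60/20/20. These sizes are the smallest at which
fine-tuning converges on the training split (train PCC > 0.9), chosen so
the whole benchmark runs in well under a minute per arm. Under them,
intermediate multi-task training raises mean test PCC over fine-tuning
alone, and appending the noise task lowers it — the two qualitative
transfer properties the benchmark exists to measure.

## Numerical choices and degenerate inputs

- Cross-entropy floors probabilities at 1e-12; layer-norm ε = 1e-5.
- Pair packing truncates longest-first (one subword off the currently
  longer side until the budget fits), so both sentences keep content;
  markers always survive.
- Vocabulary merges break frequency ties lexicographically; merging
  stops when no adjacent pair repeats.
- Head biases are included by default, switchable off for exact-formula
  tests.
- Empty-vs-empty string similarity is defined as 1; empty-vs-nonempty
  as 0 (Levenshtein/cosine).
- Non-finite training losses abort with the offending epoch, batch and
  task named; readers reject malformed rows and out-of-space labels with
  line numbers instead of coercing.
- Every stochastic component draws from `numpy` generators seeded from
  explicit integers; reruns with the same config are bit-identical
  (asserted for loss logs and full pipeline artifacts).

## Known limitations

The encoder is desk-scale: absolute PCC values on the synthetic
benchmark are not comparable to systems initialized from GPU-scale
pretrained language models, and no pretrained checkpoints can be loaded
from third-party formats. The medication extractor is rule-based and
intentionally narrow. External scorers participate only through
prediction files; the package does not run them.
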