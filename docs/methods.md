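# Methods

This note records what `portalfusion` computes, the assumptions behind
it, and the design choices made where the design was genuinely open.

## Pipeline

Given a labeled corpus and K encoders, each (repeat, fold) of the
cross-validation does:

1. **Baseline fine-tuning.** One classifier per encoder on the training
   split. With a frozen backend (mock or precomputed embeddings) this
   is a linear softmax head trained by full-batch Adam on the fixed
   embeddings; the chosen rebalancing strategy (class weights,
   oversampling, or focal loss) applies here.
2. **Routing.** Both the training and the test split are partitioned by
   baseline agreement: a message is *agreed* iff all K predicted labels
   coincide, and then carries that consensus label with probability 1.
3. **Fusion training.** The fusion head is trained on the *training*
   split's disagreed messages only, using their gold labels — not any
   baseline's prediction — with the same loss machinery as step 1.
4. **Combination.** On the test split, agreed ids keep the consensus,
   disagreed ids get the fusion head's prediction; every final label
   has exactly one provenance (`consensus` xor `fusion`), recorded in
   the output.
5. **Scoring.** Accuracy and per-class/macro precision, recall, F1 for
   each baseline, the routed fusion, and the majority-vote ensemble,
   on the untouched test fold.

Computing train-side disagreement from the fold-trained baselines
predicting on their own training split is deliberate: it mirrors how
the framework is meant to be deployed, but it makes the training
disagreement set optimistically easy relative to test disagreement.
The harness keeps these splits strictly separated (an id-level audit
trail is asserted in the tests); a nested-CV variant was considered
and left out of scope as the bias affects only the fusion head's
training distribution, not the reported test scores.

## Fusion heads

All heads are plain numpy with analytic gradients and Adam
(full-batch by default), so results are bit-reproducible given a seed.

* **average** — fused vector = column-wise mean over the K embeddings,
  then a dense softmax layer.
* **attention** — additive attention over the encoder axis:
  score_k = vᵀ tanh(W e_k), weights = softmax(scores) (they sum to 1
  by construction and are reported), fused = Σ_k weight_k e_k, then
  dense softmax.
* **cnn** — the K×d stack as a single-channel image; for each filter
  height h ∈ {2, 3} (capped at K) and width 5 (capped at d), 64 filters
  per size, valid-mode convolution + ReLU + global max-pool; pooled
  features concatenated, dropout 0.1 (training only), dense softmax.
  This is the TextCNN convention transplanted to the encoder axis: the
  filters detect cross-encoder patterns in local embedding-coordinate
  windows. Exact layer sizes are configurable; the defaults above are
  recorded in every run manifest.

The backward passes (including softmax-attention and argmax-routed
max-pool gradients) are verified against central-difference numerical
gradients in the test suite.

**Dimension reconciliation.** Encoders of different dimension are
mapped to a common width by a fixed, per-encoder seeded Gaussian
projection applied when the fusion training set is built, and recorded
with the fitted model so inference replays it exactly. A fixed map
(rather than a jointly learned projection) keeps the training-set
builder a pure function of its inputs and the heads independent of K
encoders' native widths; the common case — equal dimensions — uses the
identity. Encoders are always stacked in ascending name order, and the
order is stored with the fitted fusion model so CNN filters see a
stable row layout.

**Degenerate disagreement sets.** If the baselines agree on (almost)
every training message, or the disagreed messages span a single class,
the fusion head cannot be trained; the pipeline logs prominently and
falls back to the majority vote of the baselines for disagreed test
messages (consensus ids are unaffected).

## Training parameters

| parameter | default | notes |
|---|---|---|
| head optimizer | Adam, lr 0.05, 300 epochs, full batch | linear probe on frozen embeddings; converges in seconds |
| fusion optimizer | Adam, lr 0.05, 150 epochs, full batch | the CNN head prefers lr ≤ 0.05 with dropout on |
| focal loss | γ = 2, α = inverse-frequency | the canonical form −α(1−p)^γ log p; γ = 0 recovers cross-entropy |
| class weights | w_c = N/(K·n_c) | weighted masses recombine to N |
| oversampling | to the majority count, training folds only | originals always retained; duplicates drawn with a fold-derived seed |
| CV | 10 folds × 3 repeats (harness default); 5 × 2 in the shipped test configurations | per class, ids are shuffled per repeat and dealt round-robin through a running cursor, guaranteeing fold sizes and per-class counts within ±1 |

Transformer-style fine-tuning settings (learning rate 2e-5, a few
epochs, small batches) apply only when a transformer runtime backs the
encoder; they are configurable on the encoder spec but are not the
defaults for the frozen-encoder path, where they would badly underfit
a linear head.

Cross-validation is stratified. With a 44/13/14/28 class mix,
unstratified folds can nearly empty a minority class from a test fold,
which destabilizes macro metrics; stratification removes that variance
source at no cost.

Aggregation reports mean, sample SD (n−1) and a t-based 95% CI over
the k×r run-level scores (a normal-approximation CI is available via a
flag). Run-level scores are retained in the reports, so alternative
aggregations (e.g. over fold means) can be computed from the same
output. Per-category model selection uses mean macro-F1, with mean
accuracy as the tie-break; the criterion is fixed and recorded.

Zero-denominator precision/recall (a class never predicted, or absent
from the truth) scores 0 with a logged warning — conservative for
macro averages.

## Mock encoder

The offline encoder lowercases, strips punctuation, splits on
whitespace, hashes each token (BLAKE2b salted with the encoder name)
to seed a fixed unit-norm Gaussian vector, and averages token vectors;
the empty message maps to the zero vector. Mean pooling (not a CLS
token) is the pooling convention for all backends because it is
well-defined for every encoder family; it is configurable where a real
transformer backend is used. Hashing involves no process-randomized
state, so embeddings are identical across processes and platforms.

## Synthetic generator

The generator defines the conditions under which the package's claims
are tested:

* labels drawn i.i.d. from proportions A 0.443, P 0.134, L 0.141,
  U 0.282;
* texts from per-class templates over pairwise-disjoint keyword
  vocabularies; with probability q (default 0.3) a sentence from
  another class is appended without changing the label, emulating the
  multi-topic messages that make primary-concern triage hard. The
  default q is a generator choice: multi-topic messages are common in
  real portal traffic but not the majority;
* embeddings e = s·g_k(c)·μ_c + σ·ε with orthogonal axis-aligned class
  directions μ_c, s = 3, σ = 1, and encoder gains g_k(c) = 1 on the
  encoder's complementary classes, γ_low = 0.3 elsewhere. Default
  complementary sets for K = 3: enc1 → {A, U}, enc2 → {P},
  enc3 → {L}, so each class is resolved well by at least one encoder.
  The embedding dimension defaults to 16 — enough for four orthogonal
  class axes plus noise coordinates while keeping the benchmark fast
  on one CPU.

Axis-aligned orthogonal class means make the single-encoder and fused
error rates analytically controllable: for a weak class pair the
between-mean distance is s·γ_low·√2 ≈ 1.27σ, so every single encoder
must confuse its weak classes, while the concatenation always contains
a strongly separated axis per class. At these defaults the trained
baselines disagree on roughly two thirds of messages — a deliberately
disagreement-rich regime that gives the fusion head a large training
set.

What the generator does **not** emulate: real clinical vocabulary and
style, label noise and annotator disagreement, correlation between
text difficulty and embedding noise, and encoders whose strengths are
graded rather than binary. Passing benchmarks here show the machinery
is correct and that routing+fusion exploits complementary encoders;
they do not certify performance on real portal messages.

## Benchmark problem sizes

The standard benchmark (`benchmark_complementary_fusion`) uses
n = 2000 messages, a 70/30 split and a CNN fusion head; the shipped
cross-validation configurations use n = 300–400 with 5 folds × 2
repeats. These sizes were chosen so the full pipeline remains a
desk-scale computation while keeping per-class test counts large
enough for stable macro-F1.

## Known limitations

* With a frozen encoder the baseline is a linear probe; genuine
  transformer fine-tuning (updating encoder weights) requires an
  external runtime and is not exercised by the offline test path.
* The bucket analysis is defined for exactly three baselines, matching
  the three-encoder design; other K skip it.
* The consensus path assigns probability 1 to the consensus label, so
  probabilities on agreed messages are not calibrated scores.
* Focal loss uses the standard multiclass form; the α vector and γ are
  configurable but no automatic tuning is attempted.
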