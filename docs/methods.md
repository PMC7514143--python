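# Methods

## Task and data model

The unit of classification is a *candidate instance*: one unordered pair of
drug-entity mentions inside one sentence, labeled Mechanism, Effect, Advice,
Int or Negative. A sentence with m mentions yields C(m,2) candidates, which
makes the class distribution strongly negative-dominated (most co-mentioned
pairs do not interact). The corpus dialect is the DDIExtraction 2013 XML:
documents → sentences → entities with 0-based, inclusive-end character
offsets (discontinuous mentions use `a-b;c-d`) → pairs with a `ddi` flag and
a type. Pairs listed in an annotated corpus are trusted as the candidate
set; exhaustive C(m,2) enumeration (unannotated pairs defaulting to
Negative) is used for synthetic data and validation, which avoids double
counting.

## Preprocessing

**Blinding.** The candidate pair is replaced by `DRUG1`/`DRUG2` and every
other mention by `DRUG0`, offset-based and applied right-to-left so earlier
offsets remain valid. For discontinuous mentions only the first span is
replaced; remaining spans are deleted — single replacement keeps token
alignment across the blinded variants of a sentence. Overlapping or nested
mention spans are rejected as malformed (they do not occur in practice).

**Tokenization** splits on whitespace, isolates punctuation, lowercases
everything except the `DRUG*` symbols and normalizes digit runs to zeros
("44" → "00"). It is deliberately simple and deterministic; no parser, POS
tagger or other NLP tool is used anywhere in the pipeline.

**Negative-instance filtering.** Three heuristic rules remove negatives that
trivially cannot interact; each is independently toggleable and every
removal is logged (instance id, rule, mention texts) so the filtering trail
is auditable:

* **R1** — the two mention texts are equal after case-folding, or one is a
  parenthesized abbreviation immediately following the other;
* **R2** — the mentions sit in a coordinate structure: at least one token
  lies strictly between them, all such tokens are in {`,`, `;`, `and`,
  `or`, `/`, `DRUG0`} and at least one is a coordinator (the extra
  "at least one coordinator" condition keeps the predicate from firing
  vacuously on adjacent mentions);
* **R3** — one mention text is a strict substring of the other, or the
  mentions are linked by "such as" / "including" / "e.g." with no other
  intervening content word.

Positive instances are *never* filtered, by construction: published corpus
statistics show positives nearly unchanged by filtering, and strict
exemption makes the behaviour deterministic and testable (the count of
positives is invariant under filtering on any corpus).

**Encoding.** Sequences are padded with id 0 / truncated to `max_len`
(default 150). Each token also carries two position features: its signed
distance to DRUG1 and to DRUG2, clipped to ±(max_len−1) and shifted by
+max_len, so a single embedding table of 2·max_len rows serves each entity
and 0 stays reserved for padding. If truncation would drop an entity token,
the window is shifted so both entities survive whenever their span fits;
otherwise the instance is flagged rather than silently corrupted (an
instance without its entities is unlabelable).

## Network

Defaults (all configurable): word embeddings n_w = 200; recurrent hidden
size 100 per direction, so left/right context embeddings are 200-d each;
fused semantic dimension 200; position embeddings n_d = 15 per entity
(N_E = 230); filter sizes {3, 5} in both branches with 100 filters each;
dilation d = 2; two conv blocks with pooling window 2; dropout 0.5; Adam at
learning rate 10⁻³ with batch size 32.

**Context encoding.** The left/right context embeddings are produced by
recurrent chains over the neighbouring tokens' word embeddings; the cell is
an LSTM by default (`cell="simple"` gives a plain tanh recurrence for
ablation). Two readings of the recurrence are implemented behind
`context_mode`:

* `"causal"` (default): the left context of position i is built from two
  independently parameterized chains run *in the causal direction* over the
  right-shifted input sequence, concatenated to 2·hidden dims; the right
  context is symmetric. This guarantees the clean separation the design
  argues for — left context depends only on positions < i, right context
  only on positions > i — while keeping the stated 2·hidden context size.
* `"bilstm"`: a conventional full-sequence BiLSTM whose neighbour hidden
  states serve as contexts. This is the standard reading but the left
  context then sees the whole sentence; both modes are kept because the
  design is genuinely ambiguous between them.

Boundary states are zero vectors. The fusion layer is a single affine map;
with `use_fusion=False` the raw 600-d concatenation is used instead
(ablation), and `use_context`/`use_position` drop those feature groups
entirely. The fused dimension of 200 keeps the semantic:position ratio at
about 200:30 so position information is not dimensionally overwhelmed —
that balance is the point of fusing rather than concatenating.

**Convolutions.** Layer 1 uses valid windows, so the output-length formulas
are exact and testable: n−k+1 for typical filters, n−(k−1)·d for dilated
filters (receptive span (k−1)·d+1, taps at offsets 0, d, 2d, …). Deeper
layers use same-padding so short sequences survive repeated reductions.
Between blocks a sliding max with window 2 and stride equal to the window
downsamples; after the last block a global max over time yields one value
per filter. Branches and filter sizes stay separate until the pooled
vectors are concatenated into the sentence vector s (dropout in training
mode, then affine + softmax). A dilated convolution with d = 1 is exactly
the typical convolution — this equivalence is enforced by test.

**Out-of-vocabulary handling.** Embeddings are initialized uniform in
[−0.05, 0.05]; tokens found in an optional word2vec-text file overwrite
their rows. Padding positions look up row 0 like any other id; since all
instances in a batch share the same padded length and pooling is a max,
this adds no asymmetry worth special-casing.

**Autodiff.** No deep-learning framework is used: the network runs on a
small reverse-mode autodiff core over float64 NumPy arrays implementing
exactly the required ops. Correctness is established end to end by central
finite differences against the analytic gradients of the full
forward-plus-loss at step 10⁻⁵, with worst-case relative error around 10⁻⁵
(the acceptance threshold is 10⁻⁴).

## Objective and training

The loss blends the class-weighted focal term with plain cross-entropy,
L = −e·α_t·(1−p_t)^γ·log p_t − (1−e)·log p_t, with γ = 2 and e = 0.9 by
default and α from normalized inverse class frequency computed once from
the (post-filtering) training counts. The published α table for the
filtered benchmark training set — (0.15, 0.08, 0.10, 0.67, 0.01) in class
order Advice, Effect, Mechanism, Int, Negative — is reproduced exactly by
this formula. Reading notes: the blend weight is interpreted as −(1−e)·log
p_t (the only reading under which e ∈ [0,1] balances the two terms), and
e = 0 reduces the loss to plain cross-entropy to machine precision, which
is the ablation switch. p_t is floored at 10⁻⁷ before the log. Batch
reduction is the mean, decoupling the learning rate from batch size.

Training runs mini-batch Adam (lr 10⁻³, defaults otherwise) for at most 50
epochs with early stopping (patience 5) on dev micro-F over the four
positive classes, returning the best-dev parameters. A class missing from
the training set is an explicit error before training (the α formula is
undefined). Everything is seeded: initialization, shuffling and dropout
derive from the run seed, so identical runs produce identical histories.

## Evaluation

Micro precision/recall/F pool TP/FP/FN across the four positive classes
only; the Negative class enters only through its confusions with positive
classes. This convention is forced by arithmetic on the published benchmark
prediction table: 722/934 = 77.30% precision and 722/979 = 73.75% recall
match the published scores only under positive-class pooling (it is also
the task's standard convention). Per-type P/R/F and a misclassification
breakdown (positives→Negative, Negatives→positive, positive↔positive,
total) are reported alongside. The published table's composite cells mix
classifier predictions with filter-rule assignments; summing them (i.e.
treating filtered-out instances as predicted Negative) reconciles all row
and column totals. Percentages are printed half-up at two decimals; note
the Effect F computes to 73.497, which half-up printing shows as 73.50
while the published table prints 73.49 — the underlying counts agree
exactly. Zero denominators define the metric as 0 with a warning.

## Synthetic corpus generator

The generator emulates the structural properties the pipeline depends on —
the five-class label scheme with controllable imbalance (default mix
≈ 4/7/6/1/82%, mirroring the filtered benchmark training distribution),
≥ 2 entity mentions per sentence with exact character offsets, distractor
mentions that add extra Negative pairs, and byte-identical determinism per
seed. Class signal is carried by trigger phrases ("should not be
coadministered with", "increases the plasma concentration of", …), which
makes the task nearly linearly separable on purpose: end-to-end learning
tests are then fast and stable. `hard_mode` adds Int templates that reuse
Effect wording, reproducing the Int→Effect confusion structure seen on
real data. What the generator does *not* emulate: real biomedical
vocabulary and syntax, long-range discourse, annotation noise, or realistic
sentence lengths. Passing the end-to-end tests therefore demonstrates that
the pipeline, optimizer and metric wiring are correct — not that the
architecture reaches any particular score on real corpora, which would
require the licensed benchmark and long training runs.

## Problem sizes used in tests and the acceptance script

Desk-scale configurations keep the default suite and the acceptance run
fast while exercising the full architecture: the end-to-end experiments use
2,000 training / 500 held-out sentences with a reduced geometry (32-d
words, 16 hidden units, 8 filters, max_len 40), which reaches held-out
micro-F 1.0 within a few epochs; the focal-vs-cross-entropy comparison
uses 1,200 sentences at 1:20 imbalance, 4 epochs, paired over 5 seeds and
compared by the mean per-seed difference in held-out positive-class recall;
the gradient check uses a miniature configuration (sequence length 12) with
3 sampled entries per parameter tensor.

## Known limitations

* The NumPy implementation is single-threaded and unsuited to full-corpus
  training at the published scale; the architecture is faithful but the
  headline benchmark score is not desk-reproducible.
* Abbreviation detection in R1 only recognizes the parenthesized pattern;
  the original filtering also removed a small number of positive mentions
  (3998 vs 4020 in the published counts), which strict positive exemption
  intentionally does not reproduce.
* Cross-sentence and nested mentions are rejected as malformed rather than
  handled.
* The word2vec loader reads the text format only (no binary format).
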