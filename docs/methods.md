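# Methods

This note documents the models and procedures `crcs` implements, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical and design choices made where the design was
genuinely open.

## Codon-switch representation

A coding SNV on a transcript is rendered as a sequence over the 640-entry
codon-switch vocabulary (64 identity pairs + 576 single-base substitution
pairs).  Codons are framed in **spliced transcript space**: minus-strand
transcripts are reverse-complemented before framing and the variant's
alternative base is complemented with them, so codons spanning exon
junctions are handled uniformly.  The dictionary ordering is canonical —
reference codons lexicographic (AAA..TTT); within a block the identity
switch first, then substitutions by position (0,1,2) and alternative base
(A<C<G<T) — and a fingerprint of the ordering is stamped onto every
embedding matrix so a classifier can refuse an embedding trained against a
different ordering.  Only the 0–639 range is externally meaningful; the
specific order is a reproducibility device.

Variant pruning mirrors standard tumor-only preprocessing: SNVs only,
coding only (inflating by splice variants), duplicate removal on the
transcript-level key (transcript, CDS codon offset, switch) — duplicates
are defined *after* splice mapping — removal of synonymous switches,
removal of records flagged pathogenic, and an optional 40 % hold-out of
variants (not transcript records) reserved for embedding training, disjoint
from the classification set.

## Embedding model

Skip-gram with negative sampling, cast as binary classification of
(center, partner) pairs.  Parameters, with defaults:

| parameter | default | meaning |
|---|---|---|
| ws | 3 | context half-window, in codon switches |
| nsr | 0.2 | negative sampling rate; ⌈(2·ws+1)·nsr⌉ = 2 negatives/center |
| ε | 0.001 | subsampling frequency floor (dimensionless) |
| L | 300 | embedding length |
| epochs | 200 | ADAM (lr 1e-3, β₁ 0.9, β₂ 0.999), batch 1024, per-epoch shuffling |

The subsampling keep probability is min(1, √(1+f/ε)·ε/f) with f the
**relative** frequency of the switch over the embedding corpus —
normalization is required for ε = 0.001 to be meaningful, and f = 0 maps to
1 by continuity.  Negatives are drawn uniformly over all 640 switches with
no exclusion of true context partners; collisions are rare and harmless.
One matrix is shared between the center and partner roles (not two as in
classic word2vec): the model is σ(w·⟨e_c,e_p⟩+b), giving 640·L + 2
trainable parameters (192,002 at L = 300).  Gradients are analytic and are
checked against finite differences in the tests.

## BLAC classifier

Stack: frozen embedding lookup → bi-LSTM → batch norm → bi-LSTM → batch
norm → time-distributed dense (tanh) → batch norm → additive attention →
dense sigmoid.  Defaults: hidden sizes 64/64/32/32 (exposed in
`BLACArchSpec`; tests and the acceptance run use 16/16/8/8), ADAM lr 1e-3,
batch 32, binary cross-entropy.  Implementation notes:

* **Variable lengths.**  Batches bucket by length and pad.  Padding is
  always trailing (the reverse LSTM direction reverses only the valid
  prefix of each sequence), batch-norm statistics are computed over valid
  positions only, and attention softmax masks padded steps — so padded and
  unpadded forward passes agree to numerical precision (asserted at 1e-10).
* **Batch norm** uses batch statistics in training and running statistics
  (momentum 0.99) at inference.
* **Attention** is additive: score_t = v·tanh(W x_t + b), masked softmax
  over time, weighted sum.  No attention form was prescribed; this is the
  common default.
* The embedding layer is non-trainable; a test asserts its rows are
  bit-identical after an optimization step.

Training-set filters: sequence length strictly < 1500 switches; genes must
retain ≥ 200 sequences (splice variants included).  Evaluation is
gene-disjoint k-fold cross-validation (k = 4): genes are partitioned into
near-equal folds and every sequence is scored exactly once, by the model
whose training fold excluded its gene (asserted on every run).  Average
precision is computed as the mean of precision at each ranked positive,
with tied scores treated as one threshold group (a constant scorer earns
the positive prevalence).  The no-signal control randomly halves a
single-class pool into balanced pseudo-classes and runs the full
cross-validation cycle; its AP concentrates near 0.5.

The layer widths are deliberately configurable and no attempt is made to
match any particular total parameter count; the architecture, not its
width, is the contract.

## Driver-gene scan

Scores are grouped by (cancer type, gene) for the cancer cohort and by gene
for the control cohort; groups with fewer than 5 scores are dropped.  Each
(cancer type, gene) group is tested one-sided (cancer > control) with the
Mann–Whitney U test: exact enumeration of all C(n, n_a) assignments when
n_a + n_b ≤ 12 (midrank U for ties), normal approximation with tie
correction otherwise.  Within each cancer type, gene p-values are
Holm–Šidák adjusted (adj₍ᵢ₎ = max_{j≤i}[1 − (1−p₍ⱼ₎)^{m−j+1}]); the
correction is per cancer type, not global.  Significance is called at
α = 0.05 on adjusted p.  Recurrence selection keeps genes significant in
≥ 10 cancer types, then drops cancer types retaining ≤ 5 such genes; both
thresholds are parameters.  Driver enrichment uses a one-sided two-sample
KS test on −log10(adjusted p) (known drivers stochastically larger); zero
adjusted p-values are floored at the machine-precision cap, logged.

## Survival scoring

Patient score: BLACs(P) = mean over mutations of 2^{k·s} − 1, k = 4,
bounded by [0, 2^k − 1] and strictly increasing in every mutation score.
Cohort filters: patients need ≥ 5 scored mutations; cancer types need
≥ 100 such patients.  Per cancer type, candidate cutpoints are midpoints of
consecutive distinct scores subject to each side holding ≥ 10 % of patients
and ≥ 5 patients (configurable; prevents degenerate splits), and the
cutpoint maximizing the log-rank χ² is chosen (ties → lowest).  The
log-rank test is the standard Mantel–Haenszel accumulation of
observed-minus-expected events over distinct event times with
hypergeometric variance, events before censorings at tied times; it matches
`lifelines` to 1e-10 in the tests and is vectorized over cutpoints (the
high-risk group of every cutpoint is a suffix of the score-sorted cohort,
so all cutpoints share one risk table).

**Selection-adjusted p.**  Choosing the χ²-maximizing cutpoint makes the
raw log-rank p anti-conservative (the classic maximally-selected-statistic
problem).  `stratify_and_test` therefore reports both the raw p at the
chosen threshold — the quantity practitioners usually quote — and a
permutation-based adjusted p: scores are permuted against (time, event)
pairs, the maximal χ² over admissible cutpoints is recomputed per
permutation (default 200), and the adjusted p is the upper-tail proportion
with the +1 correction.  All calibration claims in the tests use the
adjusted p; under a null hazard it rejects at the nominal rate while the
raw p does not.  Only overall survival is modelled, and no multiplicity
correction is applied across cancer types.

## N-gram profiles

CDS translation uses the standard genetic code with stop codons as a 21st
symbol, giving 21/441/9261 possible unigrams/bigrams/trigrams.  N-grams are
counted with stride 1 within each protein, never across protein boundaries,
and normalized to frequencies.  Chromosome profiles are compared by
Spearman rank correlation with average-rank tie handling.

## Synthetic data

The generator emulates the statistical structure the method assumes, at a
scale that runs in minutes on one CPU:

* **Genome**: 2 chromosomes, 50 genes of 40–63 random sense codons (no
  internal stops), 1–3 exons split at arbitrary nucleotide boundaries (so
  codons cross junctions), both strands, tunable GC content; all pure
  functions of (config, seed).
* **Variant classes**: each gene is partitioned into disjoint slots of
  2·ws+1 codons; a variant owns a slot and, with probability β, the 2·ws
  codons flanking its (untouched) center codon are redrawn from a
  class-conditional codon pool (A/T-leading codons for class 0,
  G/C-leading for class 1; background otherwise).  β = 0 makes the classes
  indistinguishable by construction; β parameterizes task difficulty.
  Genes are assigned to a single class (greedily balancing slot capacity)
  because two classes writing conflicting contexts into one shared
  reference CDS would cancel each other; gene-disjoint cross-validation
  still forces the classifier to generalize by context rather than gene
  identity.  The signal is planted in the *flanking* composition, never in
  the variant codon itself.
* **Survival**: event times exponential with rate base·exp(γ·BLACs),
  independent censoring at a configured rate.

What passing tests on these data do show: the encoder, embedding trainer,
classifier, rank tests and survival scan recover signals that are present
and stay calibrated when they are absent.  What they do not show:
performance on real tumor data — real mutational contexts are far weaker
and confounded (mutational signatures, coverage, gene length, selection),
and no attempt is made to simulate them.

## Problem sizes and numerical choices

Test and acceptance runs use reduced scales chosen as the package's
defaults for desk-scale work: 400–800 sequences of 20–63 codons, embedding
length 16–24 with 6–10 epochs, BLAC widths 16/16/8/8 with 6–8 epochs,
survival cohorts of 120–150 patients with 60–200 permutations.  All
computation is float64.  Degenerate inputs fail loudly: empty corpora,
single-class training folds, all-equal survival scores, empty rank-test
groups and out-of-range probabilities raise errors rather than returning
defaults.

## Known limitations

Indels, multi-nucleotide and complex alterations are out of scope, as are
UTR/noncoding variants, genome liftover, BAM/CRAM input, and fully
spec-compliant VCF parsing (a minimal SNV subset is read; the pathogenicity
flag comes from a configurable INFO key, default CLNSIG).  The embedding
and classifier are deterministic given a seed but are not tuned for GPU- or
corpus-scale runs.
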