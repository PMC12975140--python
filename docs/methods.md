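# Methods

## Problem and model

`m6ahd` casts differential m6A methylation as binary classification of
sequence windows. For a condition with experimental and control m6A
evidence, a *true* site is a single-base candidate adenosine contained in
a MeRIP-seq peak (0-based half-open BED containment, matched on reference
sequence and strand). The up-direction positives are sites methylated only
in the experimental sample; the down-direction positives only in the
control. The classifier never sees methylation calls — only the window
sequence — so a good model implies that differential sites carry a
distinctive local sequence context.

Two negative-set conventions exist in practice and both are implemented
(`negative_mode`):

- `definitional` (default): up-negatives are stably methylated sites
  (present in both samples); down-negatives are candidates methylated in
  neither.
- `unmethylated`: both directions use never-methylated candidates.

The candidate universe for "unmethylated" is the supplied single-base
candidate list minus all true sites; no transcript-composition matching is
applied between classes.

## Encodings

Six schemes, concatenated in the fixed order OH, NAC, CP, EIIP, ANF,
PseDNC so column indices are stable across runs. Dinucleotides are ordered
lexicographically over A<C<G<U. One-hot uses the lexicographic base order
(A=e1, C=e2, G=e3, U=e4). DNA input is uppercased and T→U mapped at read
time; windows containing other characters are dropped upstream with a
logged count.

PseDNC needs a per-dinucleotide physicochemical property table. The
bundled table derives three properties from RNA nearest-neighbor
thermodynamics — Watson–Crick stack free energy ΔG°37, enthalpy ΔH°, and
the entropy implied by them at 310.15 K — each z-score normalized over the
16 dinucleotides. Defaults λ=3, w=0.05; all three are configurable, and
λ=0 reduces the encoding exactly to the dinucleotide composition (a unit
test enforces agreement to 1e−12).

## Selection and training

Selection is staged (length → feature combination → algorithm → RF grid)
rather than factorial; each stage scores held-out AUROC on the single
80/20 split (no k-fold, matching the single independent-test design).
Ties break toward the simpler setting: smallest window, fewest schemes,
smaller ntree then mtry. The base algorithm during the length scan and
feature search is the random forest, which is also the final model family.

Algorithm realizations: RF = scikit-learn `RandomForestClassifier`
(ntree=`n_estimators`, mtry=`max_features`; default ntree 500, mtry
⌊√p⌋); SVM = RBF kernel with probability outputs, features standardized
inside the SVM path only (trees are scale-invariant); GLM = logistic
regression (binomial family, the natural GLM for binary labels); GBT =
XGBoost with depth 6, 300 rounds, learning rate 0.1. All estimators are
seeded and single-threaded, so a fixed seed reproduces scores bitwise on
one machine.

Gini importance is the per-tree impurity decrease summed over splits
(scikit-learn's sample-weighted variant of the classical mean decrease in
Gini), averaged over trees and reported raw plus as fraction-of-total.
Aggregation sums by scheme and, within CP, by channel — making claims
like "the ring/purine channel dominates" checkable instead of anecdotal.

## Metrics

Sn, Sp and ACC use a 0.5 score threshold by default (configurable); ties
at the threshold count as positive calls. A missing class makes Sn or Sp
NaN with a warning rather than an error. AUROC is the Mann–Whitney rank
statistic with ties counted ½; AUPRC is step-interpolated average
precision. Both are computed via scikit-learn and cross-checked in the
test suite against hand-written brute-force oracles (all positive×negative
pairs; exhaustive threshold sweep) to 1e−12.

Cross-condition prediction trims target windows centrally to the source
model's length (parity always matches since lengths are odd), re-encodes
with the source model's scheme set and reports AUROC per (source, target)
cell; a target shorter than the source length yields a missing cell with a
recorded reason.

## Synthetic generator

The generator emulates called peaks and single-base candidates — not
reads: no coverage model, no FASTQ. Background is i.i.d. sequence at the
configured GC (no higher-order composition), each condition drawing an
independent transcript set from the same parameters. Each planted site is
a concrete RRACH instance (R, H uniform over their codes). Control
methylation is Bernoulli(`base_methyl_rate`); the experimental sample
gains an unmethylated site with probability `gain_rate` and loses a
methylated one with probability `loss_rate`. Differential sites receive a
purine-biased flank (`signal_bias`, default 0.85) within
±`signal_halfwidth` (default 8) nt of the anchor, outside the motif
itself.

Defaults define the standard benchmark: 5 conditions × 250 transcripts ×
2,000 nt × 10 sites (2,500 sites/condition), peak half-width 50 nt,
gain = loss = 0.3, base rate 0.5. Site placement uses per-transcript bins
with guard margins so motifs never overlap, every site admits an 81-nt
window, and peaks of adjacent sites never swallow a neighboring candidate
— which makes peak-intersection recovery of the truth table exact, a
property the tests assert.

What passing tests therefore show: the framework recovers a *planted,
localized, composition-level* signal and its purine character, and behaves
at chance on permuted labels. What they cannot show: performance on real
epitranscriptomes, where signal is weaker, context is structured (RNA
secondary structure, RBP competition, isoform effects) and methylation
calls are noisy.

## Benchmark properties and problem sizes

The benchmark assertions run the default bundle with fixed seeds: every
condition/direction random-forest model must reach held-out AUROC ≥ 0.85,
and its label-permutation null must lie in [0.4, 0.6]. The null is
estimated as the mean AUROC over 3 independent full-label permutations
(retrain and rescore per permutation): with ~150-row test sets a single
permutation's null AUROC has a standard deviation near 0.05, so averaging
is the standard way to report a stable permutation estimate. The planted
signal-recovery and window-scan properties use 5 seeded replicates and
require 4 successes; the scan fixture deliberately weakens the bias to
0.65 so that longer windows measurably dilute the signal — at the default
bias every length saturates and the argmax is uninformative.

Grid-search tests use reduced grids; the full 13×51 default grid is
enumerated (663 settings) but not fitted in the test suite, which keeps
the whole suite in a few minutes on one CPU.

## Numerical and degenerate-input choices

- Boundary sites (flank would leave the transcript) are dropped, never
  padded — padding would fabricate sequence; drops are logged.
- `subsample_split` clamps a short class to its availability with a
  warning; an empty class is an error.
- mtry values above the column count clamp to it and deduplicate.
- An all-tie score vector gives AUROC exactly 0.5; single-class inputs
  raise for AUROC and AUPRC rather than returning a misleading number.
- Every PRNG stream is derived from the run seed (split seeds as
  `seed·1000 + 10·condition + direction`) and recorded in the manifest.

## Known limitations

- Sequence-only features: no secondary-structure (icSHAPE) or RBP-binding
  inputs, no k>2 tuple compositions, no deep-learning predictors.
- No peak calling or GFF annotation handling; inputs start at called
  peaks, candidate sites and FASTA sequences.
- The synthetic generator's i.i.d. background understates real
  compositional autocorrelation, so absolute synthetic AUROCs are
  optimistic by construction.
- Negative-set convention materially changes the learning task; both
  modes are exposed precisely because the field has not settled on one.
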