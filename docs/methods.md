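# Methods

## Problem and data model

The task is binary classification of center-aligned RNA windows: the
central residue is a candidate uridine and the label says whether it is a
pseudouridine (Ψ) site. Inputs are assumed pre-windowed (a positives FASTA
and a negatives FASTA, or a single TSV); no window extraction from
transcripts and no redundancy removal is performed here. Windows of 21 and
31 nt are the common benchmark lengths, but the pipeline works for any
length ≥ 2. T is silently normalized to U on input (benchmark files are
often distributed in the DNA alphabet); the normalization is logged once
per file. Labels come exclusively from which file a record is in, never
from header parsing. The central-uridine check is warning-level: odd-length
windows whose center is not U are reported, even-length windows are
reported as unverifiable, and neither is removed, because the feature
pipeline itself does not depend on the center.

## Feature extraction

Each window is encoded twice using per-dinucleotide constants — RNA
stacking free energy (kcal/mol) and hydrophilicity — over the 16 ordered
dinucleotides. The profile of a length-N window has length N−1. Profiles
are right-padded with zeros to `max_length − 1` of the dataset; padding
acts on the numeric profile, not the nucleotide string, since no "zero
nucleotide" exists. The DFT (numpy's FFT; an O(L²) double-sum oracle in
the test suite pins the convention H(k) = Σ h(n)·exp(−i2πkn/L)) is taken
and all L amplitudes are kept, including the DC term and the redundant
conjugate-symmetric half — the feature count 2(N−1) implies no truncation.
Blocks are concatenated free energy first, then hydrophilicity, with
auditable column names `FreeEnergy_Amp_k` / `Hydrophilicity_Amp_k`
(k from 1). No standardization is applied by default; a z-score switch
exists and defaults off. Feature TSVs are written at 17 significant digits
and read back with round-trip float parsing, so the disk round trip is
bit-exact.

## Network

Architecture, in order:

1. **Input mapping** to a `reshape_dim × reshape_dim × 1` grid. Default
   mode is a learnable *linear* affine projection to reshape_dim² units
   (the feature-engineering stage); `zero_pad` mode instead appends
   reshape_dim² − dim zeros and reshapes row-major (a 60-feature vector on
   an 8×8 grid gains exactly 4 zeros). Both modes are first-class because
   the two descriptions of this stage are genuinely different mechanisms;
   the choice is a flag rather than a silent resolution. The projection
   has no nonlinearity by default.
2. **Convolution**: one valid 2-D convolution, square kernel, configurable
   stride, `filters` output maps (default 16 — the filter count is not
   fixed by the method, and 16 is the smallest power of two that keeps the
   flattened size nontrivial when pooling reduces the map to 1×1).
   Activation (ReLU or SeLU) follows the convolution.
3. **2×2 max pooling**, stride 2, no padding; an odd conv side is cropped
   by one row/column. A conv side of exactly 1 skips pooling (logged)
   instead of erroring — degenerate but shape-legal, and required to keep
   the 8×8-grid / 5×5-kernel / stride-3 configuration trainable.
4. **Dense stack**: `dense_layers` layers of `dense_units` units, same
   activation, inverted dropout at rate 0.30 after every dense layer
   (train time only; prediction is deterministic).
5. **Head**: 2-unit softmax; loss is cross-entropy.

Training: minibatch Adam (lr 1e-3, β₁ 0.9, β₂ 0.999, ε 1e-8), batch size
32 — conventional defaults, all configurable. Weight init is He-scaled
normal for ReLU and LeCun-scaled for SeLU. One integer seed drives
initialization, epoch shuffling and dropout masks, so results are
bit-reproducible per platform. A non-finite loss raises immediately with
a diagnostic. Reshape order is row-major and recorded in the model spec.

Reference configurations `HUMAN_CONFIG` (8×8, 5×5, stride 3, 2×32 dense,
SeLU) and `YEAST_CONFIG`/`MOUSE_CONFIG` (8×8, 4×4, stride 2, 1×32 dense,
ReLU) ship as constants.

## Evaluation

ACC, Sn, Sp and MCC are computed directly from the confusion counts; any
metric with a zero denominator is defined as 0 and flagged as degenerate
rather than raised, so hyperparameter screening survives pathological
folds. AUC is the Mann–Whitney rank statistic (ties count one half),
computed per validation fold and averaged like the other four metrics; a
pooled-AUC variant over out-of-fold scores is available behind a flag.
Cross-validation folds are stratified — the benchmarks are balanced, and
stratification both matches that design and stabilizes small-fold metrics
— with assignment a function of (labels, k, seed) only. A fresh model is
trained per fold with a fold-derived seed. Hard labels use threshold 0.5
on the class-1 probability (configurable). Metrics are printed to 4
decimal places.

## Hyperparameter search

Random search over the product of the six candidate lists (648
combinations). Each of `n_iter` draws (default 30, ≈5% of the space —
n_iter is not fixed by the method and is configurable) samples every field
uniformly and independently, as a pure function of (master seed, draw
index). Structurally illegal combinations — e.g. a zero-pad grid smaller
than the feature count — are rejected and redrawn, with rejections logged;
with the default space and the projection mode no combination is illegal.
All draws are screened on the *same* seeded 5-fold split at 15 epochs for
fairness; the selection key is screening ACC with MCC as tie-break
(ACC is the headline metric of this literature) and earliest draw as the
final tie-break. The winner is re-evaluated with 10-fold cross-validation
at 30 epochs and that result is attached to the trace, which serializes
to JSON deterministically.

## Synthetic data generator

The generator emulates the *shape and compositional contrast* of the
benchmark datasets: balanced classes, fixed odd window length (21 or 31
typical), central U in every window of both classes (negatives are
unmodified uridine sites), and flanks drawn independently per position
from uniform {A,C,G,U} mixed with an enrichment: positives shift s·δ of
probability mass toward U within 5 positions of the center on each side,
negatives shift s·δ toward A across all flank positions. δ = 0.4 and the
5-position half-width are fixture constants (both configurable), not
claims about biology; at s = 1 the enriched base has probability 0.65.
The signal strength s ∈ [0,1] interpolates from exchangeable classes to
strong separation. U-rich and A-rich flanks separate sharply on both
property tables (e.g. UU stacking free energy −0.930 vs ≈ −3 for
G/C-containing pairs), which is exactly the contrast the DFT features
amplify.

What passing on this generator shows: the pipeline recovers a planted
compositional difference and reports chance on a null. What it does not
show: performance on real species-specific motif structure, positional
dependence beyond independent positions, dinucleotide correlations, or
secondary structure — real benchmarks must be run through the same
commands to assess those.

## Problem sizes and defaults used in the shipped checks

The test suite and the examples use 100+100 windows of length 21,
10-fold cross-validation at 30 epochs for end-to-end checks (≈1 s per CV
run in numpy), 5-fold/15-epoch screening in search demonstrations, and
smaller budgets (2–5 epochs) where only determinism or plumbing is being
exercised. These sizes were chosen to make the full suite and examples
comfortably quick on a single CPU while leaving the end-to-end signal
criteria far from their thresholds.

## Known limitations

- The convolution stage is single-layer by design; the architecture is a
  deliberate reproduction of a compact model, not a general CNN library.
- Zero-padding mixed-length sets changes spectral leakage for the shorter
  sequences; all standard benchmarks are fixed-length, so the padding rule
  is implemented as specified but exercised only by synthetic tests.
- The numpy implementation targets CPU and datasets of benchmark scale
  (hundreds to thousands of windows); it is not intended for
  transcriptome-scale scoring.
- MCC/Sn/Sp conventions (degenerate → 0 with a flag) are a reporting
  choice; comparisons against tools that raise or return NaN should align
  conventions first.
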