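# Methods

## The model

`motiflm` implements a short-context masked language model (MLM) of
regulatory DNA. Inputs are 350-bp windows over candidate cis-regulatory
elements; tokens are single nucleotides (A, C, G, T, N, MASK). The encoder
is a bidirectional pre-LayerNorm transformer with rotary position embeddings
(RoPE) applied to queries and keys in every attention layer, and a
language-modeling head (linear → GeLU → LayerNorm → linear) producing a
4-way distribution over A, C, G, T at every position. The published scale is
768 dimensions, 8 blocks, 8 heads, feed-forward 3072 (57.3M parameters); a
desk-scale preset (64 dimensions, 2 blocks, 4 heads, feed-forward 128, 72k
parameters) is used by the test suite. The N token's embedding is fixed at
zero and excluded from optimization; N positions participate in attention
but never contribute to any loss.

The entire network — forward pass, backpropagation through attention, RoPE,
LayerNorm, GeLU and the head, and the Adam optimizer — is implemented
directly against numpy, with fused numba kernels for the attention softmax
(bitwise-equivalent numpy fallbacks exist). Gradients of every parameter
tensor are verified against float64 central finite differences in the test
suite (relative error < 1e-4).

## Masked-LM objective with repeat-aware loss masking

Per sequence, each eligible position is selected independently with
probability 0.15; of the selected positions 80% are replaced by MASK, 10%
are mutated to a uniformly chosen different base, and 10% are left
unchanged. All selected positions contribute the negative log probability of
the original base; the loss is averaged per sequence, then per batch.
Eligible positions exclude N and the interior of soft-masked (lowercase)
repeat runs of at least 30 bp. When training *without* the spectral prior,
every soft-masked base is excluded, not just long runs — long repeat tracts
are exactly the low-frequency structure the prior otherwise penalizes, so
the ablation compensates by excluding repeats outright.

## The Fourier motif-discovery prior

Regulatory motifs are mostly 6–20 bp, so motif-scale structure in a per-base
profile of length L concentrates spectral mass between C_L = L/20 and
C_H = L/6 cycles per window. The prior takes the dense profile p of the
model's predicted probability of the original base at every position (from
the same masked forward pass as the MLM loss; N positions are filled with
the mean of the others), computes the magnitude DFT at positive frequencies
1..⌊L/2⌋ excluding DC, L1-normalizes it to a, and scores

    w_i = 1/(1 + (C_L − i)/s)  for i < C_L
    w_i = 1                    for C_L ≤ i ≤ C_H
    w_i = 1/(1 + (i − C_H)/s)  for i > C_H

    L_att = 1 − Σ w_i a_i,   L_total = L_MLM + λ·L_att

with smoothing s = 5 and weight λ = 0.002 by default. The cutoffs are kept
real-valued (at L=350: C_L = 17.5, C_H ≈ 58.33) and compared with closed
inequalities to integer indices, so the unit-weight band at L=350 is
i ∈ [18, 58]. An ε = 1e-8 floor in the L1 normalization makes a constant
profile (zero non-DC spectrum) score L_att ≈ 1 — flat, uninformative
profiles are maximally penalized. The analytic gradient of L_att with
respect to the profile is propagated through the softmax head jointly with
the MLM gradient; the profile gradient at N positions is redistributed to
the non-N positions through the mean-fill rule.

Two readings of the objective were possible: computing the profile from the
masked training pass (chosen — it shares the forward pass with the MLM loss
and covers every position) or from a second unmasked pass (twice the cost).
Similarly, all selected positions (masked, mutated, unchanged) contribute to
L_MLM, following standard masked-LM practice; the sources leave both points
open.

## Training

Adam (β = 0.9/0.999, ε = 1e-8), gradient clipping at global norm 1, no
weight decay, constant learning rate. Published-scale defaults: lr 1e-4,
150 epochs. Augmentation per epoch: reverse complement with probability 0.5
and, when a genome is available for re-extraction, a uniform shift in
[−50, +50] bp clamped at chromosome edges. Validation MLM loss (fixed
validation masking) is computed each epoch; the best-validation parameters
are retained; early stopping patience is 10 epochs.

### Desk-scale preset

The tiny preset compresses a pretraining run by roughly four orders of
magnitude (2,000 sequences × ~2 epochs vs. 2.3M sequences × 150 epochs), so
its optimization settings are necessarily different from the published
scale: lr 3e-3, batch 16, dropout 0. Two initialization choices specifically
shorten the long plateau before motif-scale attention forms on very short
schedules, and both leave the architecture and its learnability unchanged:

- **RoPE base 100** (instead of the long-context convention 10000): at
  L = 350 most rotary channels then rotate appreciably over motif-scale
  offsets, making relative positions within ±20 bp linearly discriminable
  from the start.
- **Offset-kernel attention initialization**: query/key *biases* (otherwise
  zero) are set per head so that, before any learning, head h's attention
  kernel over relative offsets Δ is ≈ Σ_f cos(ω_f(Δ − d_h)) peaked at
  d_h ∈ {−2, −1, 1, 2} — a constant key vector paired with a query bias
  pre-rotated by d_h. Attention thus starts out reading specific nearby
  positions, like a small convolution, instead of averaging over all 350.
  The biases remain ordinary trainable parameters.

## Likelihood reconstruction and normalization

The reconstruction profile of a sequence masks each position in turn (L
forward passes, batched; the result is invariant to the batching) and
records the predicted distribution at the masked position. Normalization
divides the probability of the observed base by that base's sequence-wide
mean predicted probability: p_norm[i] = p[i, b_i] / p̄_{b_i}, where p̄_k
averages column k over all non-N positions. The alternative reading of the
normalizer — averaging only over positions whose observed base is k — was
rejected because the sequence-wide column mean is well-defined even for
bases rare in the window and reduces exactly to 1 under a composition-only
model. N positions carry no p_norm (stored as NaN, excluded from means).

Contribution tracks for seqlet-based motif discovery carry ln p_norm on the
observed base's channel (zeros elsewhere), with an optional "hypothetical"
track ln(p[i, ·]/p̄) on all four channels; both are written to HDF5 together
with one-hot sequences in the layout seqlet-discovery tools consume.

Motif-vs-shuffle comparisons dinucleotide-shuffle only the motif span
(Altschul–Erickson Eulerian-path shuffle, preserving exact dinucleotide
counts), recompute the profile, and report the fraction of replicates the
observed mean ln p_norm strictly exceeds.

## Nucleotide dependency maps

With no masking, one reference pass and three substitution passes per
position i (1 + 3L passes) give, for every target j and base k, the log2
ratio of odds(p) = p/(1−p) between the substituted and reference passes.
e[i][j] is the signed value of maximal absolute magnitude over the 3
alternate bases at i and 4 bases k at j; probabilities are clamped to
[1e-6, 1−1e-6] before forming odds; the diagonal is 0 by convention. The
printed formula fixes only that the substituted base differs from the
reference; maximizing over the alternates (keeping the sign) is this
package's convention.

## Variant scoring

Zero-shot: the 350-bp window centered on the variant (clamped at chromosome
edges) is extracted, the variant position masked, and the score is the
natural-log likelihood ratio s = ln p(alt)/p(ref) from a single forward
pass. The log base is recorded in output headers; rank metrics are
base-invariant. A genome/reference mismatch withholds the score rather than
swapping alleles. Supervised-style scoring applies a user-supplied positive
oracle g to two 2,114-bp windows differing only at the center and reports
log2 g(S_alt)/g(S_ref). Evaluation computes Pearson and Spearman
correlations against observed effect sizes on significant variants only,
and AUROC for significant vs. non-significant discrimination using |score|
over all variants.

## Embeddings and chunking

Per-base embeddings average the outputs of the last min(6, n_blocks)
encoder blocks. Sequences longer than the context are embedded by tiling:
when the length M is an exact multiple of the 350-bp context the windows
tile end-to-end; otherwise a central window is placed symmetrically about
the sequence midpoint (ties toward the 5' side), full windows tile outward,
and the uncovered ends take their rows from embeddings of the first/last
350 bp. For M = 2,114 this yields 5 full windows covering [182, 1932) and
edge fills from [0, 350) and [1764, 2114); every output row is produced by
exactly one window.

## Generation and design

Untargeted generation repeats N_i times: mask each non-N token with
probability p_m, compute softmax(logits/τ), and resample only the masked
positions. Targeted design is a beam search: the pool starts at the seed;
each step every retained sequence spawns 4 candidates (configurable) via
untargeted generation, the scalar objective scores them, and the top k of
parents-plus-children survive (ties to earlier insertion). Because parents
compete at retention, the best score is non-decreasing — asserted at run
time. For oracles with longer inputs, the candidate is spliced into the
center of a frozen full-length sequence before scoring. Built-in objectives:
absolute-error-to-target on one oracle, and a weighted difference of two
oracles (cell-type-specificity style).

## Synthetic study conditions

The corpus generator emulates a regulatory-element training set at desk
scale: 2,000 sequences of 350 bp; i.i.d. background with composition
(0.30, 0.20, 0.20, 0.30); four planted PWMs of widths 6/8/10/12 with one
dominant base per column (0.92, information ≈ 1.5 bits/column; floor 0.01
keeps log-odds finite), Poisson(2) non-overlapping instances per sequence
on uniform strands; 10% of sequences receive one lowercase repeat run of
30–80 bp outside planted spans; splits 85/10/5 train/val/test. Variant sets
substitute the highest-information column of a planted instance with the
column's least likely base (effect size = PWM log-odds delta, natural log;
flagged significant), keeping only sites whose mutation strictly lowers the
sequence's best PWM match; background variants fall outside planted spans
with N(0, 0.05) effects and are not significant.

What the generator does not emulate: dinucleotide and repeat structure of
real genomic background, motif co-occurrence grammar, cell-type-specific
motif lexicons, and measurement noise in QTL effect sizes. Passing tests
therefore demonstrate the correctness and internal consistency of the
machinery, and the qualitative behaviors (motif recovery, prior effects,
variant separation) at desk scale — not performance on real regulatory
genomics data.

## Problem sizes used by the test suite and acceptance script

All heavy checks run on the default 2,000-sequence corpus. The trained-model
sweep trains 5 matched seed pairs (with/without prior), 2 epochs each at the
tiny preset; reconstruction summaries use 3 validation sequences per model;
variant scoring uses 50 + 50 variants; dependency analysis uses 2 validation
sequences; guided design uses 20 seeded beam-search runs (10 in the
acceptance script). The acceptance script trains one matched pair for 8 epochs (its single
pair affords a longer schedule than the 5-pair test sweep) and summarizes
reconstruction over 5 validation sequences. These sizes are this package's desk-scale choices; anything
larger is a matter of increasing the corpus or epochs in the configs.

## Known limitations

- Training at the published scale (2.3M windows, 150 epochs) is supported
  by the code but far outside desk-scale runtimes; no trained checkpoint of
  that scale is shipped.
- At the two-epoch desk schedule the motif-likelihood contrast is small;
  dependable motif recovery requires a few thousand optimization steps. Two
  consequences are visible in the test suite at that schedule: the in-band
  spectral contrast between the with-prior and no-prior models is within
  seed noise (it separates clearly at eight epochs, as the acceptance
  script's longer run shows), and zero-shot LLRs of motif-disrupting
  variants are dominated by a base-composition artifact — the G/C-rich
  motif consensi sit in an A/T-rich background, so a composition-level
  model scores a consensus-to-worst substitution *positively*
  (≈ ln(0.30/0.20)); the sign only reverses once motif likelihoods are
  genuinely learned.
- Single CPU, float32; no mixed precision, no distributed training, no
  learning-rate schedules beyond constant.
- Indels and multi-allelic variants are out of scope; variant records are
  biallelic SNVs.
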