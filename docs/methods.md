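# Methods

## The modelling problem

Given a fixed-length genomic DNA window, predict the read-coverage
profiles of many functional-genomics experiments (RNA-seq, CAGE,
DNase-seq, 3' RNA-seq, ...) simultaneously, as nonnegative rates over
fixed-width bins.  The reference geometry is a 393,216-bp window pooled
to 32-bp bins (12,288 bins), with 2,048 bins cropped from each end before
the loss so edge effects do not dominate; every constant is configurable
through `DataConfig` / `ModelConfig`, and the package's verified desk
scale uses 8,192-bp windows, 256 bins, a 32-bin crop and eight tracks.

## Data transforms

**Squash transform.**  Coverage is compressed before modelling by
`min(x^{3/4}, 384) + max(0, x^{3/4} − 384)`, implemented exactly as that
two-branch expression.  Algebraically the branches sum to `x^{3/4}`; the
two-branch form matters when the above-threshold term is soft-clipped, a
behaviour earlier coverage models used, so `squash` exposes an optional
`clip_exponent` applied to the excess term (default off, i.e. the plain
printed form).  Both variants are strictly monotone and exactly
invertible by `unsquash`.

**Binning** is sum-pooling: coverage is count-like and the Poisson loss
expects counts, so bins conserve totals exactly.  **Cropping** removes a
fixed number of bins from each end, after binning and before the loss.

**Augmentation.**  (1) Reverse complementation: the sequence is
reverse-complemented, every track's bin order is reversed, and each
forward-oriented track exchanges values with its reverse partner
(unstranded tracks are only reversed).  This is an exact involution.
(2) Small shifts: the one-hot rows are translated by up to ±3 bp with
vacated rows zero-filled, while output bins are left untouched — the
model must tolerate sub-bin phase jitter.  Ambiguous (N) bases also
encode as all-zero rows, the same convention as shift-vacated positions.

**Folds and splits.**  Windows are shuffled once (seeded) and dealt into
six near-equal contiguous blocks; rotation r uses fold r as test and fold
r+1 as validation, giving four rotations with pairwise distinct test and
validation folds in a 4:1:1 ratio.  Whether folds should respect
chromosome contiguity is left to the caller (the shuffle is over whatever
window list is supplied); the generator's synthetic windows are
independent, so contiguity has no meaning there.

## Layers

All sequence layers are residual and shape-preserving over a (L, d_model)
embedding produced by the convolutional trunk (norm → GeLU → convolution
→ twofold max-pool per block; five blocks take one-hot input to 32-bp
resolution).  Because training operates on single sequences (batch size
2 via gradient accumulation), the trunk's "batch" normalisation computes
per-channel statistics over the length axis of the example at hand.
The trunk's channel schedule is configuration: the full-scale default
interpolates geometrically from 4 to d_model; the desk-scale preset
starts at d_model/2 so the first convolution has enough motif detectors
at small width.

**Selective SSM (Mamba-style).**  Per expanded channel, a diagonal
linear recurrence `h_t = exp(Δ_t A) h_{t−1} + B̄_t x_t`, `y_t = ⟨C_t,
h_t⟩`, where Δ_t (softplus-positive), B_t and C_t are projections of the
input.  A is parameterised as −exp(A_log), initialised to −(1..N) per
channel; Δ's bias is drawn so the initial step sizes span ≈[1e-3, 1e-1].
B̄ uses the simplified Euler rule Δ_t·B_t by default with full
zero-order-hold behind a flag (`zoh=True`); the two agree to first order
in Δ and the Euler form avoids a division by A.  The recurrence is
evaluated by an associative parallel scan (combine (a₁,b₁)∘(a₂,b₂) =
(a₁a₂, a₂b₁+b₂)), with the sequential recurrence kept as the oracle; a
`checkpoint_every` chunk size changes the schedule, never the values.
The scan's adjoint is itself a reverse-time scan, implemented as a custom
vector-Jacobian product.  A short depthwise convolution (width 4)
precedes the scan.  The bidirectional layer adds a second scan on the
length-reversed sequence with its own scan parameters but a *tied* input
projection; what a "reverse-complement operation" should mean on interior
feature channels is genuinely underdetermined, so the backward branch
applies a configurable channel permutation at the tied projection,
defaulting to identity (interior embeddings carry no base-complement
structure).  The two branch outputs are summed before a shared
GeLU-gated output projection; disabling the backward branch recovers the
causal layer exactly.

**Gated long convolution (Hyena-style).**  LayerNorm, a projection to
order+1 branches each passed through a short nearest-neighbour
convolution (depthwise by default; a `channel_mixing` flag makes them
dense) and SiLU, then `order` rounds of elementwise gating interleaved
with FFT long convolutions whose length-L kernels are generated
implicitly by a SIREN (two sin-activated hidden layers of width 32,
ω=30) and windowed by a learnable per-channel exponential-decay
envelope.  Order defaults to 2.  The convolution is linear (length-2L
transforms, never circular); bidirectional mode aligns kernel index L/2
with lag zero so both flanks contribute, causal mode aligns index 0.

*Initialization.*  A SIREN drawn for unit output variance makes the long
convolution's output variance grow ∝ L, which compounds across stacked
layers — an eight-layer stack visibly explodes.  The final SIREN layer is
therefore drawn with variance ∝ 1/L (only the final layer carries the
rule).  Both behaviours are kept so the regression test can demonstrate
the pathology and its fix.

**Attention.**  Pre-LayerNorm multi-head softmax attention (4 heads,
query/key width 64 at full scale) with a pointwise feed-forward sublayer
(expansion 2, GeLU).  Three positional modes: none (permutation-
equivariant), rotary embedding (scores depend only on the query−key
offset), and additive logits from geometrically-spaced threshold
indicators of the separation (32 features, symmetric + signed halves).
Attention can be computed over key chunks with running max/denominator
accumulation (flash-style); chunking is exactly value-preserving and is
verified against dense attention.  A U-Net wrapper max-pools the
embedding 1–2 rounds before the attention stack and upsamples back by
nearest-neighbour repeat plus a pointwise linear combined additively with
the saved skip — additive rather than concatenating, which keeps the
wrapper width-preserving and is the cheaper of the two standard choices.

## Loss

Per track, with predicted rates λ_i over cropped bins and observed
(squashed) counts x_i, Λ=Σλ, X=Σx:

    loss = [Λ − X log Λ]  +  w · [−Σ_i x_i log(λ_i / Λ)]

a Poisson term on the track total plus a multinomial term on the
positional distribution.  At w=1 the gradient equals that of independent
per-bin Poisson likelihoods exactly (verified numerically); training
defaults to w=4, upweighting positional accuracy.  The head is an affine
map with softplus plus a floor of 1e-6, guaranteeing strictly positive
rates.

## Training

Adam (β₁=0.9, β₂=0.999), linear warm-up then constant learning rate,
two-stage gradient clipping — each named layer group (conv block, Mamba
layer, attention block, head) to norm 5.0, then the global norm to 10.0 —
L2 regularisation at 1e-6, batch size 2 by gradient accumulation, both
augmentations applied per example, epochs defined as one pass over the
shuffled training windows, and early stopping on validation mean Pearson
r with patience 5 (the stopping metric's patience is a package choice;
only "stopping on validation metrics" is inherited).  Everything is
deterministic given the seed.

The full-scale schedule (lr 1e-4, 10,000 warm-up steps) is sized for
multi-week runs over thousands of tracks.  The desk-scale preset
(`desk_train_config`) uses lr 2e-3 with a 100-step warm-up: a ~160k-
parameter model on a ~100-window corpus needs its optimizer scaled to a
few-hundred-step budget, and these are ordinary small-model Adam
settings, fixed once.

## Synthetic corpus

The generator emulates the causal chain the real task assumes: sequence
→ regulatory elements → assay-specific coverage.  Motif occurrences
(exact consensus matches, both strands) deterministically add per-assay
kernels to a background of 0.5 counts/bin: a CAGE point source at the
motif, an RNA block over the 24 bins downstream, a 3'-RNA point at the
block's end, a smooth symmetric DNase peak, all oriented by match strand;
stranded assays drive the track of the matching orientation, unstranded
assays receive both.  Observed coverage is Poisson-sampled from these
rates.  Kernel amplitudes are quantised to multiples of 1/64 so that
overlapping-kernel sums are exact in floating point, making the
strand-exchange symmetry of the rates bit-exact — which is what makes the
equivariance and augmentation tests sharp.  The default desk corpus uses
96 windows of 8,192 bp with on average eight planted instances per window
(a gene-dense regime), enough motif occurrences (~750 in the training
split) for a small model to generalise within a few hundred steps.

Because rates are a pure function of sequence (matches are re-scanned,
not remembered), variant effects are exactly consistent: an effect
variant mutates a base inside a match, a null variant mutates background
verified to leave the rate field bit-identical, and the truth table
records the recomputed rate change.

What the generator does **not** emulate: chromatin-state spatial
correlation, splicing structure, GC/mappability biases, overdispersion
beyond Poisson, linkage between variants, and degenerate (PWM-soft)
motif matches.  Passing tests therefore demonstrate that the
architecture, loss, augmentation and scoring machinery can recover a
known sequence→coverage mapping from count noise at desk scale — not
that any particular accuracy carries over to real genomes.

## Variant scoring

For a single-base substitution, each ensemble member predicts all tracks
for the window under both alleles; per track the per-bin differences d
and log-ratios ℓ (pseudocount 1e-6) are summarised as sign(Σd)·log(1+|Σd|)
— a signed-log chosen to preserve direction while compressing scale,
since the summary is named but not specified precisely in the source
protocol — and √(Σℓ²).  Summaries are computed on the modelling
(squashed) scale, before any unsquashing.  Features concatenate across
ensemble members and feed a random forest (1000 trees, seeded); AUROC is
computed on out-of-fold probabilities from stratified 5-fold
cross-validation, and Spearman correlates classifier score with the true
effect magnitude (standing in for a fine-mapping probability).

## Metrics

Pearson r and r² (1 − SSE/SST) per track over bins concatenated across
windows, averaged over defined tracks and grouped by assay;
zero-variance observed tracks are flagged undefined and excluded with a
count.  Per-window-then-average Pearson is a reasonable alternative
reading of the benchmark protocol; concatenated-bins is the default here
because it is the stricter of the two (a model cannot score well by
ranking windows alone).

## Numerical choices

float64 is the default dtype; `Module.astype(np.float32)` casts a model
for training (half the memory traffic, ~2× faster, and the scan/attention
oracles bound the 32-bit error at 1e-4/1e-5).  Softmax subtracts a
detached running max.  Max-pool ties send gradient to the first argmax.
The rate floor (1e-6) and log pseudocounts (1e-9 in the loss, 1e-6 in
log-ratios) guard the logs.  Degenerate inputs are rejected loudly:
non-IUPAC characters with their position, malformed BedGraph/VCF records
with their line or record number, nonpositive Δ, negative counts,
over-cropping, broken strand pairings.

## Known limitations

Single-sequence processing (no batched tensors) keeps the code simple
but leaves BLAS under-fed at small d_model; the desk scale is sized
around that.  The bidirectional SSM is only approximately equivariant
(tied input projections, not a fully equivariant construction).  Training
at the full 393k-bp, 768-channel, thousands-of-tracks scale is out of
scope: the package verifies that geometry only through shape-level
forward passes.  Indels, multi-allelic variants and fine-mapping itself
are out of scope for the variant pipeline.
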