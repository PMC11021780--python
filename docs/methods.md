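# Methods

## The segmentation problem

Gliomas appear in multi-parametric MRI as heterogeneous lesions whose
sub-compartments — peritumoral edema, necrotic core, and the
contrast-enhancing rim — have different signatures across the four standard
contrasts (FLAIR, T1, T1-weighted post-contrast T1ce, T2).  The evaluation
regions used throughout are nested unions of the raw labels {0 healthy,
1 necrotic, 2 edema, 4 enhancing}: whole tumor WT = {1,2,4}, tumor core
TC = {1,4}, enhancing tumor ET = {4}.

## Model

### Coarse-to-fine cascade

Two encoder–decoder (U-Net style) 3-D networks are cascaded.  Stage 1 maps
the 4-channel modality stack to 4-class logits.  Its channelwise softmax
probabilities are concatenated with the input (8 channels) and refined by
stage 2.  Fusing probabilities rather than hard labels keeps the cascade
differentiable, so the joint loss

    L = 0.5·L_CE(stage 1) + 0.5·L_CE(stage 2) + L_DC(stage 2)

trains both stages end-to-end (verified by a gradient test: stage-1
parameters receive gradient through stage 2).

Each stage has four resolution levels.  An encoder level is two 3³
convolutions, each followed by group normalization (8 groups — batch sizes
of ~3 make batch statistics unreliable) and a rectifier; levels are
separated by 2³ max-pooling.  Skip (lateral) features are taken before each
pooling.  The decoder mirrors this with trilinear 2× upsampling, a pointwise
channel projection, concatenation with the lateral feature, and another
double-convolution block.  Channel widths double per level from a base width
of 16: 16/32/64/128 with a 256-channel bottleneck.  This geometry is forced
by the reference configuration: a 128³ input yields a fourth (deepest)
lateral tensor of 128 channels × 16³, which is exactly what the attention
block receives.  Spatial sides must be divisible by 16.

### Expectation–maximization attention (stage 2, fourth lateral)

Pairwise non-local attention over N = D·H·W voxels is quadratic in N; the EM
variant instead iterates a compact dictionary μ ∈ R^{D×K} of K bases:

* E step: responsibilities `A = row-softmax(Xᵀμ)` (N×K), unit scaling;
* M step: `μ_k ← Σ_n A_nk X_n / (Σ_n A_nk + ε)`, then each column is
  L2-normalized (the "maintenance" that keeps logits bounded);
* after t alternations the features are reconstructed as the rank-≤K
  product `X̃ = μAᵀ`.

t = 3 by default.  The block wraps the loop with two pointwise convolutions
and a residual sum: `x + conv_out(reconstruct(EM(conv_in(x))))`.  The inner
loop runs outside the gradient graph — responsibilities and bases are
treated as constants — so only the pointwise convolutions learn.  A
consequence worth stating plainly: the input-side pointwise convolution
receives no gradient through the EMA branch (its output only feeds the
detached loop); gradient reaches the preceding encoder through the residual
connection.  This is the intended trade: an iterative inner loop inside the
gradient graph is a training-stability hazard.

Basis maintenance across training: after each training forward the converged
bases are folded into a persistent global set by an exponential moving
average with momentum 0.9 (one fold per sample), and the global set seeds
the next iteration; at inference the global bases are used and never
updated.  K = 64 by default at full width (configurable; the desk-scale
tests use 8).

Initialization matters when t is small.  Random Gaussian bases occasionally
start two bases in a near-tie for the same feature mode; three alternations
cannot break the tie and the mode's responsibility stays split (observed in
roughly a quarter of random seeds on a 4-cluster benchmark).  For
clustering-style use the package therefore provides distance-spread seeding
(`init_bases_from_data`, the k-means++ scheme: each new basis drawn from the
data with probability proportional to squared distance from the chosen set),
which resolved every seed in a 300-seed study.  The network layer keeps
Gaussian init — its bases are maintained across thousands of updates, where
init is immaterial.

### Dynamic convolutions (stage 2, all 3³ convolutions)

Each dynamic layer holds K parallel kernels (default 4) and a
squeeze-and-excitation head: global average pooling, a bottleneck
fully-connected pair (reduction 4) with a rectifier, and a softmax with
temperature τ producing mixture weights π (Σπ = 1).  The kernels are
aggregated *before* convolving — `W̃ = Σ_k π_k W_k` — which by linearity
equals mixing the K convolution outputs at 1/K the cost; the expanded form
is kept as the test oracle.  π is computed per sample even in batches.  The
aggregation is linear in the kernels; the layer's nonlinearity is entirely
π's dependence on the input.  τ is annealed linearly from 30 to 1 over the
first 30 % of training steps (then held at 1) so that early training does
not collapse onto a single kernel.

## Losses

Cross-entropy is the voxel mean of −Σ_i x_i log x̂_i (mean, not sum, so the
value is independent of crop size), stabilized by log-sum-exp.  The Dice
loss is soft (softmax probabilities), per-class smoothed with ε = 1e-5 in
numerator and denominator, computed over the three foreground classes only
and averaged; including background would let empty space dominate exactly
the imbalance the term exists to fix.  The composite weights (0.5, 0.5, 1.0)
are exposed for ablation; there is deliberately no stage-1 Dice term.

## Preprocessing and augmentation

Intensities are z-scored per modality and per case over nonzero voxels only
(inputs are skull-stripped; background would otherwise dominate the
statistics), with the population (1/N) standard deviation; background stays
exactly zero.  A channel with vanishing spread (< 1e-8) is zeroed with a
warning.  Whether statistics should be per-case or dataset-wide is an open
choice; per-case is used, matching common practice for scanner-varying
cohorts.

Training patches (default 128³, tests use 32³) are random crops; with
probability 0.5 the crop centers on a uniformly drawn tumor voxel when one
exists, countering class imbalance.  Augmentation is label-safe by
construction: per-axis flips (p = 0.5 each), 90°-multiple rotations in the
axial plane (p = 0.5), and an affine intensity jitter on the inputs only
(scale ~ U(0.9, 1.1), shift ~ U(−0.1, 0.1) on normalized intensities).
Magnitudes are package defaults — reasonable for z-scored data — not
reported values.

## Training and inference

AdamW with learning rate 1e-3, first-moment decay 0.95 (second moment
0.999), decoupled weight decay 1e-5; batch size 3; 550 optimizer steps by
default.  "Iterations" are optimizer steps.  The learning rate is constant.
A non-finite loss aborts with a diagnostic.  Every random draw (weights,
crops, augmentation, phantoms) descends from one seed.

Full volumes are segmented by sliding a crop-sized window at 50 % overlap,
averaging stage-2 softmax probabilities over overlapping windows, taking the
voxelwise argmax and mapping class 3 back to raw label 4.  Volumes smaller
than the window are zero-padded and un-padded afterwards.

## Evaluation metrics

Dice uses the count form 2TP/(FP + 2TP + FN).  HD95 is the 95th percentile
of the pooled symmetric surface-distance set, computed via exact Euclidean
distance transforms; surfaces are mask voxels with a 6-connected background
neighbor (array borders count as background).  Pooling (rather than taking
the max of two directed percentiles) is one of several HD95 conventions in
circulation; it is symmetric by construction and is validated against an
exhaustive pairwise-distance oracle in the tests.  Conventions for empty
masks are explicit because low-grade gliomas may lack enhancing tumor: both
empty → Dice 1, HD95 0; exactly one empty → Dice 0, HD95 undefined (NaN,
excluded from means and counted), with an optional fixed-penalty variant.

## Synthetic phantoms

The generator emulates the BraTS layout — four co-registered contrasts plus
labels, NIfTI files named `<case>_{flair,t1,t1ce,t2,seg}.nii.gz` — with
concentric-ellipsoid tumors inside a spherical brain: an edema shell around
a necrotic rim around an enhancing nucleus, guaranteeing ET ⊆ TC ⊆ WT.
Intensities are compartment means plus Gaussian noise (default sd 10 against
compartment separations of 40–120), clipped at zero, zero outside the brain.
Default contrasts follow qualitative radiology (edema brightest on
FLAIR/T2, enhancement brightest on T1ce, necrosis dark on T1/T1ce).

What the phantoms do *not* model: MRI physics, bias fields, partial-volume
gradients, irregular or multi-focal lesions, inter-scanner variation.
Passing the end-to-end test therefore shows that the architecture, losses,
optimization and inference plumbing can jointly fit a well-posed volumetric
task — it says nothing about accuracy on clinical data.

## Desk-scale test conditions

The test suite and the acceptance script run a reduced configuration chosen
for CPU execution: 48³ phantom grids, 32³ crops, base width 8, 2 dynamic
kernels, 8 EM bases, 300 optimizer steps on 4 training phantoms with 2 held
out.  At this scale training takes on the order of ten minutes on one core
and reaches whole-tumor Dice ≥ 0.85 on the held-out phantoms.

## Numerical choices

* All network arithmetic is float32 on a numpy reverse-mode autodiff engine
  (`autodiff.py`); z-score statistics accumulate in float64.
* M-step denominator ε = 1e-6; a basis receiving no responsibility keeps its
  previous value.  Dice smoothing ε = 1e-5.  Group-norm ε = 1e-5.
* Max-pooling gradient follows the first argmax on ties.  Trilinear
  upsampling is half-voxel aligned with clamped edges; its backward is the
  exact adjoint.
* He (Kaiming) initialization throughout; biases start at zero.

## Known limitations

* Single-sample layer semantics with a Python-level batch loop: correct (and
  required for per-sample kernel attention) but not vectorized across the
  batch.
* Full 240×240×155 BraTS volumes are supported by the sliding-window path
  but CPU inference at that scale is slow; the package targets method study
  and desk-scale verification, not clinical throughput.
* EM iterations are excluded from the gradient graph by design (see above);
  an optional differentiable variant is not provided.
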