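# Methods

`hemignn` implements a cross-subject EEG classifier for major depressive
disorder (MDD) built around a structural prior: the two cerebral hemispheres
are modeled as separate functional graphs whose node signals interact only
within a hemisphere, and the two hemisphere summaries are fused by attention
at the very end. This note records the model, its assumptions, the synthetic
data it is validated on, and the numerical choices a maintainer would want to
know about.

## Model

One classification unit is a 2 s window `X ∈ R^{C×T}` of a 19-channel 10–20
recording at 256 Hz (`C = 19`, `T = 512`), in microvolts.

**Multi-scale temporal filter (MSTF).** Three parallel depthwise 1-D
convolutions with receptive fields of 0.4, 0.2 and 0.1 s. Kernel lengths are
`odd(α · f_s)` — floor, incremented to the next odd integer — giving
103/51/25 samples at 256 Hz, so symmetric same padding is exact. Each branch
is batch-normalized per channel (over batch × time) and ELU-activated; the
branch outputs are averaged:

    X_m = ELU(BN(DWConv_{k_m}(X))),   X^(1) = mean_m X_m ∈ R^{C×T}.

Depthwise means channels never mix here; all spatial interaction is deferred
to the graph stage. Any non-empty subset of the three scales is a valid
configuration (ablation axis `mstf.scales`).

**Hemispheric partition.** The 19 channels are split into left
(Fp1 F7 F3 Fz T3 C3 Cz T5 P3 Pz O1) and right
(Fp2 F8 F4 Fz T4 C4 Cz T6 P4 Pz O2) groups of `N = 11`; the midline trio
Fz/Cz/Pz belongs to both, carrying bilateral activity into each hemisphere
graph. Anterior–posterior, four-region and full-brain partitions are
available for ablations. T3/T4/T5/T6 are treated as equivalent to the modern
T7/T8/P7/P8 labels.

**Per-region graph.** For each region slice `X_i^(1) ∈ R^{N×T}` (recomputed
for every window — the graphs are adaptive, data-derived, and carry no
trained parameters):

1. rows are L2-normalized; pairwise inner products give cosine similarities;
2. negative entries are zeroed (ReLU) and the self-similarity diagonal is
   excluded so it cannot consume a sparsity slot;
3. each row keeps its `K = 10` largest positive entries (ties break toward
   the lower column index, for cross-platform determinism);
4. the directed result is symmetrized by element-wise maximum (preserving
   every retained edge; mean-symmetrization is a config alternative);
5. `L = I − D^{−1/2} A D^{−1/2}`; zero-degree nodes use `D^{−1/2} = 0`,
   leaving identity rows, so the spectrum stays in `[0, 2]`.

Gradients do not flow through graph construction; node features alone carry
the learning signal.

**Node-wise temporal embedding.** Per region, each node's time course is
encoded independently: two per-node convolution stages (1 → C1 = 16 →
C2 = 32 channels, time extent 7, ReLU), a per-node scoring convolution
(C2 → 1) whose softmax over time yields attention weights summing to one per
node, an attention-weighted sum over time, and a shared linear map
C2 → T1 = 64. Per-node weight groups are tied to electrode labels, so a
permuted channel ordering resolves to the same function (this is what the
permutation-equivariance test exercises).

**Chebyshev graph convolution.** Two stacked residual layers

    X ← LN(X + Dropout(ReLU(ChebConv(X)))),

with order-3 Chebyshev filters `Σ_{p<3} T_p(L̃) X Θ_p`, `T_0 = I`,
`T_1 = L̃`, `T_p = 2 L̃ T_{p−1} − T_{p−2}`, using the scaled operator
`L̃ = L − I` (i.e. `λ_max` fixed at its upper bound 2 rather than computed
per graph — deterministic and cheap on per-window graphs). The residual
forces the hidden width to stay `T2 = T1 = 64`. Dropout rate 0.2, active
only in training. Node embeddings are then mean-pooled into a region vector
`X_i^(4) ∈ R^{T2}`.

**Attentive fusion and classification.** Region vectors are stacked,
scored by a single shared linear map, softmax-normalized into weights `w`
(so `Σ w = 1`, and identical regions get equal weights), and combined as
`X^(6) = w^T X^(5)`. Alternatives for ablation: plain average, element-wise
max, concatenation + widened classifier. The fused vector is
layer-normalized ("normalized" is otherwise unspecified; LN is consistent
with the graph blocks) and mapped linearly to two class scores; MDD is the
positive class (index 1). The loss is window-level cross-entropy; cohorts
are balanced by construction so no class weighting is used.

## Evaluation protocol

Subjects are matched into MDD–HC pairs (seeded random matching; the pairing
is recorded in the output). Leave-one-pair-out: each fold tests on every
window of one pair and trains on all other pairs' windows, so evaluation is
strictly cross-subject. Within a fold, 20% of training windows are split off
as a validation set — window-level and class-stratified, following the
protocol's wording; note this mixes a subject's windows across train and
validation, which is optimistic for checkpoint selection but faithful.
Training: Adam (lr 0.001), cosine annealing to 1e−6 with period 50, batch 64,
at most 50 epochs, early stopping after 10 epochs without validation-loss
improvement; the checkpoint with the best validation accuracy (ties → lower
loss) is restored before testing.

Metrics are computed from window-level confusion counts: accuracy,
sensitivity (MDD recall) and specificity as percentages, and the F-measure
`2·TP / (FP + FN + 2·TP)` as a fraction. Zero-denominator metrics are NaN,
not errors. Fold means are reported with sample standard deviations
(ddof = 1); the pooled confusion matrix is also summarized (for equal-sized
folds the pooled accuracy equals the fold mean; the F-measure is nonlinear,
so its pooled and fold-mean values differ). Runs are compared with one-sided
paired t-tests on fold-wise accuracies; zero-variance differences are
flagged degenerate with `p ∈ {0, 0.5, 1}` by sign.

## Synthetic cohorts

Real clinical recordings cannot ship with the package, so every end-to-end
claim is validated on a generator whose stated world is:

- 19 channels at 256 Hz; one eyes-closed and one eyes-open recording per
  subject; `n_pairs` MDD and `n_pairs` HC subjects;
- background noise: spectrally shaped Gaussian `1/f^β` with `β = 1`,
  10 µV RMS per channel, partially shared across channels through 4 common
  pink sources mixed at amplitude fraction 0.5 (chosen so within-window
  cosine-similarity graphs are nontrivial rather than near-diagonal);
- an alpha oscillation: a sinusoid at a subject-specific peak drawn from the
  middle of the 8–12 Hz band, random phase per channel, RMS = `snr` × noise
  RMS;
- the planted class signal: for MDD subjects the alpha amplitude is scaled
  by `effect^(−1/4)` on left-lateral and `effect^(+1/4)` on right-lateral
  electrodes, so the right/left alpha **power** ratio equals
  `asymmetry_effect`; midline channels and HC subjects are untouched. This
  emulates the lateralized alpha abnormalities reported in depression.

Limitations a green test does **not** speak to: no blink/EMG artifacts, no
volume-conduction head model, a single sinusoidal rhythm rather than
broadband oscillatory dynamics, and stationary statistics within a
recording. The generator validates the pipeline's mechanics and its ability
to recover a known lateralized signal — not clinical performance.

## Scaled-down recovery experiments

The signal-recovery acceptance tests run the full protocol (6 pairs,
`asymmetry_effect = 4`, `snr = 1`, 15 epochs, 3 seeds, complete architecture
and 2 s/256 Hz windows) but on 16 s recordings (12 s analysis segment → 6
windows per recording) instead of 5-minute ones, chosen purely so 24 fold
trainings fit a single-CPU budget; the default generator duration stays
200 s so the 180 s mid-segment extraction is exercised elsewhere. Because
the batch size governs how many optimizer steps an epoch contains, it is
scaled down together with the data (64 × 12/180 ≈ 4, set to 8): with the
full-size batch a scaled epoch would collapse to two Adam steps and 15
epochs would terminate far from convergence, which tests the scaling, not
the model. With batch 8 a fold performs 180 steps — still an order of
magnitude fewer than the full-scale protocol. The
no-signal sanity check compares pooled accuracy against the 95% binomial
band around 0.5 with `n = 12` — the number of held-out subjects — because
windows within one subject are strongly dependent and the window count would
wildly overstate the effective sample size. Full-run determinism is checked
on a 2-pair, 3-epoch experiment: byte-identical summaries are a scale-free
property.

## Numerical and engineering choices

- The network runs on a small in-package reverse-mode autodiff engine over
  numpy (float32), with FFT-based depthwise convolutions and per-node
  im2col + GEMM grouped convolutions; every custom gradient is verified
  against float64 central finite differences in the test suite.
- Filtering: 4th-order Butterworth band-pass (0.5–70 Hz) plus an IIR notch
  (50 Hz, Q = 30), both applied forward–backward (zero phase). An optional
  common-average reference stands in for reference-free schemes that would
  need a head model. ICA-based artifact rejection is out of scope.
- Batch-norm running statistics use the biased variance with momentum 0.1;
  evaluation uses the running estimates.
- All randomness (weights, splits, batching, dropout, pairing, generator)
  derives from explicit integer seeds through `numpy.random.SeedSequence`;
  two runs with the same seeds serialize byte-identically on one platform.
- EDF support is a minimal 16-bit reader/writer for continuous recordings
  (1 s records, per-signal linear scaling); delimited text with a
  channel-name header is the second interchange format. Channel matching is
  case-insensitive with the legacy/modern alias table.
- On import the package asks glibc to keep large freed blocks on the heap
  (`mallopt`); repeated allocation of tens-of-MB activation arrays otherwise
  spends most of its time page-faulting freshly mmapped memory.
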