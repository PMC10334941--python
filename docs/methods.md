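# Methods

`tripoint` implements a knowledge-integrated, semisupervised approach to
dermoscopic lesion classification: a convolutional network is trained not
only on melanoma / melanocytic-nevus labels but also on the three criteria
of the 3-point checklist (asymmetry, atypical pigment network, blue-white
structures) and on the checklist's diagnostic rule itself, encoded as a
pairwise ranking constraint. A mean-teacher consistency term extends the
training signal to images that carry no checklist annotation.

## Model

One convolutional trunk ends in global average pooling; two linear heads
read the pooled representation:

* a 2-way softmax head for the disease label;
* a 3-way independent-sigmoid head for the checklist features.

The melanoma logit of the disease head is denoted `f(x)`. Two backbones are
provided: `tiny_cnn` (four stride-2 conv/BN/ReLU blocks, 64×64 input,
~30k parameters — the default for CPU-scale work) and `resnet18_style`
(a narrow ResNet-18-shaped trunk of basic blocks with identity/projection
shortcuts). The feature heads share the pooled representation with the
disease head; perturbing one head never changes the other head's output.

The network engine is a compact numpy implementation with hand-written
backward passes (im2col convolution, batch normalization, SGD with
classical momentum). This keeps every gradient analytically transparent;
the combined-loss gradient is verified against central finite differences
on a float64 probe (max relative error ~4e-7, tolerance 1e-4).

## Training objective

Four terms are combined as `λ_dsl·DSL + λ_fsl·FSL + λ_rl·RL + λ_cl·CL`;
a term with zero coefficient is skipped entirely and never touches the
labels it would need.

**DSL** — mean softmax cross-entropy on the disease head.

**FSL** — mean sigmoid binary cross-entropy per feature head, with
per-feature weights normalized to sum to 3 (so `(1,1,1)` is unweighted and
`(2,1,1)` is the asymmetry-emphasis variant).

**RL (ranking loss)** — for every unordered pair (i, j) in a batch with
checklist scores s_i, s_j (the score is the number of positive features,
0–3), let o_ij = f(x_i) − f(x_j) and P_ij = σ(o_ij). The target posterior
P̄_ij is 1 if s_i > s_j, 0 if s_i < s_j, ½ on ties; the pair cost is the
cross-entropy −P̄·log P − (1−P̄)·log(1−P), computed in the stable form
−P̄·o + log(1+e^o), and the loss is the mean over pairs. This pushes the
melanoma-logit ordering to match the checklist's "higher score, more likely
malignant" rule. Ties are kept (with target ½) rather than dropped, and the
mean (not sum) over pairs keeps λ_rl comparable across batch sizes. The
loss depends only on logit differences and is invariant to relabeling a
pair's order.

By default the ranking pairs come from the feature-annotated portion of the
batch; an optional mode (`ranking_source="teacher"`) also scores unlabeled
samples with the teacher's hard-thresholded (σ(z) > 0.5 ⇔ z > 0) feature
predictions, letting predicted checklist features participate in training.

**CL (consistency loss)** — student and teacher each see an independently
augmented view of the same batch; each head's logits are mapped to
probabilities (softmax / sigmoid) and the cost is the per-head mean squared
difference, summed over heads (a disease-only mode exists). Teacher outputs
are constants — no gradient flows to the teacher. λ_cl ramps linearly over
the first 20% of training steps, following mean-teacher practice.

**Teacher** — a structural copy of the student updated only by exponential
moving average, θ′ ← α·θ′ + (1−α)·θ, after every optimizer step, with
α = 0.99 by default. During early training the effective decay is warmed up
as min(α, (t+1)/(t+10)) so the teacher tracks the student away from its
random initialization; without this, desk-scale runs (a few hundred steps)
end with a teacher still anchored to noise. The teacher branch is the
default evaluation predictor, consistent with the mean-teacher scheme; the
student can be scored instead. Batch-norm running statistics follow the
same EMA rule so the teacher's evaluation-mode behaviour tracks the data.

**Optimization** — SGD (momentum 0.9, learning rate 0.01 — the named
optimizer's conventional setting; neither value is prescribed by the
training protocol, which fixes only the schedule), reduce-on-plateau
schedule (mode min, factor 0.5, relative threshold 0.01, patience 7)
monitoring the combined validation loss over the enabled supervised terms
(for a consistency-only configuration, the student–teacher disagreement is
monitored instead). Batches mix labeled and unlabeled samples at a
configurable labeled fraction (default 0.5). The study-scale batch size is
128; the desk-scale default is 64. Augmentation is independent horizontal /
vertical flips per branch.

## Preprocessing

1. **Crop/resize** — the largest centered square crop, then a bilinear
   resample to the target side. Center-square (rather than lesion bounding
   box) is chosen because dermoscopic framing keeps the lesion central; a
   square input already at the target passes through untouched.
2. **Shades-of-Gray color constancy** — the illuminant is estimated per
   channel as the Minkowski p-mean of intensities, m_c = (mean I_c^p)^{1/p};
   gains m̄/m_c (m̄ the channel average of the p-means) map the illuminant
   to neutral gray while preserving brightness. p = 1 reduces exactly to
   Gray World, p → ∞ to max-RGB; the default p = 6 is the canonical
   setting of the comparison literature on dermoscopic color constancy.
   After correction the per-channel Minkowski means are equal (pre-clip).
3. **CLAHE** — contrast-limited adaptive histogram equalization applied to
   the CIELAB lightness channel only, preserving hue; with one tile and an
   unbounded clip limit it reduces to global histogram equalization.

All stages run in floating point; quantization happens once, at file
output. Stage order is crop → color constancy → CLAHE and is
config-overridable for ablation.

## Synthetic data generator

Archive dermoscopy cannot ship with a test suite, so the generator renders
lesion-on-skin images in which each checklist feature is an independently
switchable, machine-detectable cue:

* *asymmetry* — the boundary radius on one angular half of the lesion is
  inflated ~1.5×, smoothly ramped across a random dividing axis;
* *atypical network* — a darker sinusoidal reticular mesh over the lesion;
* *blue-white structure* — a soft blue-gray Gaussian blob inside the lesion.

Feature flags are drawn independently at prevalence 0.5 (maximizing pair
diversity for the ranking loss). The disease label is drawn from a logistic
model on the checklist score, P(melanoma | s) = σ(β0 + β1·s) with defaults
β0 = −2.2, β1 = 1.5 — so the checklist rule is true by construction
(P rises from 0.10 at s=0 to 0.91 at s=3) and the ranking loss has a real
signal to exploit. A melanoma-specific darkening of the lesion body
(strength 0.35) gives the disease head signal beyond the checklist ceiling,
so disease supervision is not redundant with feature supervision. A random
per-channel multiplicative cast in [1−c, 1+c] (c = 0.15) is applied last,
giving the color-constancy stage real work; the cast-free render is
retained internally as an exact reference.

The default dataset emulates the study design: 900 feature-annotated images
balanced 450/450 between the classes (by rejection sampling against
per-class quotas), split 80/20 into train/validation; a disease-only
unlabeled pool (desk-scale default 2000); and a balanced, fully annotated
400-image holdout, disjoint from everything else. The whole dataset is a
pure function of (config, seed). A 10-nearest-neighbor classifier on 8×8
downsampled pixels separates every feature at AUC > 0.7 on 500 samples —
the cues are detectable before any deep model is blamed for missing them.

**What the generator does not emulate:** photorealism, hair/ruler
artifacts, skin-tone diversity, inter-annotator label noise, and the
long-tailed acquisition variability of archive data. Passing mirror
experiments therefore shows that the losses, the training scheme and the
plumbing behave as designed — not that study-scale accuracy transfers to
real dermoscopy.

**CLAHE and the synthetic cue:** the melanoma darkening cue is a global
brightness difference of the lesion body, and per-image lightness
equalization removes precisely that kind of signal; with the full 3-stage
chain the disease head stalls near chance, with crop + color constancy it
reaches ~0.9 accuracy. The mirror experiments therefore feed the model
crop + color-constancy outputs. This is a property of the synthetic cue,
not of the preprocessing chain, which remains fully implemented and tested.

## Evaluation

Per-head accuracy (feature probabilities thresholded at 0.5) and ROC AUC
(raw probabilities; Mann-Whitney formulation with half credit for ties);
mean and sample SD (n−1) across the 5 stratified cross-validation folds.
Cohen's kappa, (p_o − p_e)/(1 − p_e), is computed per feature and pooled
across the three features (the annotation protocol's single agreement
figure does not say which aggregation it used, so both are reported), and
the two-annotator + third-adjudicator majority vote is provided: where the
first two agree the third is ignored.

## Desk-scale experiment sizes

The mirror experiments use the tiny backbone at 64×64: one FSL run at 25
epochs (the feature heads converge quickly) and 5×2 DSL / DSL+RL runs at
45 epochs on the 720-image train split — the supervised budget is set at
convergence, since mid-transient comparisons between objectives are not
meaningful — plus five paired few-label comparisons (DSL on 90 images at
45 epochs vs mean-teacher DSL+FSL+CL on the same 90 plus the 2000-image
unlabeled pool at 10 epochs). These sizes keep the full mirror within
minutes on one CPU while comparing converged models.

## Known limitations

* The numpy engine is single-threaded BLAS-bound; it is sized for the tiny
  backbone, not for study-scale ResNet training.
* Pretrained backbones are out of scope, so absolute accuracies are not
  comparable to transfer-learning results.
* The consistency term covers both heads by default; whether the original
  scheme restricted it to the disease head is not recoverable from the
  source, so a disease-only mode is provided.
* The 80/20 split and the 5-fold rotation are implemented as one mechanism
  (each fold is the 20% validation share).
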