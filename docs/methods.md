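# Methods

## Problem and model

Neoadjuvant chemotherapy (NACT) for breast cancer is evaluated clinically
under RECIST 1.1 by comparing tumor diameters before and after treatment:
complete or partial response (CR/PR, the *responders*, ≥30% diameter
decrease for PR) versus stable or progressive disease (SD/PD, the
*non-responders*, with PD at ≥20% increase). The package predicts this
binary endpoint from paired dynamic contrast-enhanced MRI (DCE-MRI)
acquired before NACT and after the first cycle. Each timepoint contributes
one spatial slice with the six dynamic phases S0–S5 stacked as channels,
so the network input is a pair of six-channel images.

The classifier is a dual-input spatio-temporal transformer:

1. **Tokens-to-token arms.** Each timepoint has its own parameter-isolated
   tokenization arm. A block applies a transformer step (multi-head
   self-attention + feed-forward), reshapes the tokens to a spatial map,
   extracts multi-scale features with same-padded convolutions (kernels
   3/5/7 by default), fuses windowed local attention and global attention
   per scale with learned convex weights α + β = 1 (a softmax over two
   logits, so the constraint holds by construction), fuses scales with
   softmax weights ω from a fully connected layer on pooled per-scale
   descriptors, and re-tokenizes via an overlapping *soft split* (kernel
   k = 3, stride s = 2, padding 1), which preserves local structure that
   hard non-overlapping patching destroys. The raw image is first
   tokenized by one soft split with k = 7, s = 4, p = 2.
2. **Spatio-temporal embedding.** A dynamic position embedding
   E_pos(T) = W_pos·f(T) + b_pos is generated per image by a three-layer
   conv stack (3×3, 3×3, 1×1, each with batch norm + ReLU); a sinusoidal
   temporal embedding TE_t[2j] = sin(t/10000^(2j/d)),
   TE_t[2j+1] = cos(t/10000^(2j/d)) indexes the timepoint t ∈ {0, 1}.
   Their sum is added to the tokens (TE broadcast identically to all
   tokens). The embedding is applied once, after tokenization and before
   the shared encoder; ablation modes substitute a learned static table
   (SPE) or drop either component.
3. **Shared encoder and fusion head.** One transformer encoder (shared
   weights, final layer norm) encodes both sequences. The head pools each
   arm (GAP), derives convex fusion weights (α, β) from the concatenated
   pooled vectors, forms F_fused = α·F_before + β·F_after, the explicit
   difference ΔF = F_after − F_before, concatenates [F_fused ; ΔF] along
   features, pools, and classifies with a linear layer + softmax
   (argmax ties resolve to class 0). A prepended class-token head is
   available as the ablation baseline.

Where the architecture leaves free choices (block count, widths, head
count, encoder depth), the defaults are 2 tokens-to-token blocks, 64-dim
tokens, 4 heads, encoder depth 4 at 224-pixel inputs — conventional
tokens-to-token ViT scaling. The shared encoder pools [F_fused ; ΔF]
directly, without a second encoding stage.

## Numerical core

The network runs on a small reverse-mode autodiff engine over NumPy
(`_autodiff.py`): dense tensors, a dynamically built graph, and exactly
the operator set the model needs. Convolution is unfold + matmul; the
soft split is the same unfold primitive. Every operator is validated
against central finite differences, and attention/soft-split/pooling are
additionally checked against naive-loop oracles. Default dtype is float64
(so oracle tests can use tight tolerances); training runs switch to
float32 via the `precision` context for speed. Training is fully seeded
(initialization, shuffling, augmentation) and single-threaded
deterministic: identical config + seed reproduce byte-identical metrics.

## Training recipe

Cross-entropy loss; AdamW with β₁ = 0.85, β₂ = 0.998, learning rate 1e-4,
weight decay 0.02; cosine-annealed schedule; early stopping on the
minimum validation loss (default patience 10, max 100 epochs, batch 16).
Class imbalance is addressed by training-set augmentation only
(horizontal/vertical flips, ±15° and ±30° rotations), never by loss
weighting; validation and test sets are never augmented. The `uniform4`
policy yields exactly 5× the pairs (one variant per flip, one ±15° and
one ±30° rotation with seed-chosen signs, applied identically to the pre
and post image of a pair). Because a uniform multiplier cannot balance an
89:14 class split to near-parity, a separate `class_balanced` policy
chooses per-class multiplicities targeting a post-augmentation ratio
within 1.1:1.

## Cohort logistics

Eligibility requires NACT receipt and complete paired MRI. Labels map
CR/PR → 1, SD/PD → 0. The 3:1:1 patient-level split uses ⌊3n/5⌋ train,
⌊n/5⌋ validation, remainder test — the only rounding that yields
103/34/35 from 172 eligible patients. Cross-validation partitions
patients into k folds differing in size by at most one (172 → 35/35/34/
34/34). Slice selection takes the largest-diameter slice as center (ties
to the lowest index) and includes slices within ±20 mm at pitch =
thickness + gap (2.0 + 0.5 mm → ±8 slices). Confidence intervals are
mean ± 1.96·SE over folds; AUC differences use the paired DeLong test
(placement values), accuracy the continuity-corrected McNemar test
(χ² = (|b−c|−1)²/(b+c); exact binomial behind a flag), sensitivity/
specificity paired t-tests (all-zero differences → p = 1; zero variance
with nonzero mean is degenerate and reported as p → 0 with a warning).

## Image preprocessing

Rigid alignment estimates the post-slice motion over a ±10° rotation grid
(step 0.5°), resolving residual translation per angle by FFT phase
cross-correlation and scoring by normalized cross-correlation; candidates
are visited in order of increasing |θ| so exact ties prefer the smaller
rotation. Breast masking applies two-stage Otsu thresholding (the second
pass on sub-threshold intensities separates air from tissue when bright
skin/chest-wall structures dominate the histogram), keeps the largest
connected component, and erodes a 2-pixel rim to strip the skin; the
chest-wall band forms its own component and drops out. Phases S0–S5 are
stacked unchanged as channels and resized bilinearly to 224×224 (the
acquisition matrix is 320×320 at 360 mm field of view, 1.125 mm/pixel).

## Synthetic phantom cohorts

No patient data ships with the package; a generator emulates the
statistical structure the pipeline assumes. A phantom slice is an
elliptical breast with textured parenchyma, a 2-pixel bright skin rim, a
chest-wall band, and one circular enhancing lesion whose intensity
follows u(p) = (1 − e^(−washin·p))·e^(−washout·max(0, p−3)) — zero at S0,
monotone wash-in, optional late washout — scaled by an enhancement
amplitude, plus additive Gaussian noise. Follow-up lesions implement the
RECIST intervals: CR → diameter 0; PR → shrinkage uniform in [0.30,
0.95]; SD → relative change in (−0.30, +0.20) (configurably narrowed);
PD → growth in [0.20, 0.60]; the amplitude scales with the same factor.
Category allocation in a generated manifest is exact, not sampled, and
everything is deterministic under the seed.

The phantoms deliberately omit 3-D anatomy, bias fields, Rician noise,
deformable motion and scanner variability. Passing tests therefore
demonstrate that the pipeline recovers a diameter/enhancement signal it
is designed for — not clinical performance on real DCE-MRI.

## Desk-scale experiments

All learning experiments use a scaled-down profile chosen as the
package's reference desk configuration: 64×64 phantoms, 32-dim tokens,
2 heads, 2 blocks, encoder depth 2, learning rate 1e-3 (larger than the
full-scale 1e-4 because the schedule is two orders of magnitude shorter),
batch 16, ≤20 epochs with early stopping (patience 4, min-delta 1e-3).

* **Signal recovery**: a 120-patient cohort, 60 PR (shrinkage ≥30%) vs 60
  SD constrained to ±10% change, noise SD 0.05; patient-level 3:1:1
  split. The dual-input model is expected to reach held-out AUC ≥ 0.90
  (median of three seeds).
* **Timepoint comparison**: pre-treatment lesions are drawn identically
  for both classes, so the pre image carries no label information by
  construction; the pre-only variant (both arms fed the pre image) is at
  chance while the dual-input model is not — reproducing the directional
  finding that post-first-cycle imaging, and the fusion of both
  timepoints, carry the response signal.

These experiments skip the rigid-alignment stage (phantom pairs are
co-registered by construction); the alignment operator is validated
separately against injected transforms.

## Known limitations

The engine is desk-scale: the full 224-pixel default configuration is
defined but not trained in the test suite. Patient-level evaluation of
slice-level scores is a simple mean aggregation (`aggregate_by_patient`);
the per-pair evaluation is the default. The class-token head is the only
alternative classification head provided for ablation.
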