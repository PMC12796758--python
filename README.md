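# nactformer

Early prediction of response to neoadjuvant chemotherapy (NACT) in breast
cancer from paired dynamic contrast-enhanced MRI (DCE-MRI), using a
dual-input spatio-temporal transformer.

## The problem

NACT shrinks breast tumors before surgery, but a substantial fraction of
patients respond poorly and lose time to ineffective therapy. Response is
graded under RECIST 1.1 by diameter change — complete/partial response
(CR/PR, "responders") versus stable/progressive disease (SD/PD,
"non-responders"). Imaging after the *first* chemotherapy cycle already
carries much of that signal. This package implements a classifier that
consumes one six-channel DCE-MRI composite (dynamic phases S0–S5 stacked
as channels) per timepoint — pre-treatment and post-first-cycle — and
predicts the binary response label.

The network has three stages, each exposed and tested separately:

* **tokens-to-token arms** (one per timepoint, parameters never shared):
  transformer step → multi-scale convolution → fusion of windowed local
  and global attention with learned weights α + β = 1 → softmax-weighted
  scale fusion → overlapping *soft split* re-tokenization;
* **spatio-temporal embedding**: an image-conditioned dynamic position
  embedding E_pos(T) = W_pos·f(T) + b_pos from a small conv net, plus a
  sinusoidal temporal embedding TE_t indexed by timepoint t ∈ {0, 1},
  added to every token;
* **adaptive fusion head**: a shared-parameter encoder, pooled fusion
  weights (α, β) = softmax(FC([F̄_before ; F̄_after])), the fused features
  α·F_before + β·F_after, the explicit difference ΔF = F_after − F_before,
  and a linear softmax classifier over the pooled concatenation.

Training follows the recipe: cross-entropy, AdamW (β₁ = 0.85,
β₂ = 0.998), lr 1e-4, weight decay 0.02, cosine annealing, early stopping
on validation loss. Evaluation reports AUC / accuracy / sensitivity /
specificity with 95% CIs (mean ± 1.96·SE over folds) and compares models
with the DeLong, McNemar and paired t-tests.

Because clinical DCE-MRI cohorts are private, the package ships a
synthetic phantom generator whose lesion kinetics and RECIST diameter
dynamics encode the label, making the entire pipeline testable end to end
with no patient data. The model itself runs on a small NumPy autodiff
engine included in the package — there is no deep-learning framework
dependency. See `docs/methods.md` for the full model description and the
desk-scale experiment design.

## Worked example

Generate a small synthetic cohort and train the desk-scale model:

```bash
nactformer simulate --out cohort --n-patients 40 --n-incomplete 2 \
    --counts PR=20,SD=18 --image-size 64 --seed 7
nactformer run --cohort cohort --out results --seed 7 --no-align --quiet
```

`results/metrics.json` then contains (this exact output, seed 7):

```json
{
  "split": {
    "metrics": {
      "auc": 1.0,
      "accuracy": 1.0,
      "sensitivity": 1.0,
      "specificity": 1.0
    },
    "n_train": 22,
    "n_val": 7,
    "n_test": 9,
    "best_epoch": 18
  },
  "seed": 7
}
```

The 38 eligible patients (2 of 40 are excluded for incomplete MRI) split
3:1:1 into 22/7/9 at patient level. On this small, cleanly separable
phantom cohort the model reaches perfect held-out discrimination
(AUC = 1.0): responders' lesions shrink by ≥30% with matching enhancement
loss, and the fusion head's difference features ΔF capture exactly that
change. Real DCE-MRI is far harder; the phantom result only demonstrates
that the pipeline recovers the signal class it is built for.

Compare two score files (DeLong / McNemar / paired t, significance at
0.05):

```bash
nactformer compare results/scores.csv other/scores.csv
```

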