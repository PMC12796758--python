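"""Desk-scale validation experiments on synthetic cohorts.

Real patient imaging is private, so the package validates its directional
claims on phantom cohorts whose construction guarantees where the label
signal lives:

* signal recovery — a separable cohort (responders shrink ≥ 30%,
  non-responders change within ±10%, moderate acquisition noise) on which
  the dual-input model should reach high held-out AUC;
* timepoint comparison — because pre-treatment lesions are drawn
  identically for both classes, only the post-treatment image carries
  label signal; a pre-only model is reduced to chance while the dual-input
  model is not.

Pairs are built in memory (phantoms are already co-registered, so the
rigid-alignment stage is skipped here; the preprocessing tests exercise it
separately).
"""

from __future__ import annotations

import numpy as np

from .model import DualInputTransformer, ModelConfig
from .preprocess import LabeledPair, SixChannelImage, normalize_image, response_label
from .synthetic import generate_cohort, simulate_patient_pair
from .train import TrainConfig, auc_score, predict_scores, train_model

#: Study conditions for the separable recovery cohort.
RECOVERY_N_PATIENTS = 120
RECOVERY_CATEGORY_COUNTS = {"PR": 60, "SD": 60}
RECOVERY_SD_CHANGE_RANGE = (-0.10, 0.10)
RECOVERY_NOISE_SD = 0.05
RECOVERY_IMAGE_SIZE = (64, 64)


def build_synthetic_pairs(
    n_patients: int = RECOVERY_N_PATIENTS,
    category_counts: dict = None,
    seed: int = 0,
    image_size=RECOVERY_IMAGE_SIZE,
    noise_sd: float = RECOVERY_NOISE_SD,
    sd_change_range=RECOVERY_SD_CHANGE_RANGE,
) -> list[LabeledPair]:
    """Simulate a labeled cohort of pre/post six-channel pairs in memory."""
    counts = category_counts or dict(RECOVERY_CATEGORY_COUNTS)
    manifest = generate_cohort(n_patients, 0, counts, seed=seed)
    pairs = []
    for record in manifest.eligible:
        pre_s, post_s, _, _ = simulate_patient_pair(
            record,
            seed,
            image_size=image_size,
            noise_sd=noise_sd,
            sd_change_range=sd_change_range,
        )
        pre = normalize_image(
            SixChannelImage(pre_s.phases, patient_id=record.patient_id, timepoint="pre")
        )
        post = normalize_image(
            SixChannelImage(post_s.phases, patient_id=record.patient_id, timepoint="post")
        )
        pairs.append(
            LabeledPair(
                pre=pre,
                post=post,
                label=response_label(record.response_category),
                patient_id=record.patient_id,
            )
        )
    return pairs


def split_pairs(pairs: list[LabeledPair], seed: int):
    """Patient-level 3:1:1 split of in-memory pairs."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pairs))
    n = len(pairs)
    n_train, n_val = (3 * n) // 5, n // 5
    train = [pairs[i] for i in order[:n_train]]
    val = [pairs[i] for i in order[n_train : n_train + n_val]]
    test = [pairs[i] for i in order[n_train + n_val :]]
    return train, val, test


def run_recovery_experiment(
    seed: int,
    model_config: ModelConfig | None = None,
    train_config: TrainConfig | None = None,
    n_patients: int = RECOVERY_N_PATIENTS,
) -> dict:
    """Train the dual-input model on the separable cohort; return held-out
    test AUC and the train/val loss trace."""
    model_config = model_config or ModelConfig.test_profile()
    train_config = train_config or TrainConfig.test_profile(seed=seed)
    counts = {
        k: round(v * n_patients / RECOVERY_N_PATIENTS)
        for k, v in RECOVERY_CATEGORY_COUNTS.items()
    }
    pairs = build_synthetic_pairs(
        n_patients=n_patients, category_counts=counts, seed=seed
    )
    train, val, test = split_pairs(pairs, seed)
    model = DualInputTransformer(model_config, seed=seed)
    result = train_model(model, train_config, train, val)
    scores = predict_scores(model, test)
    labels = np.array([p.label for p in test])
    return {
        "auc": auc_score(scores, labels),
        "n_train": len(train),
        "n_test": len(test),
        "train_losses": result.train_losses,
        "val_losses": result.val_losses,
        "best_epoch": result.best_epoch,
    }


def run_timepoint_experiment(
    seed: int,
    model_config: ModelConfig | None = None,
    train_config: TrainConfig | None = None,
    n_patients: int = RECOVERY_N_PATIENTS,
) -> dict:
    """Dual-input vs pre-only on a cohort whose label signal is entirely in
    the post image. Returns both held-out AUCs."""
    import dataclasses

    model_config = model_config or ModelConfig.test_profile()
    train_config = train_config or TrainConfig.test_profile(seed=seed)
    counts = {
        k: round(v * n_patients / RECOVERY_N_PATIENTS)
        for k, v in RECOVERY_CATEGORY_COUNTS.items()
    }
    pairs = build_synthetic_pairs(
        n_patients=n_patients, category_counts=counts, seed=seed
    )
    train, val, test = split_pairs(pairs, seed)
    labels = np.array([p.label for p in test])
    aucs = {}
    for name, overrides in (("dual", {}), ("pre_only", {"timepoints": "pre"})):
        cfg = dataclasses.replace(model_config, **overrides)
        model = DualInputTransformer(cfg, seed=seed)
        train_model(model, train_config, train, val)
        aucs[name] = auc_score(predict_scores(model, test), labels)
    return aucs
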