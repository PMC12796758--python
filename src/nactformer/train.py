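"""Training recipe, cross-validation, metrics and model-comparison tests.

The recipe follows the published protocol: cross-entropy loss, AdamW with
β₁ = 0.85 and β₂ = 0.998, initial learning rate 1e-4, weight decay 0.02,
cosine-annealed schedule, and early stopping selecting the checkpoint with
the minimum validation loss. Evaluation reports AUC, accuracy, sensitivity
and specificity with 95% confidence intervals (mean ± 1.96·SE over folds),
and model pairs are compared with the DeLong test (AUC), the
continuity-corrected McNemar test (accuracy) and paired t-tests
(sensitivity/specificity).
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score

from ._autodiff import AdamW, Tensor, cosine_lr, cross_entropy, precision
from .model import DualInputTransformer, ModelConfig, batch_from_pairs
from .preprocess import LabeledPair


@dataclasses.dataclass
class TrainConfig:
    lr: float = 1e-4
    betas: tuple = (0.85, 0.998)
    weight_decay: float = 0.02
    epochs_max: int = 100
    patience: int = 10
    min_delta: float = 0.0
    batch_size: int = 16
    seed: int = 0
    dtype: str = "float64"

    def __post_init__(self):
        if self.lr <= 0:
            raise ValueError("lr must be > 0")
        if not (0 < self.betas[0] < 1 and 0 < self.betas[1] < 1):
            raise ValueError("AdamW betas must lie in (0, 1)")

    @classmethod
    def test_profile(cls, **overrides) -> "TrainConfig":
        """Desk-scale schedule used with ModelConfig.test_profile."""
        base = dict(
            lr=1e-3,
            epochs_max=20,
            patience=4,
            min_delta=1e-3,
            batch_size=16,
            dtype="float32",
        )
        base.update(overrides)
        return cls(**base)


@dataclasses.dataclass
class TrainResult:
    best_state: list
    best_epoch: int
    train_losses: list
    val_losses: list


def select_checkpoint(val_losses) -> int:
    """0-based epoch index of the minimum validation loss (first minimum)."""
    if len(val_losses) == 0:
        raise ValueError("no validation losses recorded")
    return int(np.argmin(val_losses))


def _epoch_loss(model, pairs, batch_size: int) -> float:
    total, n = 0.0, 0
    for i in range(0, len(pairs), batch_size):
        chunk = pairs[i : i + batch_size]
        pre, post, labels = batch_from_pairs(chunk)
        loss = cross_entropy(model(pre, post), labels)
        total += loss.item() * len(chunk)
        n += len(chunk)
    return total / n


def train_model(
    model: DualInputTransformer,
    config: TrainConfig,
    train_pairs: list[LabeledPair],
    val_pairs: list[LabeledPair],
    log=None,
) -> TrainResult:
    """Train with seeded shuffling, cosine-annealed AdamW and early stopping.

    Returns the checkpoint whose validation loss is minimal; the model is
    left loaded with that checkpoint. Divergence (NaN loss) aborts.
    """
    if not train_pairs or not val_pairs:
        raise ValueError("training and validation sets must be non-empty")
    with precision(config.dtype):
        for p in model.parameters():
            p.data = p.data.astype(config.dtype)
        rng = np.random.default_rng(config.seed)
        opt = AdamW(
            model.parameters(),
            lr=config.lr,
            betas=config.betas,
            weight_decay=config.weight_decay,
        )
        steps_per_epoch = max(1, (len(train_pairs) + config.batch_size - 1) // config.batch_size)
        total_steps = config.epochs_max * steps_per_epoch
        train_losses, val_losses = [], []
        best_state, best_loss, best_epoch = None, np.inf, -1
        last_significant = -1
        step = 0
        for epoch in range(config.epochs_max):
            model.set_training(True)
            order = rng.permutation(len(train_pairs))
            epoch_loss, seen = 0.0, 0
            for i in range(0, len(order), config.batch_size):
                chunk = [train_pairs[j] for j in order[i : i + config.batch_size]]
                pre, post, labels = batch_from_pairs(chunk)
                loss = cross_entropy(model(pre, post), labels)
                if not np.isfinite(loss.item()):
                    raise RuntimeError(
                        f"training diverged: loss={loss.item()} at epoch {epoch}"
                    )
                opt.zero_grad()
                loss.backward()
                opt.step(lr=cosine_lr(step, total_steps, config.lr))
                step += 1
                epoch_loss += loss.item() * len(chunk)
                seen += len(chunk)
            train_losses.append(epoch_loss / seen)
            model.set_training(False)
            val_losses.append(_epoch_loss(model, val_pairs, config.batch_size))
            if log is not None:
                log(
                    f"epoch={epoch} train_loss={train_losses[-1]:.4f} "
                    f"val_loss={val_losses[-1]:.4f}"
                )
            if val_losses[-1] < best_loss:
                if best_loss - val_losses[-1] > config.min_delta:
                    last_significant = epoch
                best_loss = val_losses[-1]
                best_epoch = epoch
                best_state = model.state_arrays()
            if epoch - last_significant >= config.patience:
                break
        model.load_state_arrays(best_state)
        model.set_training(False)
    return TrainResult(best_state, best_epoch, train_losses, val_losses)


def predict_scores(model: DualInputTransformer, pairs, batch_size: int = 16):
    """Class-1 probabilities for a list of pairs."""
    model.set_training(False)
    dtype = model.parameters()[0].data.dtype
    scores = []
    with precision(dtype):
        for i in range(0, len(pairs), batch_size):
            pre, post, _ = batch_from_pairs(pairs[i : i + batch_size])
            scores.append(model.predict(pre, post).probabilities[:, 1])
    return np.concatenate(scores)


def aggregate_by_patient(scores, labels, patient_ids):
    """Mean slice-pair score (and the shared label) per patient."""
    order = {}
    for s, y, pid in zip(scores, labels, patient_ids):
        order.setdefault(pid, []).append((s, y))
    agg_scores, agg_labels = [], []
    for pid, rows in order.items():
        agg_scores.append(float(np.mean([r[0] for r in rows])))
        agg_labels.append(rows[0][1])
    return np.asarray(agg_scores), np.asarray(agg_labels)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self):
        return self.tp + self.tn + self.fp + self.fn


@dataclasses.dataclass
class Metrics:
    auc: float
    accuracy: float
    sensitivity: float
    specificity: float
    counts: ConfusionCounts

    def as_dict(self):
        return {
            "auc": self.auc,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
        }


def confusion_counts(scores, labels, threshold: float = 0.5) -> ConfusionCounts:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    preds = (scores >= threshold).astype(int)
    return ConfusionCounts(
        tp=int(((preds == 1) & (labels == 1)).sum()),
        tn=int(((preds == 0) & (labels == 0)).sum()),
        fp=int(((preds == 1) & (labels == 0)).sum()),
        fn=int(((preds == 0) & (labels == 1)).sum()),
    )


def auc_score(scores, labels) -> float:
    """AUC with midrank tie handling; equals the probability that a random
    positive outscores a random negative, ties counted one half."""
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC undefined: labels contain a single class")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def compute_metrics(scores, labels, threshold: float = 0.5) -> Metrics:
    c = confusion_counts(scores, labels, threshold)
    auc = auc_score(scores, labels)
    return Metrics(
        auc=auc,
        accuracy=(c.tp + c.tn) / c.total,
        sensitivity=c.tp / (c.tp + c.fn) if (c.tp + c.fn) else float("nan"),
        specificity=c.tn / (c.tn + c.fp) if (c.tn + c.fp) else float("nan"),
        counts=c,
    )


def confidence_interval(fold_values, rate: bool = True):
    """mean ± 1.96·SE over folds; SE = sample SD / √k; rate metrics are
    clipped to [0, 1]."""
    values = np.asarray(fold_values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 fold values for a confidence interval")
    mean = float(values.mean())
    se = float(values.std(ddof=1) / np.sqrt(values.size))
    lo, hi = mean - 1.96 * se, mean + 1.96 * se
    if rate:
        lo, hi = max(0.0, lo), min(1.0, hi)
    return mean, lo, hi


# ---------------------------------------------------------------------------
# Pairwise model-comparison tests
# ---------------------------------------------------------------------------


def _placement_values(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    # ψ(x, y) = 1 if x > y, ½ if x == y, 0 otherwise
    psi = (pos[:, None] > neg[None, :]).astype(float) + 0.5 * (
        pos[:, None] == neg[None, :]
    )
    v10 = psi.mean(axis=1)  # one per positive
    v01 = psi.mean(axis=0)  # one per negative
    return v10, v01


def delong_test(scores_a, scores_b, labels):
    """Paired DeLong test for the difference of two correlated AUCs.

    Returns (auc_a, auc_b, two-sided p). The variance of the AUC difference
    is estimated from per-case placement values; a degenerate zero-variance
    comparison with zero AUC difference yields p = 1.
    """
    scores_a, scores_b = np.asarray(scores_a, float), np.asarray(scores_b, float)
    labels = np.asarray(labels, dtype=int)
    if scores_a.shape != scores_b.shape or scores_a.shape[0] != labels.shape[0]:
        raise ValueError("scores_a, scores_b and labels must be paired")
    if len(np.unique(labels)) < 2:
        raise ValueError("DeLong test requires both classes present")
    v10_a, v01_a = _placement_values(scores_a, labels)
    v10_b, v01_b = _placement_values(scores_b, labels)
    auc_a, auc_b = float(v10_a.mean()), float(v10_b.mean())
    m, n = v10_a.size, v01_a.size

    def cov(x, y):
        if x.size < 2:
            return 0.0
        return float(np.cov(x, y, ddof=1)[0, 1])

    var = (
        cov(v10_a, v10_a) + cov(v10_b, v10_b) - 2 * cov(v10_a, v10_b)
    ) / m + (cov(v01_a, v01_a) + cov(v01_b, v01_b) - 2 * cov(v01_a, v01_b)) / n
    diff = auc_a - auc_b
    if var <= 0:
        return auc_a, auc_b, 1.0 if abs(diff) < 1e-12 else 0.0
    z = diff / np.sqrt(var)
    p = float(2 * stats.norm.sf(abs(z)))
    return auc_a, auc_b, p


def mcnemar_test(preds_a, preds_b, labels, exact: bool = False):
    """McNemar test on discordant classifications of two paired models.

    b = cases model a classifies correctly and b wrongly; c = the converse.
    Default: continuity-corrected χ² = (|b−c|−1)²/(b+c) on 1 df; `exact`
    switches to the two-sided binomial. No discordant pairs → p = 1.
    """
    preds_a, preds_b = np.asarray(preds_a, int), np.asarray(preds_b, int)
    labels = np.asarray(labels, dtype=int)
    if preds_a.shape != preds_b.shape or preds_a.shape[0] != labels.shape[0]:
        raise ValueError("predictions and labels must be paired")
    correct_a = preds_a == labels
    correct_b = preds_b == labels
    b = int((correct_a & ~correct_b).sum())
    c = int((~correct_a & correct_b).sum())
    if b + c == 0:
        return b, c, 1.0
    if exact:
        p = float(stats.binomtest(min(b, c), b + c, 0.5).pvalue * 1.0)
        return b, c, min(1.0, p)
    chi2 = (abs(b - c) - 1) ** 2 / (b + c)
    return b, c, float(stats.chi2.sf(chi2, df=1))


def paired_t_test(values_a, values_b):
    """Two-sided paired t-test over per-fold metric values.

    All-zero differences give (0, 1). Zero difference-variance with a
    nonzero mean difference is degenerate: reported as p → 0 with a
    warning, since the t statistic is unbounded.
    """
    a, b = np.asarray(values_a, float), np.asarray(values_b, float)
    if a.shape != b.shape:
        raise ValueError("paired t-test needs equal-length vectors")
    if a.size < 2:
        raise ValueError("need at least 2 paired values")
    d = a - b
    if np.allclose(d, 0.0):
        return 0.0, 1.0
    sd = d.std(ddof=1)
    if sd == 0:
        warnings.warn("degenerate paired t-test: zero variance, nonzero mean")
        return float(np.sign(d.mean()) * np.inf), 0.0
    t = d.mean() / (sd / np.sqrt(d.size))
    p = float(2 * stats.t.sf(abs(t), df=d.size - 1))
    return float(t), p


# ---------------------------------------------------------------------------
# Cross-validation and ablation
# ---------------------------------------------------------------------------


def make_folds(patient_ids, k: int, seed: int) -> list[list[str]]:
    """Deterministic patient-level k-fold partition; fold sizes differ by at
    most one (172 patients → 35/35/34/34/34)."""
    ids = list(patient_ids)
    if k < 2 or k > len(ids):
        raise ValueError(f"cannot make {k} folds from {len(ids)} patients")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    shuffled = [ids[i] for i in order]
    base, extra = divmod(len(ids), k)
    folds, start = [], 0
    for f in range(k):
        size = base + (1 if f < extra else 0)
        folds.append(shuffled[start : start + size])
        start += size
    return folds


@dataclasses.dataclass
class FoldMetrics:
    per_fold: list          # Metrics per evaluated fold
    skipped_folds: list     # fold indices skipped for missing a class
    aggregate: dict         # metric -> (mean, lo, hi)

    @classmethod
    def from_folds(cls, per_fold, skipped=()):
        agg = {}
        for name in ("auc", "accuracy", "sensitivity", "specificity"):
            values = [getattr(m, name) for m in per_fold]
            if len(values) >= 2:
                agg[name] = confidence_interval(values)
            else:  # a single evaluated fold has no spread to estimate
                agg[name] = (float(values[0]), float(values[0]), float(values[0]))
        return cls(list(per_fold), list(skipped), agg)


def cross_validate(
    pairs: list[LabeledPair],
    model_config: ModelConfig,
    train_config: TrainConfig,
    k: int = 5,
    val_fraction: float = 0.25,
) -> FoldMetrics:
    """Patient-level k-fold cross-validation.

    Each fold is held out for evaluation; the remaining patients are split
    into train/validation for early stopping. Folds whose evaluation split
    lacks a class are skipped with a warning.
    """
    ids = sorted({p.patient_id for p in pairs})
    by_id = {}
    for p in pairs:
        by_id.setdefault(p.patient_id, []).append(p)
    folds = make_folds(ids, k, train_config.seed)
    per_fold, skipped = [], []
    for f, held_out in enumerate(folds):
        eval_pairs = [p for pid in held_out for p in by_id[pid]]
        if len({p.label for p in eval_pairs}) < 2:
            warnings.warn(f"fold {f} evaluation split lacks a class; skipped")
            skipped.append(f)
            continue
        rest = [pid for g, fold in enumerate(folds) if g != f for pid in fold]
        rng = np.random.default_rng([train_config.seed, f])
        order = rng.permutation(len(rest))
        n_val = max(1, int(len(rest) * val_fraction))
        val_ids = {rest[i] for i in order[:n_val]}
        train_pairs = [p for pid in rest if pid not in val_ids for p in by_id[pid]]
        val_pairs = [p for pid in val_ids for p in by_id[pid]]
        model = DualInputTransformer(model_config, seed=train_config.seed + f)
        train_model(model, train_config, train_pairs, val_pairs)
        scores = predict_scores(model, eval_pairs)
        labels = np.array([p.label for p in eval_pairs])
        per_fold.append(compute_metrics(scores, labels))
    if not per_fold:
        raise ValueError("all folds were skipped")
    return FoldMetrics.from_folds(per_fold, skipped)


#: Named architecture-variant overrides used by the ablation harness.
ABLATION_VARIANTS = {
    "full": {},
    "hard_split": {"tokenizer": "hard"},
    "cls_head": {"head": "cls"},
    "no_st": {"st_mode": "none"},
    "te_only": {"st_mode": "te"},
    "dpe_only": {"st_mode": "dpe"},
    "spe_only": {"st_mode": "spe"},
    "spe_te": {"st_mode": "spe_te"},
    "pre_only": {"timepoints": "pre"},
    "post_only": {"timepoints": "post"},
}


def run_ablation(
    variants: list[str],
    train_pairs,
    val_pairs,
    test_pairs,
    model_config: ModelConfig,
    train_config: TrainConfig,
    reference: str = "full",
):
    """Train each variant with identical seeds and splits; compare each to
    the reference variant with DeLong (AUC) and McNemar (accuracy) tests.

    Returns a list of per-variant result dicts in input order.
    """
    for v in variants:
        if v not in ABLATION_VARIANTS:
            raise ValueError(
                f"unknown ablation variant {v!r}; choose from {sorted(ABLATION_VARIANTS)}"
            )
    labels = np.array([p.label for p in test_pairs])
    results = {}
    cache = {}
    for name in dict.fromkeys(list(variants) + [reference]):
        cfg = dataclasses.replace(model_config, **ABLATION_VARIANTS[name])
        model = DualInputTransformer(cfg, seed=train_config.seed)
        train_model(model, train_config, train_pairs, val_pairs)
        scores = predict_scores(model, test_pairs)
        cache[name] = scores
        results[name] = compute_metrics(scores, labels)
    rows = []
    ref_scores = cache[reference]
    ref_preds = (ref_scores >= 0.5).astype(int)
    for name in variants:
        scores = cache[name]
        m = results[name]
        _, _, p_auc = delong_test(scores, ref_scores, labels)
        _, _, p_acc = mcnemar_test(
            (scores >= 0.5).astype(int), ref_preds, labels
        )
        rows.append(
            {
                "variant": name,
                **m.as_dict(),
                "delong_p_vs_ref": p_auc,
                "mcnemar_p_vs_ref": p_acc,
            }
        )
    return rows
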