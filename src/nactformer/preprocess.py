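"""Cohort logistics and image preprocessing.

Implements the workflow between raw paired series and model-ready tensors:
eligibility filtering, responder/non-responder labeling, patient-level
3:1:1 splitting, central-slice selection, rigid pre/post alignment, breast
masking, six-channel phase stacking, resizing, and training-set
augmentation.

All splits are patient-level: no patient's images ever appear in more than
one of train/validation/test.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import erosion, footprint_rectangle
from skimage.registration import phase_cross_correlation
from skimage.transform import resize as _sk_resize

from .synthetic import (
    CohortManifest,
    RESPONDER_CATEGORIES,
    RESPONSE_CATEGORIES,
    read_series,
)

DEFAULT_IMAGE_SIDE = 224


@dataclasses.dataclass
class SixChannelImage:
    """One spatial slice with the six dynamic phases stacked as channels."""

    channels: np.ndarray  # (6, H, W), ordered S0..S5
    patient_id: str = ""
    timepoint: str = "pre"  # "pre" | "post"
    slice_index: int = 0

    def __post_init__(self):
        self.channels = np.asarray(self.channels, dtype=np.float64)
        if self.channels.ndim != 3 or self.channels.shape[0] != 6:
            raise ValueError(f"expected (6, H, W) channels, got {self.channels.shape}")
        if self.timepoint not in ("pre", "post"):
            raise ValueError(f"timepoint must be 'pre' or 'post', got {self.timepoint!r}")


@dataclasses.dataclass
class LabeledPair:
    pre: SixChannelImage
    post: SixChannelImage
    label: int
    patient_id: str

    def __post_init__(self):
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label}")
        if self.pre.channels.shape != self.post.channels.shape:
            raise ValueError("pre and post images must share shape")


@dataclasses.dataclass
class SplitAssignment:
    train_ids: list[str]
    val_ids: list[str]
    test_ids: list[str]

    def __post_init__(self):
        sets = [set(self.train_ids), set(self.val_ids), set(self.test_ids)]
        if sum(len(s) for s in sets) != len(sets[0] | sets[1] | sets[2]):
            raise ValueError("splits must be pairwise disjoint")


# ---------------------------------------------------------------------------
# Cohort logistics
# ---------------------------------------------------------------------------


def apply_inclusion_exclusion(manifest: CohortManifest) -> CohortManifest:
    """Retain exactly the records with received_nact and complete MRI."""
    return CohortManifest(
        [r for r in manifest if r.received_nact and r.mri_complete]
    )


def response_label(category: str) -> int:
    """RECIST category → binary response label (CR/PR → 1, SD/PD → 0)."""
    if category not in RESPONSE_CATEGORIES:
        raise ValueError(f"unknown response category {category!r}")
    return int(category in RESPONDER_CATEGORIES)


def assign_labels(manifest: CohortManifest) -> dict[str, int]:
    """Map every patient id to its binary response label."""
    labels = {}
    for r in manifest:
        if r.response_category is None:
            raise ValueError(f"patient {r.patient_id} is missing a response category")
        labels[r.patient_id] = response_label(r.response_category)
    return labels


def split_dataset(
    manifest: CohortManifest,
    seed: int,
    stratify: bool = False,
) -> SplitAssignment:
    """Patient-level 3:1:1 split.

    Unstratified sizes are ⌊3n/5⌋ / ⌊n/5⌋ / remainder (for n = 172 this is
    103/34/35). With `stratify`, the same rounding is applied per class so
    each split keeps the cohort's class ratio within rounding.
    """
    records = list(manifest)
    if len(records) < 5:
        raise ValueError(f"need at least 5 records to split 3:1:1, got {len(records)}")
    rng = np.random.default_rng(seed)

    def allocate(ids: list[str], rng) -> tuple[list[str], list[str], list[str]]:
        ids = list(ids)
        order = rng.permutation(len(ids))
        shuffled = [ids[i] for i in order]
        n = len(ids)
        n_train, n_val = (3 * n) // 5, n // 5
        return (
            shuffled[:n_train],
            shuffled[n_train : n_train + n_val],
            shuffled[n_train + n_val :],
        )

    if not stratify:
        tr, va, te = allocate([r.patient_id for r in records], rng)
        return SplitAssignment(tr, va, te)

    labels = assign_labels(manifest)
    tr, va, te = [], [], []
    for cls in (1, 0):
        ids = [r.patient_id for r in records if labels[r.patient_id] == cls]
        if not ids:
            continue
        a, b, c = allocate(ids, rng)
        tr += a
        va += b
        te += c
    return SplitAssignment(tr, va, te)


def select_slices(
    tumor_diameters: list[float],
    slice_thickness: float,
    interslice_gap: float,
    extent_mm: float = 20.0,
) -> list[int]:
    """Slice indices covering ±extent_mm around the largest-diameter slice.

    The central reference slice is the argmax diameter (ties → lowest
    index); the inter-slice pitch is thickness + gap; the window is clamped
    to the volume bounds.
    """
    diameters = np.asarray(tumor_diameters, dtype=np.float64)
    if diameters.size == 0 or not np.any(diameters > 0):
        raise ValueError("need at least one slice with positive tumor diameter")
    center = int(np.argmax(diameters))
    pitch = slice_thickness + interslice_gap
    span = int(extent_mm // pitch)
    lo = max(0, center - span)
    hi = min(len(diameters), center + span + 1)
    return list(range(lo, hi))


# ---------------------------------------------------------------------------
# Image operations
# ---------------------------------------------------------------------------


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    return float((a * b).sum() / denom) if denom > 0 else 0.0


def rigid_align(
    pre_slice: np.ndarray,
    post_slice: np.ndarray,
    max_rotation: float = 10.0,
    rotation_step: float = 0.5,
) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Estimate and undo the rigid motion of `post_slice` relative to `pre_slice`.

    Rotation candidates span ±max_rotation degrees; for each candidate the
    residual translation is resolved by FFT phase cross-correlation and the
    candidate is scored by normalized cross-correlation against the pre
    image. Returns (aligned_post, (drow, dcol, dtheta)) where the transform
    is the displacement the post image had undergone. Identical inputs
    yield the identity transform.
    """
    pre_slice = np.asarray(pre_slice, dtype=np.float64)
    post_slice = np.asarray(post_slice, dtype=np.float64)
    if pre_slice.size == 0 or post_slice.size == 0:
        raise ValueError("empty images")
    if pre_slice.shape != post_slice.shape:
        raise ValueError("pre and post slices must share shape")

    angles = np.arange(-max_rotation, max_rotation + 1e-9, rotation_step)
    angles = angles[np.argsort(np.abs(angles), kind="stable")]  # prefer small |θ|
    best = None
    for theta in angles:
        undone = ndi.rotate(
            post_slice, -theta, reshape=False, order=1, mode="constant"
        )
        shift, _, _ = phase_cross_correlation(
            pre_slice, undone, upsample_factor=4, normalization=None
        )
        candidate = ndi.shift(undone, shift, order=1, mode="constant")
        score = _ncc(pre_slice, candidate)
        if best is None or score > best[0] + 1e-12:
            best = (score, candidate, (-float(shift[0]), -float(shift[1]), float(theta)))
    _, aligned, transform = best
    return aligned, transform


def segment_breast(image: np.ndarray) -> np.ndarray:
    """Binary breast-tissue mask.

    Two-stage Otsu thresholding separates air background from tissue even
    when bright structures (skin, chest wall, enhancing lesion) dominate
    the histogram: the second Otsu pass on the sub-threshold intensities
    recovers the background/tissue cut. The largest connected foreground
    component is kept, then eroded by a 2-pixel rim to strip the skin; the
    chest-wall band forms its own component and is thereby excluded.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError("segment_breast expects a single 2-D slice")
    if np.allclose(image, image.flat[0]):
        return np.zeros(image.shape, dtype=bool)
    t = threshold_otsu(image)
    low = image[image < t]
    if low.size and np.ptp(low) > 0:
        t = min(t, threshold_otsu(low))
    fg = image > t
    if not fg.any():
        return fg
    labels = cc_label(fg)
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    mask = labels == largest
    for _ in range(2):
        mask = erosion(mask, footprint_rectangle((3, 3)))
    return mask


def stack_phases(phases: list[np.ndarray], **meta) -> SixChannelImage:
    """Stack six aligned phase images S0..S5 into one composite image."""
    if len(phases) != 6:
        raise ValueError(f"expected exactly 6 phase images, got {len(phases)}")
    shapes = {np.asarray(p).shape for p in phases}
    if len(shapes) != 1:
        raise ValueError(f"phase shapes differ: {sorted(shapes)}")
    return SixChannelImage(np.stack([np.asarray(p) for p in phases]), **meta)


def resize_image(image: SixChannelImage, side: int = DEFAULT_IMAGE_SIDE) -> SixChannelImage:
    """Bilinear per-channel resize to side × side pixels."""
    if side < 8:
        raise ValueError(f"side must be >= 8, got {side}")
    resized = np.stack(
        [
            _sk_resize(
                ch, (side, side), order=1, anti_aliasing=False, preserve_range=True
            )
            for ch in image.channels
        ]
    )
    return SixChannelImage(
        resized,
        patient_id=image.patient_id,
        timepoint=image.timepoint,
        slice_index=image.slice_index,
    )


# ---------------------------------------------------------------------------
# Augmentation
# ---------------------------------------------------------------------------


def _hflip(x: np.ndarray) -> np.ndarray:
    return x[:, :, ::-1].copy()


def _vflip(x: np.ndarray) -> np.ndarray:
    return x[:, ::-1, :].copy()


def _rot(x: np.ndarray, angle: float) -> np.ndarray:
    return np.stack(
        [ndi.rotate(ch, angle, reshape=False, order=1, mode="constant") for ch in x]
    )


_BASE_VARIANTS = (
    ("hflip", lambda x, _s: _hflip(x)),
    ("vflip", lambda x, _s: _vflip(x)),
    ("rot15", lambda x, s: _rot(x, 15.0 * s)),
    ("rot30", lambda x, s: _rot(x, 30.0 * s)),
    ("hflip_rot15", lambda x, s: _rot(_hflip(x), 15.0 * s)),
    ("vflip_rot15", lambda x, s: _rot(_vflip(x), 15.0 * s)),
    ("hflip_rot30", lambda x, s: _rot(_hflip(x), 30.0 * s)),
    ("vflip_rot30", lambda x, s: _rot(_vflip(x), 30.0 * s)),
)


def _apply_variant(pair: LabeledPair, name: str, sign: int, tag: str) -> LabeledPair:
    fn = dict(_BASE_VARIANTS)[name]

    def transform(img: SixChannelImage) -> SixChannelImage:
        return SixChannelImage(
            fn(img.channels, sign),
            patient_id=img.patient_id,
            timepoint=img.timepoint,
            slice_index=img.slice_index,
        )

    return LabeledPair(
        pre=transform(pair.pre),
        post=transform(pair.post),
        label=pair.label,
        patient_id=pair.patient_id,
    )


def augment_training_set(
    pairs: list[LabeledPair],
    policy: str = "uniform4",
    seed: int = 0,
) -> list[LabeledPair]:
    """Augment training pairs; pre and post always receive the identical
    transform, and validation/test sets must never pass through here.

    uniform4: each pair yields itself plus horizontal flip, vertical flip,
    one ±15° and one ±30° rotation (signs drawn under `seed`), i.e. a 5×
    multiplier. class_balanced: per-class multipliers are chosen so the
    augmented class ratio is within 1.1:1 of parity, drawing variants from
    a flip/rotation pool.
    """
    if not pairs:
        return []
    rng = np.random.default_rng(seed)
    if policy == "uniform4":
        out = []
        for pair in pairs:
            sign15 = int(rng.choice([-1, 1]))
            sign30 = int(rng.choice([-1, 1]))
            out.append(pair)
            out.append(_apply_variant(pair, "hflip", 1, "hflip"))
            out.append(_apply_variant(pair, "vflip", 1, "vflip"))
            out.append(_apply_variant(pair, "rot15", sign15, "rot15"))
            out.append(_apply_variant(pair, "rot30", sign30, "rot30"))
        return out
    if policy == "class_balanced":
        by_class = {c: [p for p in pairs if p.label == c] for c in (0, 1)}
        by_class = {c: ps for c, ps in by_class.items() if ps}
        target_total = 5 * len(pairs)
        target_per_class = target_total / len(by_class)
        out = []
        names = [n for n, _ in _BASE_VARIANTS]
        for cls, ps in sorted(by_class.items()):
            mult = max(1, round(target_per_class / len(ps)))
            for pair in ps:
                out.append(pair)
                for _ in range(mult - 1):
                    name = names[int(rng.integers(len(names)))]
                    sign = int(rng.choice([-1, 1]))
                    out.append(_apply_variant(pair, name, sign, name))
        return out
    raise ValueError(f"unknown augmentation policy {policy!r}")


# ---------------------------------------------------------------------------
# End-to-end pair construction
# ---------------------------------------------------------------------------


def normalize_image(img: SixChannelImage) -> SixChannelImage:
    """Per-image z-score over all channels (zero mean, unit variance)."""
    x = img.channels
    sd = x.std()
    x = (x - x.mean()) / (sd if sd > 0 else 1.0)
    return SixChannelImage(
        x, patient_id=img.patient_id, timepoint=img.timepoint, slice_index=img.slice_index
    )


def build_pairs(
    manifest: CohortManifest,
    image_side: int | None = None,
    align: bool = True,
    mask: bool = True,
    normalize: bool = True,
) -> list[LabeledPair]:
    """Load every eligible patient's series pair and run the slice pipeline:
    rigid alignment of the post slice to the pre slice (estimated on S1 and
    applied to every phase), breast masking, phase stacking, optional
    resizing and per-image normalization."""
    eligible = apply_inclusion_exclusion(manifest)
    labels = assign_labels(eligible)
    pairs = []
    for record in eligible:
        pre_series = read_series(record.pre_path)
        post_series = read_series(record.post_path)
        pre_phases = list(pre_series.phases)
        post_phases = list(post_series.phases)
        if align:
            _, (drow, dcol, dtheta) = rigid_align(pre_phases[1], post_phases[1])
            post_phases = [
                ndi.shift(
                    ndi.rotate(ph, -dtheta, reshape=False, order=1, mode="constant"),
                    (-drow, -dcol),
                    order=1,
                    mode="constant",
                )
                for ph in post_phases
            ]
        if mask:
            m_pre = segment_breast(pre_phases[1])
            m_post = segment_breast(post_phases[1])
            pre_phases = [ph * m_pre for ph in pre_phases]
            post_phases = [ph * m_post for ph in post_phases]
        pre_img = stack_phases(pre_phases, patient_id=record.patient_id, timepoint="pre")
        post_img = stack_phases(post_phases, patient_id=record.patient_id, timepoint="post")
        if image_side is not None:
            pre_img = resize_image(pre_img, image_side)
            post_img = resize_image(post_img, image_side)
        if normalize:
            pre_img = normalize_image(pre_img)
            post_img = normalize_image(post_img)
        pairs.append(
            LabeledPair(
                pre=pre_img,
                post=post_img,
                label=labels[record.patient_id],
                patient_id=record.patient_id,
            )
        )
    return pairs
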