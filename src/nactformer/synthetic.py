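"""Synthetic paired DCE-MRI phantom cohorts.

Generates cohorts of breast DCE-MRI phantoms at two timepoints (before
neoadjuvant chemotherapy and after the first cycle) whose lesion-size
dynamics encode the RECIST response label. Each series is one axial slice
with six dynamic post-contrast phases (S0–S5): a breast region with textured
parenchyma, a thin bright skin rim, a chest-wall band, and a circular
enhancing lesion whose intensity follows a wash-in/wash-out kinetic curve.

The phantom emulates the statistical structure the downstream pipeline
assumes — eligibility flags, the four RECIST categories with their class
imbalance, diameter change by response class — not realistic breast anatomy.

Default geometry follows a 3.0-T protocol with field of view 360 mm at a
320 matrix (1.125 mm/pixel), slice thickness 2.0 mm and interslice gap
0.5 mm.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

RESPONSE_CATEGORIES = ("CR", "PR", "SD", "PD")

#: Responders under RECIST: complete or partial response.
RESPONDER_CATEGORIES = frozenset({"CR", "PR"})

#: RECIST 1.1 diameter-change thresholds (relative): PR ≤ −30%, PD ≥ +20%.
RECIST_PR_SHRINKAGE = 0.30
RECIST_PD_GROWTH = 0.20

DEFAULT_PIXEL_SPACING = 360.0 / 320.0   # mm/pixel
DEFAULT_SLICE_THICKNESS = 2.0           # mm
DEFAULT_INTERSLICE_GAP = 0.5            # mm
N_PHASES = 6

MANIFEST_COLUMNS = (
    "patient_id",
    "response_category",
    "received_nact",
    "mri_complete",
    "pre_path",
    "post_path",
)


@dataclasses.dataclass
class LesionParams:
    """Parameters of one circular enhancing lesion.

    center is (row, col) in 0-based pixel indices; diameter in mm is
    converted to pixels via the series' pixel spacing. The enhancement
    amplitude is the peak added intensity; wash-in/wash-out rates are per
    dynamic phase.
    """

    center: tuple[float, float]
    diameter: float
    enhancement_amplitude: float = 1.0
    washin_rate: float = 1.2
    washout_rate: float = 0.15

    def __post_init__(self):
        if self.diameter < 0:
            raise ValueError(f"diameter must be >= 0, got {self.diameter}")
        if self.enhancement_amplitude < 0:
            raise ValueError("enhancement_amplitude must be >= 0")
        if self.washin_rate < 0 or self.washout_rate < 0:
            raise ValueError("kinetic rates must be >= 0")


@dataclasses.dataclass
class DCESeries:
    """One spatial slice with six dynamic phases S0..S5."""

    phases: np.ndarray  # (6, H, W)
    pixel_spacing: float = DEFAULT_PIXEL_SPACING
    slice_thickness: float = DEFAULT_SLICE_THICKNESS
    interslice_gap: float = DEFAULT_INTERSLICE_GAP

    def __post_init__(self):
        self.phases = np.asarray(self.phases, dtype=np.float64)
        if self.phases.ndim != 3 or self.phases.shape[0] != N_PHASES:
            raise ValueError(
                f"expected {N_PHASES} phases of identical shape, got {self.phases.shape}"
            )
        if self.pixel_spacing <= 0:
            raise ValueError("pixel_spacing must be > 0")


@dataclasses.dataclass
class PatientRecord:
    patient_id: str
    response_category: str | None
    received_nact: bool
    mri_complete: bool
    pre_path: str | None = None
    post_path: str | None = None

    def __post_init__(self):
        if self.response_category is not None:
            if self.response_category not in RESPONSE_CATEGORIES:
                raise ValueError(
                    f"unknown response_category {self.response_category!r}"
                )
            if not self.received_nact:
                raise ValueError(
                    "response_category defined only when received_nact is true"
                )


class CohortManifest:
    """Ordered collection of patient records, round-trippable through CSV."""

    def __init__(self, records: list[PatientRecord]):
        self.records = list(records)

    def __len__(self):
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def eligible(self) -> list[PatientRecord]:
        return [r for r in self.records if r.received_nact and r.mri_complete]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "patient_id": r.patient_id,
                "response_category": r.response_category or "",
                "received_nact": r.received_nact,
                "mri_complete": r.mri_complete,
                "pre_path": r.pre_path or "",
                "post_path": r.post_path or "",
            }
            for r in self.records
        ]
        return pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS))

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CohortManifest":
        df = pd.read_csv(path, keep_default_na=False)
        missing = set(MANIFEST_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"manifest missing columns: {sorted(missing)}")
        records = [
            PatientRecord(
                patient_id=str(row.patient_id),
                response_category=row.response_category or None,
                received_nact=_as_bool(row.received_nact),
                mri_complete=_as_bool(row.mri_complete),
                pre_path=row.pre_path or None,
                post_path=row.post_path or None,
            )
            for row in df.itertuples()
        ]
        return cls(records)


def _as_bool(v) -> bool:
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    return str(v).strip().lower() in {"true", "1"}


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------


def generate_cohort(
    n_patients: int,
    n_incomplete: int,
    category_counts: dict[str, int],
    seed: int,
    n_no_nact: int = 0,
) -> CohortManifest:
    """Generate a cohort manifest with exact category allocation.

    Exactly `n_incomplete` records are flagged mri_complete=False and
    `n_no_nact` records received_nact=False; these ineligible records carry
    no response category. The remaining eligible records are allocated to
    the requested RECIST categories exactly (not sampled). Which patients
    are ineligible, and the interleaving of categories, are shuffled
    deterministically under `seed`.
    """
    if n_patients < 0 or n_incomplete < 0 or n_no_nact < 0:
        raise ValueError("counts must be nonnegative")
    if n_incomplete + n_no_nact > n_patients:
        raise ValueError(
            f"n_incomplete ({n_incomplete}) + n_no_nact ({n_no_nact}) "
            f"exceeds n_patients ({n_patients})"
        )
    for cat in category_counts:
        if cat not in RESPONSE_CATEGORIES:
            raise ValueError(f"unknown category in category_counts: {cat!r}")
    n_eligible = n_patients - n_incomplete - n_no_nact
    total = sum(int(c) for c in category_counts.values())
    if total != n_eligible:
        raise ValueError(
            f"category_counts sum to {total}, expected n_patients - "
            f"n_incomplete - n_no_nact = {n_eligible}"
        )

    rng = np.random.default_rng(seed)
    categories: list[str | None] = []
    for cat in RESPONSE_CATEGORIES:
        categories.extend([cat] * int(category_counts.get(cat, 0)))
    flags = (
        [("eligible", c) for c in categories]
        + [("incomplete", None)] * n_incomplete
        + [("no_nact", None)] * n_no_nact
    )
    order = rng.permutation(len(flags))
    records = []
    for i, idx in enumerate(order):
        kind, cat = flags[idx]
        records.append(
            PatientRecord(
                patient_id=f"P{i:04d}",
                response_category=cat if kind == "eligible" else None,
                received_nact=kind != "no_nact",
                mri_complete=kind != "incomplete",
            )
        )
    return CohortManifest(records)


def enhancement_curve(
    phase: np.ndarray | int,
    washin_rate: float,
    washout_rate: float,
) -> np.ndarray:
    """Wash-in/wash-out kinetic curve u(p) for dynamic phase p = 0..5.

    u(p) = (1 − e^(−washin·p)) · e^(−washout·max(0, p−3)): zero at S0,
    monotone wash-in through the early phases, optional late washout.
    """
    p = np.asarray(phase, dtype=np.float64)
    return (1.0 - np.exp(-washin_rate * p)) * np.exp(
        -washout_rate * np.maximum(0.0, p - 3.0)
    )


def breast_mask_geometry(image_size: tuple[int, int]) -> np.ndarray:
    """Ground-truth breast-tissue mask for a phantom of the given size.

    The breast is an ellipse occupying most of the field of view; the
    bottom rows are the chest-wall band and the 2-pixel outer shell of the
    ellipse is the skin rim — both are excluded from the tissue mask.
    """
    H, W = image_size
    rows, cols = np.mgrid[0:H, 0:W]
    cy, cx = 0.42 * H, 0.5 * W
    ry, rx = 0.40 * H, 0.42 * W
    ellipse = ((rows - cy) / ry) ** 2 + ((cols - cx) / rx) ** 2
    inner = ellipse <= (1.0 - 2.0 / min(ry, rx)) ** 2
    chest = rows >= int(0.88 * H)
    return inner & ~chest


def _phantom_regions(image_size: tuple[int, int]):
    H, W = image_size
    rows, cols = np.mgrid[0:H, 0:W]
    cy, cx = 0.42 * H, 0.5 * W
    ry, rx = 0.40 * H, 0.42 * W
    ellipse = ((rows - cy) / ry) ** 2 + ((cols - cx) / rx) ** 2
    outer = ellipse <= 1.0
    tissue = breast_mask_geometry(image_size)
    skin = outer & ~tissue & (rows < int(0.88 * H))
    chest = (rows >= int(0.88 * H)) & (rows < int(0.95 * H))
    return tissue, skin, chest


def simulate_dce_series(
    lesion: LesionParams,
    image_size: tuple[int, int] = (64, 64),
    noise_sd: float = 0.02,
    seed: int = 0,
    pixel_spacing: float = DEFAULT_PIXEL_SPACING,
) -> DCESeries:
    """Render one six-phase phantom slice containing the given lesion.

    Inside the lesion disc, phase p has intensity
    baseline + amplitude·u(p) (+ Gaussian noise); u is `enhancement_curve`.
    Tissue, skin rim and chest wall are rendered outside; the background is
    near zero. Deterministic under `seed`.
    """
    H, W = image_size
    if H < 16 or W < 16:
        raise ValueError(f"image size must be at least 16x16, got {image_size}")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")

    rng = np.random.default_rng(seed)
    tissue, skin, chest = _phantom_regions(image_size)

    base = np.full((H, W), 0.05)
    base[tissue] = 0.35
    base[skin] = 0.90
    base[chest] = 0.70
    # frozen parenchymal texture, shared by all phases of this series
    texture = 0.04 * rng.standard_normal((H, W)) * tissue

    rows, cols = np.mgrid[0:H, 0:W]
    radius_px = 0.5 * lesion.diameter / pixel_spacing
    dist = np.hypot(rows - lesion.center[0], cols - lesion.center[1])
    disc = dist <= radius_px

    u = enhancement_curve(
        np.arange(N_PHASES), lesion.washin_rate, lesion.washout_rate
    )
    phases = np.empty((N_PHASES, H, W))
    for p in range(N_PHASES):
        img = base + texture + lesion.enhancement_amplitude * u[p] * disc
        if noise_sd > 0:
            img = img + noise_sd * rng.standard_normal((H, W))
        phases[p] = img
    return DCESeries(phases, pixel_spacing=pixel_spacing)


def lesion_mask(
    lesion: LesionParams,
    image_size: tuple[int, int],
    pixel_spacing: float = DEFAULT_PIXEL_SPACING,
) -> np.ndarray:
    """Boolean disc mask of the lesion at the phantom's pixel grid."""
    H, W = image_size
    rows, cols = np.mgrid[0:H, 0:W]
    radius_px = 0.5 * lesion.diameter / pixel_spacing
    return np.hypot(rows - lesion.center[0], cols - lesion.center[1]) <= radius_px


def simulate_followup(
    pre_lesion: LesionParams,
    response_category: str,
    seed: int,
    sd_change_range: tuple[float, float] | None = None,
) -> LesionParams:
    """Draw the post-first-cycle lesion implied by a RECIST category.

    CR: diameter 0. PR: shrinkage fraction uniform in [0.30, 0.95].
    SD: relative diameter change uniform in (−0.30, +0.20) (open interval
    approximated by a small margin), or in `sd_change_range` when given —
    e.g. (−0.10, 0.10) for a cleanly separable cohort. PD: growth uniform
    in [0.20, 0.60]. The enhancement amplitude scales by the same diameter
    factor.
    """
    if pre_lesion.diameter <= 0:
        raise ValueError("pre_lesion.diameter must be > 0")
    rng = np.random.default_rng(seed)
    if response_category == "CR":
        factor = 0.0
    elif response_category == "PR":
        factor = 1.0 - rng.uniform(RECIST_PR_SHRINKAGE, 0.95)
    elif response_category == "SD":
        lo, hi = sd_change_range or (
            -(RECIST_PR_SHRINKAGE - 0.01),
            RECIST_PD_GROWTH - 0.01,
        )
        factor = 1.0 + rng.uniform(lo, hi)
    elif response_category == "PD":
        factor = 1.0 + rng.uniform(RECIST_PD_GROWTH, 0.60)
    else:
        raise ValueError(f"unknown response category {response_category!r}")
    return LesionParams(
        center=pre_lesion.center,
        diameter=pre_lesion.diameter * factor,
        enhancement_amplitude=pre_lesion.enhancement_amplitude * factor,
        washin_rate=pre_lesion.washin_rate,
        washout_rate=pre_lesion.washout_rate,
    )


def sample_lesion(
    rng: np.random.Generator,
    image_size: tuple[int, int] = (64, 64),
    pixel_spacing: float = DEFAULT_PIXEL_SPACING,
) -> LesionParams:
    """Draw a plausible pre-treatment lesion inside the breast region."""
    H, W = image_size
    # keep the disc inside the tissue ellipse
    center = (
        rng.uniform(0.25 * H, 0.60 * H),
        rng.uniform(0.30 * W, 0.70 * W),
    )
    diameter = float(np.clip(rng.lognormal(np.log(22.0), 0.25), 10.0, 0.35 * H * pixel_spacing))
    return LesionParams(
        center=center,
        diameter=diameter,
        enhancement_amplitude=rng.uniform(0.8, 1.2),
        washin_rate=rng.uniform(1.0, 1.5),
        washout_rate=rng.uniform(0.05, 0.25),
    )


def simulate_patient_pair(
    record: PatientRecord,
    seed: int,
    image_size: tuple[int, int] = (64, 64),
    noise_sd: float = 0.02,
    pixel_spacing: float = DEFAULT_PIXEL_SPACING,
    sd_change_range: tuple[float, float] | None = None,
) -> tuple[DCESeries, DCESeries, LesionParams, LesionParams]:
    """Simulate the pre/post series pair for one eligible patient."""
    if record.response_category is None:
        raise ValueError(f"patient {record.patient_id} has no response category")
    base_seed = np.random.default_rng([seed, _stable_id(record.patient_id)])
    lesion_rng = np.random.default_rng(base_seed.integers(2**31))
    pre = sample_lesion(lesion_rng, image_size, pixel_spacing)
    post = simulate_followup(
        pre,
        record.response_category,
        int(base_seed.integers(2**31)),
        sd_change_range=sd_change_range,
    )
    pre_series = simulate_dce_series(
        pre, image_size, noise_sd, int(base_seed.integers(2**31)), pixel_spacing
    )
    post_series = simulate_dce_series(
        post, image_size, noise_sd, int(base_seed.integers(2**31)), pixel_spacing
    )
    return pre_series, post_series, pre, post


def _stable_id(patient_id: str) -> int:
    return int.from_bytes(patient_id.encode(), "little") % (2**31)


# ---------------------------------------------------------------------------
# Disk I/O
# ---------------------------------------------------------------------------


def write_series(series: DCESeries, path: Path) -> None:
    """Write a six-phase series as NIfTI with phases in the 4th dimension."""
    arr = np.transpose(series.phases, (1, 2, 0))[:, :, None, :]  # (H, W, 1, 6)
    affine = np.diag(
        [series.pixel_spacing, series.pixel_spacing,
         series.slice_thickness + series.interslice_gap, 1.0]
    )
    img = nib.Nifti1Image(arr.astype(np.float32), affine)
    img.header.set_zooms(
        (series.pixel_spacing, series.pixel_spacing,
         series.slice_thickness + series.interslice_gap, 1.0)
    )
    nib.save(img, str(path))


def read_series(path) -> DCESeries:
    img = nib.load(str(path))
    arr = np.asarray(img.dataobj, dtype=np.float64)
    if arr.ndim != 4 or arr.shape[3] != N_PHASES:
        raise ValueError(f"expected (H, W, 1, {N_PHASES}) series, got {arr.shape}")
    zooms = img.header.get_zooms()
    return DCESeries(
        np.transpose(arr[:, :, 0, :], (2, 0, 1)),
        pixel_spacing=float(zooms[0]),
    )


def write_cohort(
    manifest: CohortManifest,
    out_dir,
    seed: int = 0,
    image_size: tuple[int, int] = (64, 64),
    noise_sd: float = 0.02,
    sd_change_range: tuple[float, float] | None = None,
) -> CohortManifest:
    """Render and write every complete record's image pair plus the manifest.

    Incomplete records stay in the manifest without image files. Returns a
    manifest whose paths resolve. A JSON sidecar records the seed and
    generation parameters.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = []
    for record in manifest:
        rec = dataclasses.replace(record)
        if rec.mri_complete and rec.received_nact and rec.response_category:
            pre_s, post_s, _, _ = simulate_patient_pair(
                rec, seed, image_size, noise_sd, sd_change_range=sd_change_range
            )
            pre_path = out_dir / f"{rec.patient_id}_pre.nii.gz"
            post_path = out_dir / f"{rec.patient_id}_post.nii.gz"
            write_series(pre_s, pre_path)
            write_series(post_s, post_path)
            rec.pre_path = str(pre_path)
            rec.post_path = str(post_path)
        records.append(rec)
    out = CohortManifest(records)
    out.to_csv(out_dir / "manifest.csv")
    sidecar = {
        "seed": int(seed),
        "image_size": list(image_size),
        "noise_sd": float(noise_sd),
        "n_patients": len(out),
    }
    (out_dir / "cohort.json").write_text(json.dumps(sidecar, indent=2))
    return out
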