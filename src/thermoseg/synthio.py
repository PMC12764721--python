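"""Synthetic plantar thermograms and the on-disk dataset layout.

Real plantar thermograms encode skin surface temperature of the sole; in
diabetic subjects, focal hyperthermic regions ("hot spots") mark elevated
ulceration risk.  The generator here emulates a two-group cohort — a control
group (CG) with a smooth plantar temperature field and a diabetic group (DM)
whose fields additionally carry hot-spot lesions — together with pixel-exact
ground-truth lesion masks, which real thermographic datasets typically lack.

The parametric image model: a foot-shaped support (two overlapping ellipses
for sole and heel plus five toe discs), a smooth low-frequency temperature
gradient across the sole, additive Gaussian sensor noise, and, for DM
subjects, one or more radially Gaussian lesions of configurable contrast.
Intensities are relative temperature units in [0, 1], not calibrated °C.

On disk, a cohort is a directory of 16-bit grayscale PNGs named
``{group}{code}{gender}_{side}.png`` (e.g. ``DM003F_left.png``), optional
8-bit ``*_mask.png`` companions, and a CSV manifest.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

__all__ = [
    "Group",
    "Gender",
    "Side",
    "SubjectMeta",
    "ThermogramRecord",
    "SynthConfig",
    "generate_cohort",
    "write_dataset",
    "read_dataset",
    "MANIFEST_COLUMNS",
]

MANIFEST_COLUMNS = ["filename", "mask_filename", "subject_code", "group",
                    "gender", "side", "label"]

#: class index convention used throughout the package
LABELS = {"CG": 0, "DM": 1}


class Group(str, enum.Enum):
    CG = "CG"
    DM = "DM"


class Gender(str, enum.Enum):
    M = "M"
    F = "F"


class Side(str, enum.Enum):
    LEFT = "left"
    RIGHT = "right"


@dataclass(frozen=True)
class SubjectMeta:
    """Identity of one subject-foot: three-digit code, group, gender, side."""

    subject_code: str
    group: Group
    gender: Gender
    side: Side

    def __post_init__(self):
        if not re.fullmatch(r"[0-9]{3}", self.subject_code):
            raise ValueError(
                f"subject_code must be a three-digit string, got {self.subject_code!r}")
        object.__setattr__(self, "group", Group(self.group))
        object.__setattr__(self, "gender", Gender(self.gender))
        object.__setattr__(self, "side", Side(self.side))

    @property
    def filename_stem(self) -> str:
        return f"{self.group.value}{self.subject_code}{self.gender.value}_{self.side.value}"


@dataclass
class ThermogramRecord:
    """One thermogram with optional ground-truth lesion mask."""

    meta: SubjectMeta
    image: np.ndarray
    mask: np.ndarray | None = None
    label: int = field(default=-1)

    def __post_init__(self):
        self.image = np.asarray(self.image, dtype=np.float64)
        if self.image.ndim != 2:
            raise ValueError(f"image must be 2-D, got shape {self.image.shape}")
        if not np.all(np.isfinite(self.image)):
            raise ValueError("image contains non-finite values")
        if self.image.min() < 0 or self.image.max() > 1:
            raise ValueError("image values must lie in [0, 1]")
        if self.mask is not None:
            self.mask = np.asarray(self.mask)
            if self.mask.shape != self.image.shape:
                raise ValueError(
                    f"mask shape {self.mask.shape} != image shape {self.image.shape}")
            vals = np.unique(self.mask)
            if not np.all(np.isin(vals, (0, 1))):
                raise ValueError("mask must be binary (values in {0, 1})")
            self.mask = self.mask.astype(np.uint8)
        if self.label == -1:
            self.label = LABELS[self.meta.group.value]


@dataclass
class SynthConfig:
    """Cohort-generation parameters.

    Defaults mirror the study composition this package emulates:
    122 diabetic and 45 control subjects, with desk-scale 64x64 images.
    """

    n_dm: int = 122
    n_cg: int = 45
    image_size: int = 64
    lesion_count_range: tuple[int, int] = (1, 3)
    lesion_radius_range: tuple[float, float] = (4.0, 8.0)
    lesion_contrast: float = 0.35
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.n_dm < 0:
            raise ValueError(f"n_dm must be >= 0, got {self.n_dm}")
        if self.n_cg < 0:
            raise ValueError(f"n_cg must be >= 0, got {self.n_cg}")
        if self.image_size < 16:
            raise ValueError(f"image_size must be >= 16, got {self.image_size}")
        lo, hi = self.lesion_count_range
        if not (0 < lo <= hi):
            raise ValueError(f"lesion_count_range must satisfy 0 < lo <= hi, got {(lo, hi)}")
        rlo, rhi = self.lesion_radius_range
        if not (0 < rlo <= rhi):
            raise ValueError(f"lesion_radius_range must satisfy 0 < lo <= hi, got {(rlo, rhi)}")
        if self.lesion_contrast <= 0:
            raise ValueError(f"lesion_contrast must be > 0, got {self.lesion_contrast}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")


# ---------------------------------------------------------------------------
# image model
# ---------------------------------------------------------------------------

def _foot_support(n: int) -> np.ndarray:
    """Binary foot silhouette: sole + heel ellipses and five toe discs."""
    yy, xx = np.mgrid[0:n, 0:n] / (n - 1)
    sole = ((yy - 0.52) / 0.30) ** 2 + ((xx - 0.5) / 0.18) ** 2 <= 1.0
    heel = ((yy - 0.80) / 0.14) ** 2 + ((xx - 0.5) / 0.13) ** 2 <= 1.0
    support = sole | heel
    toe_x = np.linspace(0.30, 0.70, 5)
    toe_r = np.linspace(0.055, 0.035, 5)
    for cx, r in zip(toe_x, toe_r):
        support |= (yy - 0.17) ** 2 + (xx - cx) ** 2 <= r ** 2
    return support


def _base_field(n: int, rng: np.random.Generator) -> np.ndarray:
    """Smooth low-frequency plantar temperature field in relative units."""
    yy, xx = np.mgrid[0:n, 0:n] / (n - 1)
    a, b, c = rng.uniform(-1.0, 1.0, 3)
    field = 0.35 + 0.06 * (a * np.sin(np.pi * yy + b) + c * (xx - 0.5))
    # arch of the foot runs slightly cooler
    field -= 0.05 * np.exp(-(((yy - 0.5) / 0.18) ** 2 + ((xx - 0.5) / 0.12) ** 2))
    return field


def _synth_record(meta: SubjectMeta, cfg: SynthConfig,
                  rng: np.random.Generator) -> ThermogramRecord:
    n = cfg.image_size
    support = _foot_support(n)
    image = np.where(support, _base_field(n, rng), 0.08)
    mask = np.zeros((n, n), dtype=np.uint8)

    if meta.group is Group.DM:
        from scipy import ndimage

        yy, xx = np.mgrid[0:n, 0:n]
        dist_in = ndimage.distance_transform_edt(support)
        n_lesions = rng.integers(cfg.lesion_count_range[0],
                                 cfg.lesion_count_range[1] + 1)
        placed = 0
        attempts = 0
        while placed < n_lesions and attempts < 500:
            attempts += 1
            r = rng.uniform(*cfg.lesion_radius_range)
            sigma = r / 2.0
            # the mask is the half-maximum footprint of the Gaussian profile
            r_mask = sigma * np.sqrt(2.0 * np.log(2.0))
            cy, cx = rng.integers(0, n, 2)
            if dist_in[cy, cx] < r_mask + 1.5:
                continue  # footprint must sit on the sole
            profile = cfg.lesion_contrast * np.exp(
                -((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma ** 2))
            new = profile >= 0.5 * cfg.lesion_contrast
            # keep footprints separated so the component count is exact
            if mask.any():
                near = ndimage.binary_dilation(new, iterations=2)
                if (near & (mask > 0)).any():
                    continue
            image = image + profile
            mask |= new.astype(np.uint8)
            placed += 1
        if placed < n_lesions:
            raise RuntimeError(
                f"could not place {n_lesions} lesions on a {n}x{n} support")

    if cfg.noise_sd > 0:
        image = image + rng.normal(0.0, cfg.noise_sd, (n, n))
    image = np.clip(image, 0.0, 1.0)
    return ThermogramRecord(meta=meta, image=image, mask=mask)


def generate_cohort(cfg: SynthConfig) -> list[ThermogramRecord]:
    """Generate ``cfg.n_dm + cfg.n_cg`` records, deterministically per seed.

    Every DM record's mask contains at least one connected hot-spot component;
    every CG mask is all-zero.  Subject codes run sequentially so that
    (code, side) is unique across the cohort.
    """
    rng = np.random.default_rng(cfg.seed)
    records = []
    groups = [Group.DM] * cfg.n_dm + [Group.CG] * cfg.n_cg
    for i, group in enumerate(groups):
        meta = SubjectMeta(
            subject_code=f"{i % 1000:03d}",
            group=group,
            gender=Gender.M if rng.random() < 0.5 else Gender.F,
            side=Side.LEFT if rng.random() < 0.5 else Side.RIGHT,
        )
        records.append(_synth_record(meta, cfg, rng))
    return records


# ---------------------------------------------------------------------------
# on-disk layout
# ---------------------------------------------------------------------------

def write_dataset(records: list[ThermogramRecord], root_path) -> Path:
    """Write images (16-bit PNG), masks (8-bit PNG) and a CSV manifest.

    Returns the manifest path.  Raises on duplicate (subject_code, side).
    """
    root = Path(root_path)
    root.mkdir(parents=True, exist_ok=True)
    seen = set()
    rows = []
    for rec in records:
        key = (rec.meta.subject_code, rec.meta.side)
        if key in seen:
            raise ValueError(
                f"duplicate (subject_code, side) pair: {key[0]}/{key[1].value}")
        seen.add(key)
        stem = rec.meta.filename_stem
        img16 = np.round(rec.image * 65535.0).astype(np.uint16)
        iio.imwrite(root / f"{stem}.png", img16)
        mask_name = ""
        if rec.mask is not None:
            mask_name = f"{stem}_mask.png"
            iio.imwrite(root / mask_name, (rec.mask * 255).astype(np.uint8))
        rows.append({
            "filename": f"{stem}.png",
            "mask_filename": mask_name,
            "subject_code": rec.meta.subject_code,
            "group": rec.meta.group.value,
            "gender": rec.meta.gender.value,
            "side": rec.meta.side.value,
            "label": rec.label,
        })
    manifest = root / "manifest.csv"
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(manifest, index=False)
    return manifest


def _load_image(path: Path) -> np.ndarray:
    arr = iio.imread(path)
    if arr.ndim == 3:  # e.g. grayscale stored with a channel axis
        arr = arr[..., 0]
    if arr.dtype == np.uint8:
        return arr.astype(np.float64) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(np.float64) / 65535.0
    arr = arr.astype(np.float64)
    top = arr.max()
    return arr / top if top > 1.0 else arr


def read_dataset(manifest_path) -> list[ThermogramRecord]:
    """Load a cohort written by :func:`write_dataset` (PNG or TIFF images).

    Images are normalized to [0, 1] by their dtype range; masks are
    binarized at 0.5.
    """
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise FileNotFoundError(f"manifest not found: {manifest_path}")
    root = manifest_path.parent
    df = pd.read_csv(manifest_path, keep_default_na=False)
    records = []
    for row in df.itertuples(index=False):
        img_path = root / row.filename
        if not img_path.exists():
            raise FileNotFoundError(f"image file missing: {img_path}")
        image = _load_image(img_path)
        mask = None
        if row.mask_filename:
            mask_path = root / row.mask_filename
            if not mask_path.exists():
                raise FileNotFoundError(f"mask file missing: {mask_path}")
            mask = (_load_image(mask_path) >= 0.5).astype(np.uint8)
        meta = SubjectMeta(subject_code=f"{int(row.subject_code):03d}",
                           group=row.group, gender=row.gender, side=row.side)
        records.append(ThermogramRecord(meta=meta, image=image, mask=mask,
                                        label=int(row.label)))
    return records
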