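"""Seeded synthetic chest-radiograph-like cohorts with paired report text.

The generator produces small grayscale images in which an apical crescent
of reduced intensity stands in for a pneumothorax. Difficulty is encoded
the way it presents clinically: lesion contrast increases with lesion size,
so large lesions are easy and small ones are subtle. Every image carries
ground-truth metadata (size class under a pixel analog of the ACCP 3 cm
rule, demographics, site, manufacturer) and a templated radiology sentence
set, so the report labeler, curriculum scheduler, training loop and
validation statistics can all be exercised end to end without clinical
data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "LesionSpec",
    "ImageSample",
    "CohortSpec",
    "generate_image",
    "generate_cohort",
    "generate_report",
    "lesion_area_score",
    "write_cohort",
    "write_reports",
]

RIGHT_LOBES = ("RUL", "RML", "RLL")
LEFT_LOBES = ("LUL", "LLL")

# Table-style marginals for the external-validation cohort: sex 162M/138F,
# age 62/81/114/43, site 2:1 US:Taiwan, manufacturers 147/45/55/53 of 300.
DEFAULT_SEX_WEIGHTS = {"male": 162 / 300, "female": 138 / 300}
DEFAULT_AGE_WEIGHTS = {
    "18-34": 62 / 300, "35-49": 81 / 300, "50-64": 114 / 300, "65+": 43 / 300,
}
DEFAULT_SITE_WEIGHTS = {"US": 2 / 3, "Taiwan": 1 / 3}
DEFAULT_MANUFACTURER_WEIGHTS = {
    "Samsung Electronics": 147 / 300,
    "Shimadzu": 45 / 300,
    "Toshiba": 55 / 300,
    "Others": 53 / 300,
}


@dataclass(frozen=True)
class LesionSpec:
    """Ground-truth description of one (possible) lesion.

    ``size_px`` is the in-image analog of the apex-to-cupola distance;
    ``contrast`` is the intensity deficit of the crescent relative to the
    surrounding lung field, in [0, 1].
    """

    present: bool
    size_px: float = 0.0
    contrast: float = 0.3
    side: str = "right"
    lobe: str = "RUL"

    def __post_init__(self) -> None:
        if self.present and self.size_px <= 0:
            raise ValueError("present lesion requires size_px > 0")
        if self.present and not 0 < self.contrast <= 1:
            raise ValueError("contrast must be in (0, 1]")
        if self.side not in ("left", "right"):
            raise ValueError(f"unknown side {self.side!r}")
        ok = RIGHT_LOBES if self.side == "right" else LEFT_LOBES
        if self.present and self.lobe not in ok:
            raise ValueError(f"lobe {self.lobe} inconsistent with side {self.side}")


@dataclass
class ImageSample:
    id: str
    pixels: np.ndarray
    label: str  # positive | negative
    size_class: str  # large | small | none
    size_px: float = 0.0
    sex: str | None = None
    age_group: str | None = None
    site: str | None = None
    manufacturer: str | None = None
    side: str | None = None
    lobe: str | None = None


@dataclass
class CohortSpec:
    """Cohort composition and difficulty-link parameters.

    Defaults emulate the development-cohort structure: prevalence
    2554/6445 (~39.6% positive) and small-lesion share 773/2554 (~30.3%
    of positives), with metadata drawn from external-validation marginals.
    ``contrast = c0 + c1 * size_px / size_max_px`` links size to
    detectability (smaller is subtler). ``size_threshold_px`` is the pixel
    analog of the ACCP 3 cm large/small rule.
    """

    n: int
    prevalence: float = 2554 / 6445
    small_share: float = 773 / 2554
    exact: bool = False
    shape: tuple[int, int] = (64, 64)
    size_threshold_px: float = 12.0
    size_min_px: float = 4.0
    size_max_px: float = 24.0
    c0: float = 0.05
    c1: float = 0.5
    sex_weights: dict = field(default_factory=lambda: dict(DEFAULT_SEX_WEIGHTS))
    age_weights: dict = field(default_factory=lambda: dict(DEFAULT_AGE_WEIGHTS))
    site_weights: dict = field(default_factory=lambda: dict(DEFAULT_SITE_WEIGHTS))
    manufacturer_weights: dict = field(
        default_factory=lambda: dict(DEFAULT_MANUFACTURER_WEIGHTS)
    )
    render: bool = True  # False: metadata-only cohort (pixels omitted)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("n must be >= 0")
        for name in ("prevalence", "small_share"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if not (0 < self.size_min_px < self.size_threshold_px < self.size_max_px):
            raise ValueError("need size_min < threshold < size_max")

    def contrast_for(self, size_px: float) -> float:
        return float(np.clip(self.c0 + self.c1 * size_px / self.size_max_px, 0.01, 1.0))


def _background(shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    """Gaussian-smoothed noise plus rib-like sinusoidal bands.

    The texture is deliberately non-flat so a global-mean-intensity
    classifier carries no signal; only local apical darkening does.
    """
    h, w = shape
    noise = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=2.0)
    sd = noise.std()
    if sd > 0:
        noise /= sd
    rows = np.arange(h)[:, None] / h
    bands = np.zeros(shape)
    for freq in (3.0, 5.0, 7.0, 9.0):  # 4 rib-like horizontal bands
        bands += np.sin(2 * np.pi * freq * rows + rng.uniform(0, 2 * np.pi))
    bands /= 4.0
    img = 0.55 + 0.12 * noise + 0.08 * np.broadcast_to(bands, shape)
    return np.clip(img, 0.25, 0.85)


def lesion_mask(
    shape: tuple[int, int], size_px: float, side: str, rng: np.random.Generator
) -> np.ndarray:
    """Boolean apical-crescent mask with area proportional to size_px**2."""
    h, w = shape
    cx = w * (0.72 if side == "right" else 0.28) + rng.uniform(-2, 2)
    cy = h * 0.12 + rng.uniform(-1, 1)
    yy, xx = np.mgrid[0:h, 0:w]
    r = size_px
    outer = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
    inner = (yy - (cy + 0.6 * r)) ** 2 + (xx - cx) ** 2 <= r**2
    crescent = outer & ~inner & (yy >= 0)
    if not crescent.any():  # tiny lesion: keep at least the apex pixel
        crescent[int(max(cy, 0)), int(np.clip(cx, 0, w - 1))] = True
    return crescent


def generate_image(
    spec: LesionSpec,
    shape: tuple[int, int] = (64, 64),
    seed: int = 0,
    size_threshold_px: float = 12.0,
    sample_id: str = "img",
    return_mask: bool = False,
):
    """Render one synthetic radiograph-like image from a lesion spec.

    The lesion, when present, is an apical crescent of reduced intensity:
    amplitude proportional to ``spec.contrast``, area proportional to
    ``spec.size_px ** 2``. Same spec and seed give bit-identical pixels.
    """
    if min(shape) < 16:
        raise ValueError("shape must be at least 16x16")
    if spec.present and spec.size_px >= min(shape) / 2:
        raise ValueError("lesion size_px must be < min(shape)/2")
    rng = np.random.default_rng(seed)
    img = _background(shape, rng)
    mask = np.zeros(shape, dtype=bool)
    if spec.present:
        mask = lesion_mask(shape, spec.size_px, spec.side, rng)
        soft = ndimage.gaussian_filter(mask.astype(float), sigma=0.8)
        soft /= max(soft.max(), 1e-12)
        img = img - spec.contrast * soft
    img = np.clip(img, 0.0, 1.0)
    if spec.present:
        size_class = "large" if spec.size_px >= size_threshold_px else "small"
        label = "positive"
    else:
        size_class, label = "none", "negative"
    sample = ImageSample(
        id=sample_id,
        pixels=img,
        label=label,
        size_class=size_class,
        size_px=spec.size_px if spec.present else 0.0,
        side=spec.side if spec.present else None,
        lobe=spec.lobe if spec.present else None,
    )
    return (sample, mask) if return_mask else sample


def lesion_area_score(pixels: np.ndarray, dark_threshold: float = 0.35) -> float:
    """Oracle difficulty probe: apical dark-pixel count.

    Counts pixels in the apical band (top 40% of rows) darker than a fixed
    intensity threshold — a stand-in reader that keys directly on lesion
    area. Large high-contrast lesions produce many such pixels, small
    low-contrast ones few, so this score separates large positives from
    negatives better than small positives from negatives.
    """
    h = pixels.shape[0]
    apex = pixels[: int(0.4 * h)]
    return float(np.sum(apex < dark_threshold))


def _draw_categorical(rng: np.random.Generator, weights: dict) -> str:
    keys = list(weights)
    p = np.asarray([weights[k] for k in keys], dtype=float)
    p = p / p.sum()
    return keys[rng.choice(len(keys), p=p)]


def _draw_lesion_geometry(rng: np.random.Generator, size_px: float) -> tuple[str, str]:
    side = "right" if rng.random() < 0.5 else "left"
    if side == "right":
        lobe = RIGHT_LOBES[rng.choice(3, p=[0.5, 0.2, 0.3])]
    else:
        lobe = LEFT_LOBES[rng.choice(2, p=[0.6, 0.4])]
    return side, lobe


def generate_cohort(spec: CohortSpec) -> tuple[list[ImageSample], pd.DataFrame]:
    """Generate a full cohort of images plus its metadata table.

    With ``spec.exact`` the positive and small counts are deterministic
    quotas (round(n * prevalence), round(n_pos * small_share)); otherwise
    they are binomial draws at those rates. Identical spec (including
    seed) yields a bit-identical cohort.
    """
    if spec.n == 0:
        raise ValueError("empty cohort: n must be >= 1")
    rng = np.random.default_rng(spec.seed)
    if spec.exact:
        n_pos = int(round(spec.n * spec.prevalence))
        n_small = int(round(n_pos * spec.small_share))
    else:
        n_pos = int(rng.binomial(spec.n, spec.prevalence))
        n_small = int(rng.binomial(n_pos, spec.small_share))
    n_large = n_pos - n_small

    kinds = ["small"] * n_small + ["large"] * n_large + ["none"] * (spec.n - n_pos)
    order = rng.permutation(spec.n)
    samples: list[ImageSample] = []
    rows = []
    for i in range(spec.n):
        kind = kinds[order[i]]
        sid = f"s{i:05d}"
        if kind == "none":
            lspec = LesionSpec(present=False)
        else:
            if kind == "small":
                size = rng.uniform(spec.size_min_px, spec.size_threshold_px)
            else:
                size = rng.uniform(spec.size_threshold_px, spec.size_max_px)
            side, lobe = _draw_lesion_geometry(rng, size)
            lspec = LesionSpec(
                present=True, size_px=size,
                contrast=spec.contrast_for(size), side=side, lobe=lobe,
            )
        img_seed = int(rng.integers(0, 2**31 - 1))
        if spec.render:
            sample = generate_image(
                lspec, spec.shape, seed=img_seed,
                size_threshold_px=spec.size_threshold_px, sample_id=sid,
            )
        else:  # metadata-only: same rng consumption, no pixel rendering
            sample = ImageSample(
                id=sid, pixels=None,
                label="positive" if lspec.present else "negative",
                size_class=kind if lspec.present else "none",
                size_px=lspec.size_px if lspec.present else 0.0,
                side=lspec.side if lspec.present else None,
                lobe=lspec.lobe if lspec.present else None,
            )
        sample.sex = _draw_categorical(rng, spec.sex_weights)
        sample.age_group = _draw_categorical(rng, spec.age_weights)
        sample.site = _draw_categorical(rng, spec.site_weights)
        sample.manufacturer = _draw_categorical(rng, spec.manufacturer_weights)
        samples.append(sample)
        rows.append(
            {
                "id": sample.id, "label": sample.label,
                "size_class": sample.size_class, "sex": sample.sex,
                "age_group": sample.age_group, "site": sample.site,
                "manufacturer": sample.manufacturer,
                "size_px": round(sample.size_px, 3),
            }
        )
    return samples, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Report templates. Adjectives and the pixel->cm mapping are chosen so the
# rule-based extractor round-trips exactly: large adjectives only on large
# lesions, measurements never rounded across the 3 cm boundary.

_NEGATIVE_TEMPLATES = (
    "No evidence of pneumothorax.",
    "No pneumothorax is seen.",
    "Lungs are clear without pneumothorax.",
    "Negative for pneumothorax.",
    "No residual pneumothorax following treatment.",
)
_DISTRACTORS = (
    "Small left pleural effusion.",
    "Heart size is normal.",
    "Degenerative changes of the thoracic spine.",
    "Large hiatal hernia noted.",
)
_ADJ = {"large": ("large", "moderate"), "small": ("small", "tiny")}
_ADJ_TEMPLATES = (
    "{adj} {side} apical pneumothorax.",
    "There is a {adj} pneumothorax on the {side}.",
    "{adj} pneumothorax involving the {lobe}.",
)
_CM_TEMPLATES = (
    "Pneumothorax measuring {cm} cm from cupola to apex.",
    "A {cm} cm apical pneumothorax is present on the {side}.",
)
_MM_TEMPLATE = "Pneumothorax with an apical depth of {mm} mm on the {side}."


def size_px_to_cm(size_px: float, threshold_px: float = 12.0) -> float:
    """Map lesion pixels to the cm scale where threshold_px <-> 3 cm."""
    return size_px / threshold_px * 3.0


def generate_report(sample: ImageSample, seed: int = 0,
                    threshold_px: float = 12.0) -> str:
    """Templated radiology sentences consistent with the sample's truth."""
    rng = np.random.default_rng(seed)
    if sample.label == "negative":
        text = _NEGATIVE_TEMPLATES[rng.integers(len(_NEGATIVE_TEMPLATES))]
    else:
        side = sample.side or "right"
        lobe = sample.lobe or "RUL"
        if rng.random() < 0.5:  # adjective phrasing
            adj = _ADJ[sample.size_class][rng.integers(2)]
            tmpl = _ADJ_TEMPLATES[rng.integers(len(_ADJ_TEMPLATES))]
            text = tmpl.format(adj=adj, side=side, lobe=lobe)
            text = text[0].upper() + text[1:]
        else:  # measurement phrasing, kept on the correct side of 3 cm
            cm = round(size_px_to_cm(sample.size_px, threshold_px), 1)
            if sample.size_class == "small":
                cm = min(2.9, max(0.3, cm))
            else:
                cm = max(3.0, cm)
            if rng.random() < 0.3:
                text = _MM_TEMPLATE.format(mm=int(round(cm * 10)), side=side)
            else:
                tmpl = _CM_TEMPLATES[rng.integers(len(_CM_TEMPLATES))]
                text = tmpl.format(cm=cm, side=side)
    if rng.random() < 0.5:
        text += " " + _DISTRACTORS[rng.integers(len(_DISTRACTORS))]
    return text


def write_cohort(samples: list[ImageSample], table: pd.DataFrame,
                 outdir: str | Path) -> Path:
    """Write images as 8-bit grayscale PNG and the cohort table as CSV."""
    from PIL import Image

    outdir = Path(outdir)
    (outdir / "images").mkdir(parents=True, exist_ok=True)
    for s in samples:
        arr = np.round(s.pixels * 255).astype(np.uint8)
        Image.fromarray(arr, mode="L").save(outdir / "images" / f"{s.id}.png")
    table.to_csv(outdir / "cohort.csv", index=False)
    return outdir / "cohort.csv"


def write_reports(samples: list[ImageSample], path: str | Path,
                  seed: int = 0, threshold_px: float = 12.0) -> Path:
    """Write one report per sample as JSONL {"id", "text"}."""
    path = Path(path)
    rng = np.random.default_rng(seed)
    with open(path, "w") as fh:
        for s in samples:
            text = generate_report(s, seed=int(rng.integers(2**31 - 1)),
                                   threshold_px=threshold_px)
            fh.write(json.dumps({"id": s.id, "text": text}) + "\n")
    return path
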