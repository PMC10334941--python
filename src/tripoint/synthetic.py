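"""Seeded synthetic dermoscopy-like data with checklist ground truth.

Real dermoscopic archives cannot ship with a test suite, so this module
renders small lesion-on-skin images in which the three 3-point-checklist
features are embedded programmatically and independently switchable:

* **asymmetry** — the lesion boundary radius on one half of the lesion is
  inflated relative to the other, breaking mirror symmetry;
* **atypical network** — a darker sinusoidal reticular mesh overlays the
  lesion, mimicking an irregular pigment network;
* **blue-white structure** — a soft blue-gray blob sits inside the lesion.

The disease label is drawn from a logistic model on the checklist score
(the sum of the three flags), P(melanoma | s) = sigmoid(β0 + β1·s), so the
checklist's ranking rule is true by construction; an optional
melanoma-specific darkening cue lets disease accuracy exceed the checklist
ceiling.  A per-image multiplicative color cast is applied last, giving the
color-constancy stage real work.  Everything is a pure function of
(config, seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .losses import ChecklistAnnotation
from .preprocessing import LesionImage

__all__ = [
    "SyntheticConfig",
    "SyntheticSample",
    "SyntheticDataset",
    "render_lesion",
    "sample_disease",
    "generate_dataset",
    "write_dataset",
]

MANIFEST_COLUMNS = [
    "image_id",
    "path",
    "split",
    "labeled",
    "disease",
    "asymmetry",
    "network",
    "bluewhite",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Generation parameters; the defaults emulate the study design.

    900 feature-annotated images balanced 450/450 between melanoma and
    nevus, a larger disease-only unlabeled pool, an 80/20 train/validation
    split of the labeled set, and a 400-image holdout partition.
    """

    image_size: int = 64
    n_labeled: int = 900
    n_unlabeled: int = 2000
    holdout_size: int = 400
    class_balance: float = 0.5
    feature_prevalence: float = 0.5
    score_logit_intercept: float = -2.2  # β0 of the score→disease logistic
    score_logit_slope: float = 1.5  # β1, per checklist point
    direct_cue_strength: float = 0.35
    illumination_cast_range: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size < 32:
            raise ValueError("image_size must be at least 32")
        if min(self.n_labeled, self.n_unlabeled, self.holdout_size) < 0:
            raise ValueError("sample counts must be nonnegative")
        if not 0.0 <= self.class_balance <= 1.0:
            raise ValueError("class_balance must lie in [0, 1]")
        if not 0.0 <= self.feature_prevalence <= 1.0:
            raise ValueError("feature_prevalence must lie in [0, 1]")
        if not 0.0 <= self.direct_cue_strength <= 1.0:
            raise ValueError("direct_cue_strength must lie in [0, 1]")
        if not 0.0 <= self.illumination_cast_range < 1.0:
            raise ValueError("illumination_cast_range must lie in [0, 1)")


@dataclass
class SyntheticSample:
    image: LesionImage
    annotation: ChecklistAnnotation  # ground truth, always retained internally
    disease: int  # melanoma = 1, nevus = 0
    split: str  # train | val | holdout
    labeled: bool  # features exposed in the manifest?
    cast: np.ndarray | None = None  # the applied per-channel tint
    clean_pixels: np.ndarray | None = None  # cast-free render, for references


@dataclass
class SyntheticDataset:
    samples: list[SyntheticSample]
    config: SyntheticConfig
    warnings: list[str] = field(default_factory=list)

    def manifest(self) -> pd.DataFrame:
        """Manifest with one row per image; feature cells empty when unlabeled."""
        rows = []
        for s in self.samples:
            a = s.annotation
            rows.append(
                {
                    "image_id": s.image.image_id,
                    "path": f"{s.image.image_id}.png",
                    "split": s.split,
                    "labeled": s.labeled,
                    "disease": s.disease,
                    "asymmetry": a.asymmetry if s.labeled else np.nan,
                    "network": a.atypical_network if s.labeled else np.nan,
                    "bluewhite": a.blue_white if s.labeled else np.nan,
                }
            )
        return pd.DataFrame(rows, columns=MANIFEST_COLUMNS)

    def subset(self, split: str | None = None, labeled: bool | None = None):
        out = self.samples
        if split is not None:
            out = [s for s in out if s.split == split]
        if labeled is not None:
            out = [s for s in out if s.labeled == labeled]
        return out


_SKIN = np.array([0.85, 0.62, 0.52])
_LESION = np.array([0.42, 0.28, 0.24])
_BLUE = np.array([0.52, 0.60, 0.76])


def _render_base(
    features: tuple[int, int, int],
    image_size: int,
    rng: np.random.Generator,
    melanoma_cue: float = 0.0,
) -> np.ndarray:
    """Cast-free lesion render; consumes a fixed number of rng draws."""
    asym, network, bluewhite = features
    s = image_size
    yy, xx = np.mgrid[0:s, 0:s].astype(np.float64)

    cx = s / 2 + rng.uniform(-0.03, 0.03) * s
    cy = s / 2 + rng.uniform(-0.03, 0.03) * s
    dx, dy = xx - cx, yy - cy
    dist = np.hypot(dx, dy)
    theta = np.arctan2(dy, dx)

    r0 = rng.uniform(0.19, 0.24) * s
    wobble_phase = rng.uniform(0, 2 * np.pi)
    axis = rng.uniform(0, 2 * np.pi)
    radius = r0 * (1.0 + 0.07 * np.sin(3 * theta + wobble_phase))
    if asym:
        # inflate one angular half, smoothly ramped across the dividing axis
        half = 1.0 / (1.0 + np.exp(-6.0 * np.cos(theta - axis)))
        radius = radius * (1.0 + 0.5 * half)

    edge = 0.035 * s
    mask = 1.0 / (1.0 + np.exp((dist - radius) / edge))

    img = np.empty((s, s, 3))
    img[:] = _SKIN
    img += rng.normal(0.0, 0.015, size=(s, s, 1))  # skin texture noise
    gx, gy_ = rng.uniform(-0.04, 0.04, size=2)  # gentle shading gradient
    img += (gx * (xx - s / 2) / s + gy_ * (yy - s / 2) / s)[:, :, None]

    lesion_color = _LESION * (1.0 - 0.35 * melanoma_cue)
    img = img * (1 - mask[:, :, None]) + lesion_color[None, None, :] * mask[:, :, None]

    freq = rng.uniform(5.5, 7.5)
    ph1, ph2 = rng.uniform(0, 2 * np.pi, size=2)
    if network:
        mesh = np.sin(2 * np.pi * freq * xx / s + ph1) * np.sin(
            2 * np.pi * freq * yy / s + ph2
        )
        mesh_mask = (mesh > 0.15).astype(np.float64) * mask
        img -= 0.28 * mesh_mask[:, :, None]

    off_r = rng.uniform(0.0, 0.4) * r0
    off_a = rng.uniform(0, 2 * np.pi)
    if bluewhite:
        bx, by = cx + off_r * np.cos(off_a), cy + off_r * np.sin(off_a)
        sigma = 0.38 * r0
        blob = np.exp(-((xx - bx) ** 2 + (yy - by) ** 2) / (2 * sigma**2)) * mask
        w = 0.85 * blob[:, :, None]
        img = img * (1 - w) + _BLUE[None, None, :] * w

    return np.clip(img, 0.0, 1.0)


def _draw_cast(rng: np.random.Generator, cast_range: float) -> np.ndarray:
    return rng.uniform(1.0 - cast_range, 1.0 + cast_range, size=3)


def render_lesion(
    features: tuple[int, int, int],
    image_size: int,
    rng: np.random.Generator,
    melanoma_cue: float = 0.0,
    cast_range: float = 0.15,
    image_id: str = "",
    return_clean: bool = False,
):
    """Render one lesion image with the given checklist features embedded.

    A random per-channel multiplicative color cast (drawn uniformly from
    ``[1 - cast_range, 1 + cast_range]``) is applied last.  With
    ``return_clean=True`` the cast-free render and the cast vector are also
    returned, giving color-constancy evaluations an exact reference.
    """
    if image_size < 32:
        raise ValueError(
            f"image_size {image_size} too small to render all checklist features; "
            "need at least 32"
        )
    for f in features:
        if f not in (0, 1):
            raise ValueError("features must be three binary flags")
    clean = _render_base(tuple(features), image_size, rng, melanoma_cue)
    cast = _draw_cast(rng, cast_range)
    tinted = np.clip(clean * cast[None, None, :], 0.0, 1.0)
    image = LesionImage(tinted, image_id=image_id)
    if return_clean:
        return image, clean, cast
    return image


def sample_disease(score: int, config: SyntheticConfig, rng: np.random.Generator) -> int:
    """Draw the disease label from the logistic score model.

    P(melanoma) = sigmoid(β0 + β1·score); strictly increasing in the score
    whenever β1 > 0, which is exactly the checklist's ranking rule.
    """
    if score not in (0, 1, 2, 3):
        raise ValueError(f"checklist score must be in 0..3, got {score!r}")
    z = config.score_logit_intercept + config.score_logit_slope * score
    p = 1.0 / (1.0 + np.exp(-z))
    return int(rng.random() < p)


def _draw_annotation(config: SyntheticConfig, rng: np.random.Generator):
    flags = tuple(int(rng.random() < config.feature_prevalence) for _ in range(3))
    return ChecklistAnnotation(*flags)


def _balanced_pool(
    n: int, config: SyntheticConfig, rng: np.random.Generator, notes: list[str]
):
    """Draw (annotation, disease) pairs hitting the target class balance.

    Rejection sampling against per-class quotas: a draw whose class quota is
    full is discarded.  Mirrors selecting an even melanoma/nevus split from
    an archive.  If a quota cannot be filled within a generous attempt
    budget, the remainder is filled best-effort and a warning recorded.
    """
    n_mel = int(round(n * config.class_balance))
    quotas = {1: n_mel, 0: n - n_mel}
    out = []
    attempts, max_attempts = 0, max(1000, 200 * n)
    while len(out) < n and attempts < max_attempts:
        attempts += 1
        ann = _draw_annotation(config, rng)
        disease = sample_disease(ann.score, config, rng)
        if quotas[disease] > 0:
            quotas[disease] -= 1
            out.append((ann, disease))
    if len(out) < n:
        notes.append(
            f"class balance {config.class_balance} unreachable; "
            f"filled {len(out)}/{n}, topping up without balance"
        )
        warnings.warn(notes[-1])
        while len(out) < n:
            ann = _draw_annotation(config, rng)
            out.append((ann, sample_disease(ann.score, config, rng)))
    return out


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Generate the full labeled + unlabeled + holdout sample collection.

    The labeled pool (class-balanced, feature-annotated) is split 80/20
    into train/val; the unlabeled pool (disease label only, natural class
    mix) joins the training split; the holdout partition is balanced and
    fully annotated, disjoint from everything else.
    """
    rng = np.random.default_rng(config.seed)
    notes: list[str] = []
    samples: list[SyntheticSample] = []

    def render_one(ann, disease, idx, split, labeled):
        cue = config.direct_cue_strength if disease == 1 else 0.0
        image, clean, cast = render_lesion(
            (ann.asymmetry, ann.atypical_network, ann.blue_white),
            config.image_size,
            rng,
            melanoma_cue=cue,
            cast_range=config.illumination_cast_range,
            image_id=f"syn_{idx:06d}",
            return_clean=True,
        )
        return SyntheticSample(
            image=image,
            annotation=ann,
            disease=disease,
            split=split,
            labeled=labeled,
            cast=cast,
            clean_pixels=clean,
        )

    idx = 0
    labeled_pairs = _balanced_pool(config.n_labeled, config, rng, notes)
    order = rng.permutation(config.n_labeled)
    n_val = config.n_labeled - int(round(0.8 * config.n_labeled))
    val_ids = set(order[:n_val].tolist())
    for i, (ann, disease) in enumerate(labeled_pairs):
        split = "val" if i in val_ids else "train"
        samples.append(render_one(ann, disease, idx, split, True))
        idx += 1

    for _ in range(config.n_unlabeled):
        ann = _draw_annotation(config, rng)
        disease = sample_disease(ann.score, config, rng)
        samples.append(render_one(ann, disease, idx, "train", False))
        idx += 1

    holdout_pairs = _balanced_pool(config.holdout_size, config, rng, notes)
    for ann, disease in holdout_pairs:
        samples.append(render_one(ann, disease, idx, "holdout", True))
        idx += 1

    return SyntheticDataset(samples=samples, config=config, warnings=notes)


def write_dataset(dataset: SyntheticDataset, out_dir) -> "pd.DataFrame":
    """Write PNG images and the CSV manifest to ``out_dir``; returns the manifest."""
    from pathlib import Path

    from PIL import Image

    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    manifest = dataset.manifest()
    manifest["path"] = [f"images/{i}.png" for i in manifest["image_id"]]
    for s in dataset.samples:
        arr = np.round(s.image.pixels * 255.0).astype(np.uint8)
        Image.fromarray(arr).save(out / "images" / f"{s.image.image_id}.png")
    manifest.to_csv(out / "manifest.csv", index=False)
    if dataset.warnings:
        (out / "generation_warnings.txt").write_text("\n".join(dataset.warnings) + "\n")
    return manifest
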