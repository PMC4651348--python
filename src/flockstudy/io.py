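"""Synthetic image fixtures, manifests, and record-file round-trips.

The study's original slide and mammogram patches cannot be redistributed, so
the pipeline ships a seeded generator of class-structured stand-ins:

* histology-like textures — an eosin-pink background with granular noise and
  dark basophilic nuclei blobs; the positive (malignant-like) class has
  denser, more size-variable nuclei than the negative class;
* mammogram-like patches — a smooth gray parenchyma field with film grain;
  positives carry one or more clusters of small bright speckles
  (microcalcification-like), negatives carry none.

Each image receives a ``difficulty`` value emulating the mean accuracy of a
human reader panel, derived from how far the image's realized texture sits
from the class boundary, so difficulty is usable for balanced set splits and
correlates with simulated-observer errors.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .observer_sim import LatentStimulus
from .session_engine import RECORD_COLUMNS
from .stimulus_prep import DifficultyItem, StimulusImage

__all__ = [
    "FixtureSpec",
    "generate_image_fixtures",
    "difficulty_items",
    "latent_from_manifest",
    "read_records",
    "write_records",
    "save_images",
]

REQUIRED_RECORD_COLUMNS = [
    "observer_id",
    "day",
    "trial_index",
    "stimulus_id",
    "true_label",
    "choice",
    "correct",
    "is_correction_trial",
    "reinforced",
]

_KEY = ["observer_id", "day", "trial_index", "attempt"]


@dataclass(frozen=True)
class FixtureSpec:
    """Settings for the synthetic stimulus generator.

    ``effect_size`` scales the separation of the class texture parameters:
    1.0 gives visually distinct but overlapping classes; 0 makes the classes
    indistinguishable.
    """

    n_per_class: int = 24
    side: int = 308
    kind: str = "histology"
    effect_size: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if self.side < 16:
            raise ValueError("side must be >= 16")
        if self.kind not in ("histology", "mammogram"):
            raise ValueError("kind must be 'histology' or 'mammogram'")


def _draw_blobs(img: np.ndarray, rng, n, r_mean, r_sd, color, softness=1.0):
    side = img.shape[0]
    yy, xx = np.mgrid[0:side, 0:side]
    for _ in range(n):
        cy, cx = rng.uniform(0, side, size=2)
        r = max(1.0, rng.normal(r_mean, r_sd))
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        w = np.exp(-d2 / (2.0 * (softness * r) ** 2))[..., None]
        img[:] = img * (1 - w) + np.asarray(color, dtype=float) * w
    return img


def _histology(rng, side, n_blobs):
    img = np.empty((side, side, 3))
    img[:] = (228, 186, 205)  # eosin-pink stroma
    img += rng.normal(0, 9, size=img.shape)
    _draw_blobs(img, rng, n_blobs, r_mean=side / 45, r_sd=side / 120,
                color=(92, 56, 130))
    return np.clip(img, 0, 255).astype(np.uint8)


def _mammogram(rng, side, n_clusters):
    img = np.empty((side, side, 3))
    base = rng.uniform(90, 120)
    img[:] = base
    # low-frequency parenchyma variation
    _draw_blobs(img, rng, 6, r_mean=side / 3, r_sd=side / 8,
                color=(base + rng.uniform(15, 35),) * 3, softness=1.0)
    img += rng.normal(0, 6, size=img.shape)
    yy, xx = np.mgrid[0:side, 0:side]
    for _ in range(n_clusters):
        cy, cx = rng.uniform(side * 0.2, side * 0.8, size=2)
        n_dots = int(rng.integers(5, 14))
        for _ in range(n_dots):
            dy, dx = rng.normal(0, side / 18, size=2)
            py = float(np.clip(cy + dy, 1, side - 2))
            px = float(np.clip(cx + dx, 1, side - 2))
            r = max(1.2, side / 180) * rng.uniform(0.7, 1.3)
            d2 = (yy - py) ** 2 + (xx - px) ** 2
            w = np.exp(-d2 / (2.0 * r**2))[..., None]
            img[:] = img * (1 - w) + 240.0 * w
    return np.clip(img, 0, 255).astype(np.uint8)


def generate_image_fixtures(
    spec: FixtureSpec,
) -> tuple[list[StimulusImage], pd.DataFrame]:
    """Seeded synthetic stimulus set plus its manifest.

    Returns the images and a manifest with one row per image: ``id``,
    ``label``, ``magnification``, ``orientation``, ``compression_ratio``,
    ``n_features`` (blob or cluster count actually drawn) and ``difficulty``
    (emulated mean human accuracy in [0, 1]; negatives in the mammogram kind
    carry zero clusters by construction).  Identical spec and seed reproduce
    byte-identical images.
    """
    rng = np.random.default_rng(spec.seed)
    images: list[StimulusImage] = []
    rows = []
    if spec.kind == "histology":
        # nuclei-per-patch intensity, scaled to patch area
        scale = (spec.side / 308.0) ** 2
        mean_neg, mean_pos = 45 * scale, 45 * scale * (1 + 1.2 * spec.effect_size)
        spread = 18 * scale
        boundary = 0.5 * (mean_neg + mean_pos)
        for label, mean in (("positive", mean_pos), ("negative", mean_neg)):
            for i in range(spec.n_per_class):
                n = max(1, int(rng.normal(mean, spread)))
                pixels = _histology(rng, spec.side, n)
                sep = (n - boundary) / spread * (1 if label == "positive" else -1)
                difficulty = _difficulty_from_separation(sep, rng)
                sid = f"hist_{label[:3]}_{i:03d}"
                images.append(StimulusImage(id=sid, pixels=pixels, label=label,
                                            magnification="10x"))
                rows.append(dict(id=sid, label=label, n_features=n,
                                 difficulty=difficulty))
    else:
        for label in ("positive", "negative"):
            for i in range(spec.n_per_class):
                if label == "positive":
                    n = int(rng.integers(1, 3))
                    sep = 1.0 * spec.effect_size + rng.normal(0, 0.6)
                else:
                    n = 0
                    sep = 1.0 * spec.effect_size + rng.normal(0, 0.6)
                pixels = _mammogram(rng, spec.side, n)
                difficulty = _difficulty_from_separation(sep, rng)
                sid = f"mamm_{label[:3]}_{i:03d}"
                images.append(StimulusImage(id=sid, pixels=pixels, label=label))
                rows.append(dict(id=sid, label=label, n_features=n,
                                 difficulty=difficulty))
    manifest = pd.DataFrame(rows)
    manifest["magnification"] = "10x" if spec.kind == "histology" else "n/a"
    manifest["orientation"] = "r0"
    manifest["compression_ratio"] = 1.0
    return images, manifest


def _difficulty_from_separation(sep: float, rng) -> float:
    """Map a signed class-boundary separation to an emulated panel accuracy."""
    p = ndtr(0.8 * sep + rng.normal(0, 0.25))
    return float(np.clip(p, 0.05, 0.99))


def difficulty_items(manifest: pd.DataFrame) -> list[DifficultyItem]:
    """Manifest rows as difficulty items for balanced partitioning."""
    return [
        DifficultyItem(stimulus_id=r.id, label=r.label, difficulty=r.difficulty)
        for r in manifest.itertuples()
    ]


def latent_from_manifest(
    manifest: pd.DataFrame, scale: float = 0.5
) -> list[LatentStimulus]:
    """Latent stimuli whose evidence offsets track manifest difficulty.

    The probit of the (clipped) panel accuracy is centred across the set and
    scaled, so harder images get lower — possibly negative — offsets, which
    makes simulated-observer errors concentrate on the images humans also
    miss.
    """
    z = ndtri(np.clip(manifest["difficulty"].to_numpy(float), 1e-3, 1 - 1e-3))
    z = (z - z.mean()) * scale
    return [
        LatentStimulus(stimulus_id=r.id, true_label=r.label, evidence_offset=float(o))
        for r, o in zip(manifest.itertuples(), z)
    ]


def save_images(
    images: Sequence[StimulusImage], manifest: pd.DataFrame, out_dir: str | Path
) -> pd.DataFrame:
    """Write images as PNG plus the manifest CSV; returns the manifest with
    a ``path`` column added."""
    from PIL import Image

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for im in images:
        p = out / f"{im.id}.png"
        Image.fromarray(im.pixels).save(p, "PNG", optimize=True)
        paths.append(str(p))
    manifest = manifest.copy()
    manifest["path"] = paths
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest


# ---------------------------------------------------------------------------
# Record files
# ---------------------------------------------------------------------------


def write_records(records: pd.DataFrame, path: str | Path) -> None:
    """Write a response-record table as CSV (or JSON Lines for ``.jsonl``)."""
    path = Path(path)
    if path.suffix == ".jsonl":
        records.to_json(path, orient="records", lines=True)
    else:
        records.to_csv(path, index=False)


def read_records(path: str | Path) -> pd.DataFrame:
    """Read and validate a response-record table.

    Checks that all required columns are present, coerces dtypes, and rejects
    duplicated (observer, day, trial, attempt) keys, naming the first bad
    row.  An empty file with a valid header yields an empty table.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix == ".jsonl":
        df = pd.read_json(path, orient="records", lines=True)
        if df.empty:
            df = pd.DataFrame(columns=RECORD_COLUMNS)
    else:
        df = pd.read_csv(path)
    missing = [c for c in REQUIRED_RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"record file {path} is missing required columns: {missing}")
    if df.empty:
        return df
    if "attempt" not in df.columns:
        df["attempt"] = df["is_correction_trial"].astype(int)
    for col in ("correct", "is_correction_trial", "reinforced"):
        df[col] = df[col].astype(bool)
    for col in ("day", "trial_index", "attempt"):
        df[col] = df[col].astype(int)
    dup = df.duplicated(subset=_KEY)
    if dup.any():
        first = df.loc[dup, _KEY].iloc[0].to_dict()
        raise ValueError(f"duplicated record key in {path}: {first}")
    return df
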